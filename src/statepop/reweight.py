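"""Conformational-state population estimation by constrained least squares.

A protein's conformational ensemble is approximated as a mixture of a few
reference states, each summarised by an average inter-residue distance
matrix d^s.  Given a predicted distance matrix d̂ for a ligand-bound (or apo)
ensemble, the state populations w are estimated by minimising

    MSE(w) = (1/N) Σ_(i,j) ( Σ_s w_s d^s_ij − d̂_ij )²

over the probability simplex (w_s ∈ [0, 1], Σ w_s = 1), where the sum runs
over all ordered unmasked residue pairs, diagonal included, and N is the
number of pairs actually summed.  The objective is an explicit quadratic in
w, so it is minimised with SLSQP using the analytic gradient, restarted from
the uniform point and one vertex-biased point per state.  A brute-force
simplex-grid search is provided as an independent verification oracle.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.optimize import minimize

from .ensembles import DistanceMatrix, ResidueId, StateLibrary, _as_residue_ids
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateWeights:
    """A point on the state simplex."""

    states: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(self.states),):
            raise InputError("one weight required per state")
        if np.any(w < -1e-6) or np.any(w > 1 + 1e-6):
            raise InputError(f"weights outside [0, 1]: {w}")
        if abs(w.sum() - 1.0) > 1e-6:
            raise InputError(f"weights sum to {w.sum()}, expected 1")
        object.__setattr__(self, "w", np.clip(w, 0.0, 1.0))

    def as_dict(self) -> dict:
        return {s: float(x) for s, x in zip(self.states, self.w)}


@dataclass
class PredictedDistanceMatrix:
    """A model-predicted residue–residue distance matrix (point estimate).

    ``mask`` marks pairs that carry usable information; pairs censored by the
    prediction range (clamped at the 1/20 Å truncation bounds) are masked
    out.  Optional per-pair binned distributions ride along for the
    distribution-level analyses.
    """

    residue_ids: tuple[ResidueId, ...]
    values: np.ndarray
    mask: np.ndarray = None
    distributions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.residue_ids = _as_residue_ids(self.residue_ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.residue_ids)
        if v.shape != (n, n):
            raise InputError(f"values must be ({n}, {n}), got {v.shape}")
        if self.mask is None:
            self.mask = np.ones((n, n), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n, n):
                raise InputError("mask shape mismatch")
        both = self.mask & self.mask.T
        if not np.allclose(v[both], v.T[both], atol=1e-8):
            raise InputError("predicted matrix is not symmetric")
        if not np.all(np.isfinite(v[self.mask])):
            raise InputError("non-finite unmasked predictions")
        self.values = v

    @property
    def n_res(self) -> int:
        return len(self.residue_ids)

    def index_of(self, key) -> int:
        from .ensembles import _resolve_residue

        return _resolve_residue(self.residue_ids, key)


@dataclass
class ReweightResult:
    weights: StateWeights
    mse: float  # Å², objective value at the optimum
    n_pairs: int  # ordered pairs actually summed
    converged: bool
    restarts_used: int
    coverage: float = 1.0  # fraction of library residues used

    def to_json(self, path=None):
        payload = {
            "weights": self.weights.as_dict(),
            "mse": self.mse,
            "n_pairs": self.n_pairs,
            "converged": self.converged,
            "restarts_used": self.restarts_used,
            "coverage": self.coverage,
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass(frozen=True)
class ReweightOptions:
    tol: float = 1e-10
    max_iter: int = 500
    min_coverage: float = 0.5
    vertex_bias: float = 0.85  # dominant weight of the vertex-biased starts


def ensemble_distance(w: StateWeights, lib: StateLibrary) -> DistanceMatrix:
    """Weighted-average distance matrix d̄(w) = Σ_s w_s d^s of the ensemble."""
    if w.states != lib.states:
        raise InputError(f"weight states {w.states} != library states {lib.states}")
    values = np.tensordot(w.w, lib.stack(), axes=1)
    return DistanceMatrix(lib.residue_ids, values)


# ---------------------------------------------------------------------------
# objective assembly


def _aligned_problem(p: PredictedDistanceMatrix, lib: StateLibrary, min_coverage: float):
    """Reduce to shared residues; return (D stack, d̂, pair mask, coverage)."""
    if p.residue_ids == lib.residue_ids:
        idx_p = idx_l = np.arange(len(lib.residue_ids))
        coverage = 1.0
    else:
        shared = [r for r in lib.residue_ids if r in set(p.residue_ids)]
        coverage = len(shared) / len(lib.residue_ids)
        if coverage < min_coverage:
            raise InputError(
                f"prediction covers only {coverage:.0%} of library residues "
                f"(minimum {min_coverage:.0%})"
            )
        pos_p = {r: k for k, r in enumerate(p.residue_ids)}
        pos_l = {r: k for k, r in enumerate(lib.residue_ids)}
        idx_p = np.array([pos_p[r] for r in shared])
        idx_l = np.array([pos_l[r] for r in shared])
    D = lib.stack()[:, idx_l[:, None], idx_l[None, :]]
    dhat = p.values[idx_p[:, None], idx_p[None, :]]
    mask = p.mask[idx_p[:, None], idx_p[None, :]]
    return D, dhat, mask, coverage


def _quadratic(D: np.ndarray, dhat: np.ndarray, mask: np.ndarray):
    """MSE(w) = wᵀA w − 2 bᵀw + c over the masked ordered pairs."""
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise InputError("no unmasked residue pairs shared by prediction and library")
    Dm = D[:, mask]  # (K, n_pairs)
    dm = dhat[mask]
    A = Dm @ Dm.T / n_pairs
    b = Dm @ dm / n_pairs
    c = float(dm @ dm) / n_pairs
    return A, b, c, n_pairs


def reweight_populations(
    p: PredictedDistanceMatrix,
    lib: StateLibrary,
    opts: ReweightOptions = ReweightOptions(),
) -> ReweightResult:
    """Fit simplex state weights w* minimising the distance-matrix MSE.

    Multistart SLSQP: the uniform point plus one interior vertex-biased point
    per state; the best converged iterate wins.  ``converged`` is False only
    when every restart fails, in which case the best iterate found is still
    returned (with a warning).
    """
    if lib.n_states < 2:
        raise InputError("reweighting needs a library with at least 2 states")
    D, dhat, mask, coverage = _aligned_problem(p, lib, opts.min_coverage)
    A, b, c, n_pairs = _quadratic(D, dhat, mask)
    K = lib.n_states

    def objective(w):
        return float(w @ A @ w - 2.0 * b @ w + c)

    def gradient(w):
        return 2.0 * (A @ w - b)

    starts = [np.full(K, 1.0 / K)]
    rest = (1.0 - opts.vertex_bias) / max(K - 1, 1)
    for k in range(K):
        s = np.full(K, rest)
        s[k] = opts.vertex_bias
        starts.append(s)

    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones_like(w)}]
    bounds = [(0.0, 1.0)] * K
    best, best_val, any_ok = None, np.inf, False
    for s in starts:
        res = minimize(
            objective,
            s,
            jac=gradient,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"ftol": opts.tol, "maxiter": opts.max_iter},
        )
        any_ok = any_ok or res.success
        val = objective(_project(res.x))
        if val < best_val:
            best, best_val = _project(res.x), val
    if not any_ok:
        warnings.warn("SLSQP failed to converge from every start", stacklevel=2)
    mse = max(best_val, 0.0)
    return ReweightResult(
        StateWeights(lib.states, best), mse, n_pairs, any_ok, len(starts), coverage
    )


def _project(w: np.ndarray) -> np.ndarray:
    w = np.clip(np.asarray(w, dtype=float), 0.0, 1.0)
    return w / w.sum()


def simplex_grid_search(
    p: PredictedDistanceMatrix,
    lib: StateLibrary,
    step: float = 0.05,
    opts: ReweightOptions = ReweightOptions(),
) -> ReweightResult:
    """Exhaustive MSE evaluation on the simplex lattice {w : w_s = k_s·step}.

    A deterministic brute-force oracle for :func:`reweight_populations`; the
    first lattice point (in enumeration order) attaining the minimum wins.
    """
    if not 0 < step <= 0.5:
        raise InputError("step must be in (0, 0.5]")
    K = lib.n_states
    if K == 1:
        D, dhat, mask, coverage = _aligned_problem(p, lib, opts.min_coverage)
        A, b, c, n_pairs = _quadratic(D, dhat, mask)
        w = np.array([1.0])
        return ReweightResult(
            StateWeights(lib.states, w), max(float(w @ A @ w - 2 * b @ w + c), 0.0),
            n_pairs, True, 0, coverage,
        )
    D, dhat, mask, coverage = _aligned_problem(p, lib, opts.min_coverage)
    A, b, c, n_pairs = _quadratic(D, dhat, mask)
    m = round(1.0 / step)
    best_w, best_val = None, np.inf
    # compositions of m into K non-negative parts
    for cut in combinations_with_replacement(range(m + 1), K - 1):
        parts = np.diff((0,) + cut + (m,))
        w = parts / m
        val = float(w @ A @ w - 2.0 * b @ w + c)
        if val < best_val - 0.0:
            best_w, best_val = w, val
    return ReweightResult(
        StateWeights(lib.states, best_w), max(best_val, 0.0), n_pairs, True, 0, coverage
    )


def n_lattice_points(n_states: int, step: float) -> int:
    """Number of simplex lattice points evaluated by the grid search."""
    from math import comb

    m = round(1.0 / step)
    return comb(m + n_states - 1, n_states - 1)


# ---------------------------------------------------------------------------
# interpretation


@dataclass(frozen=True)
class PredominantState:
    label: str
    margin: float
    ambiguous: bool


def predominant_state(r: ReweightResult) -> PredominantState:
    """The state with maximum fitted weight and its gap to the runner-up."""
    w = r.weights.w
    order = np.argsort(-w, kind="stable")  # stable: ties fall back to state order
    best = int(order[0])
    margin = float(w[best] - w[int(order[1])]) if len(w) > 1 else 1.0
    return PredominantState(r.weights.states[best], margin, margin < 1e-6 and len(w) > 1)


def population_shift(holo: StateWeights, apo: StateWeights) -> np.ndarray:
    """Per-state signed population change holo − apo (sums to 0)."""
    if holo.states != apo.states:
        raise InputError("holo and apo weights must share the same state order")
    return holo.w - apo.w
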