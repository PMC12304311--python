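"""State-discrimination statistics over residue-pair distances.

Given several conformational states, each sampled by a set of conformers,
the per-pair one-way ANOVA F-statistic measures how well the distance
between a residue pair separates the states.  Following the source analysis
convention, conformers are treated as independent samples and no
multiple-comparison adjustment is applied.  Distance distributions are
summarised either as Gaussian KDE curves (measured ensembles) or as binned
probability bars (model predictions), with mean/sd summary moments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .ensembles import (
    ResidueId,
    StateEnsemble,
    StateLibrary,
    _resolve_residue,
    conformer_distance_matrix,
)
from .errors import InputError


@dataclass
class FMap:
    """Per-residue-pair one-way ANOVA F and p values across states."""

    residue_ids: tuple[ResidueId, ...]
    f_values: np.ndarray  # symmetric, diagonal NaN
    p_values: np.ndarray
    group_sizes: tuple[int, ...]
    degenerate: np.ndarray  # True where total variance was zero
    df: tuple[int, int]

    def to_tsv(self, path) -> None:
        headers = [f"{c}:{n}" for c, n, _ in self.residue_ids]
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(headers) + "\n")
            for h, row in zip(headers, self.f_values):
                fh.write(h + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


@dataclass
class DistanceDistribution:
    """A binned probability distribution over distances (Å)."""

    bin_edges: np.ndarray  # ascending, len = n_bins + 1
    probs: np.ndarray  # len = n_bins, sums to 1
    kind: str = "binned"  # "binned" | "kde-sampled"

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if edges.ndim != 1 or len(edges) != len(probs) + 1:
            raise InputError("need n_bins + 1 edges")
        if np.any(np.diff(edges) <= 0):
            raise InputError("bin edges must be strictly increasing")
        if np.any(probs < -1e-12):
            raise InputError("negative bin probability")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise InputError(f"probs sum to {probs.sum()}, expected 1")
        self.bin_edges = edges
        self.probs = np.clip(probs, 0.0, None)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_json(self, path=None):
        payload = {
            "bin_edges": self.bin_edges.tolist(),
            "probs": self.probs.tolist(),
            "kind": self.kind,
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, source) -> "DistanceDistribution":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(np.array(payload["bin_edges"]), np.array(payload["probs"]), payload["kind"])


# ---------------------------------------------------------------------------
# ANOVA


def anova_f_map(ensembles: Sequence[StateEnsemble]) -> FMap:
    """One-way ANOVA F/p per residue pair across ≥2 state ensembles.

    Pairs with zero total variance are degenerate: F = 0, p = 1, flagged.
    Pairs with zero within-group but nonzero between-group variance get
    F = inf, p = 0.
    """
    if len(ensembles) < 2:
        raise InputError("ANOVA needs at least two states")
    ref = ensembles[0].residue_ids
    for e in ensembles[1:]:
        if e.residue_ids != ref:
            raise InputError("state ensembles do not share a residue index")
    for e in ensembles:
        if e.n_conf < 2:
            raise InputError(f"state {e.state_label!r} has fewer than 2 conformers")

    stacks = [
        np.stack([conformer_distance_matrix(c).values for c in e.conformers])
        for e in ensembles
    ]
    ns = np.array([s.shape[0] for s in stacks])
    k = len(stacks)
    n_tot = int(ns.sum())
    df_b, df_w = k - 1, n_tot - k

    group_means = np.stack([s.mean(axis=0) for s in stacks])  # (k, N, N)
    grand = np.tensordot(ns, group_means, axes=1) / n_tot
    ssb = np.tensordot(ns, (group_means - grand) ** 2, axes=1)
    ssw = sum(((s - m) ** 2).sum(axis=0) for s, m in zip(stacks, group_means))

    tiny = 1e-12
    degenerate = (ssb + ssw) <= tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f = np.where(degenerate, 0.0, f)
    f = np.where(~degenerate & (ssw <= tiny), np.inf, f)
    p = np.where(np.isinf(f), 0.0, sps.f.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w))
    p = np.where(degenerate, 1.0, p)

    n = len(ref)
    diag = np.eye(n, dtype=bool)
    f[diag] = np.nan
    p[diag] = np.nan
    degenerate = degenerate | diag
    return FMap(ref, f, p, tuple(int(x) for x in ns), degenerate, (df_b, df_w))


def top_discriminative_pairs(fmap: FMap, k: int) -> list[tuple[int, int, float]]:
    """The k residue pairs with the largest F, descending; ties by (i, j)."""
    if k < 1:
        raise InputError("k must be >= 1")
    n = len(fmap.residue_ids)
    iu, ju = np.triu_indices(n, k=1)
    defined = ~fmap.degenerate[iu, ju] & ~np.isnan(fmap.f_values[iu, ju])
    pairs = [
        (int(i), int(j), float(fmap.f_values[i, j]))
        for i, j in zip(iu[defined], ju[defined])
    ]
    if not pairs:
        warnings.warn("F-map has no non-degenerate pairs", stacklevel=2)
        return []
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    if k > len(pairs):
        warnings.warn(
            f"requested {k} pairs but only {len(pairs)} are defined", stacklevel=2
        )
    return pairs[:k]


# ---------------------------------------------------------------------------
# distributions


def bin_edges(lo: float, hi: float, width: float) -> np.ndarray:
    """Half-open bins of the given width over [lo, hi]; last bin may be short."""
    if not lo < hi:
        raise InputError("lo must be < hi")
    if width <= 0:
        raise InputError("width must be positive")
    n_bins = math.ceil((hi - lo) / width - 1e-9)
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = min(edges[-1], hi)
    return edges


def binned_distribution(
    samples, lo: float = 1.0, hi: float = 20.0, width: float = 0.19
) -> DistanceDistribution:
    """Bin distance samples — or rebin native model bins — onto a fixed grid.

    ``samples`` is either a 1-D array of distances (clamped to [lo, hi]
    before binning) or a ``(native_edges, native_probs)`` pair, in which case
    the native mass is redistributed onto the requested grid proportionally
    to bin overlap, so differently gridded distributions become comparable.
    """
    edges = bin_edges(lo, hi, width)
    if isinstance(samples, tuple) and len(samples) == 2:
        native = DistanceDistribution(np.asarray(samples[0], float), np.asarray(samples[1], float))
        return rebin(native, edges)
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InputError("no samples to bin")
    if not np.all(np.isfinite(samples)):
        raise InputError("non-finite samples")
    clamped = np.clip(samples, lo, hi)
    counts, _ = np.histogram(clamped, bins=edges)
    return DistanceDistribution(edges, counts / counts.sum(), "binned")


def rebin(d: DistanceDistribution, edges: np.ndarray) -> DistanceDistribution:
    """Mass-conserving overlap resampling of a binned distribution."""
    edges = np.asarray(edges, dtype=float)
    src_lo, src_hi = d.bin_edges[:-1], d.bin_edges[1:]
    out = np.zeros(len(edges) - 1)
    for k, (lo_k, hi_k) in enumerate(zip(edges[:-1], edges[1:])):
        overlap = np.clip(np.minimum(src_hi, hi_k) - np.maximum(src_lo, lo_k), 0, None)
        out[k] = np.sum(d.probs * overlap / (src_hi - src_lo))
    total = out.sum()
    if total <= 0:
        raise InputError("rebinned distribution has no mass inside the target range")
    return DistanceDistribution(edges, out / total, "binned")


def distribution_moments(d: DistanceDistribution) -> tuple[float, float]:
    """(mean, sd) in Å over bin centers weighted by bin probabilities."""
    c = d.centers
    mean = float(np.sum(d.probs * c))
    var = float(np.sum(d.probs * (c - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


def kde_curve(samples, grid=None, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (Scott's bandwidth) of distance samples.

    When no grid is given, 512 points spanning the data range ± 3 bandwidths
    are used.  Returns ``(grid, density)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise InputError("KDE needs at least 2 samples")
    kde = sps.gaussian_kde(samples, bw_method="scott")
    bw = float(kde.factor * samples.std(ddof=1))
    if bw == 0:
        raise InputError("KDE undefined for zero-variance samples")
    if grid is None:
        grid = np.linspace(samples.min() - 3 * bw, samples.max() + 3 * bw, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    return grid, kde(grid)


@dataclass(frozen=True)
class IndicatorSummary:
    """Nearest-state call for one indicator residue pair."""

    mean: float
    sd: float
    nearest_state: str
    tie: bool
    state_values: dict


def indicator_pair_summary(prediction, lib: StateLibrary, i, j) -> IndicatorSummary:
    """Compare a predicted pair distance against each state's library value.

    ``prediction`` is a :class:`DistanceDistribution`, a matrix-like object
    with ``values``/``mask``/``index_of`` (a predicted distance matrix), or a
    plain number.  The nearest state is the one whose library value at (i, j)
    is closest to the predicted mean; exact ties are flagged.
    """
    ii = _resolve_residue(lib.residue_ids, i)
    jj = _resolve_residue(lib.residue_ids, j)
    if isinstance(prediction, DistanceDistribution):
        mean, sd = distribution_moments(prediction)
    elif hasattr(prediction, "values") and hasattr(prediction, "mask"):
        pi = _resolve_residue(prediction.residue_ids, i)
        pj = _resolve_residue(prediction.residue_ids, j)
        if not prediction.mask[pi, pj]:
            raise InputError("predicted pair is masked")
        mean, sd = float(prediction.values[pi, pj]), 0.0
    else:
        mean, sd = float(prediction), 0.0

    state_values = {s: float(m.values[ii, jj]) for s, m in zip(lib.states, lib.matrices)}
    gaps = {s: abs(v - mean) for s, v in state_values.items()}
    best = min(lib.states, key=lambda s: gaps[s])
    runner = min((s for s in lib.states if s != best), key=lambda s: gaps[s], default=None)
    tie = runner is not None and abs(gaps[best] - gaps[runner]) < 1e-9
    return IndicatorSummary(mean, sd, best, tie, state_values)
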