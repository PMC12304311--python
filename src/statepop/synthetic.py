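"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here: multi-state conformer
ensembles (geometry-first, so every synthetic distance matrix is a true
Euclidean metric), "predicted" distance matrices that are convex mixtures of
state means plus Gaussian noise, ligand panels with planted predominant
states, and screening libraries with planted passers.  Each generator is a
pure function of its configuration (seed included) and returns a
:class:`SyntheticTruth` recording the planted answers, so parameter-recovery
and selection-logic tests never depend on the real trained model or on
downloads.

Default shapes mirror the study conditions: 3 states × 20 conformers,
12-ligand panels grouped 6/2/4 over states A/I1/I2 with dominant weight 0.7,
0.2 Å prediction noise, and an 11-model screening table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .ensembles import (
    Conformer,
    StateEnsemble,
    StateLibrary,
    build_state_library,
)
from .errors import InputError
from .reweight import PredictedDistanceMatrix
from .screening import DISTANCE_HI, DISTANCE_LO

_DEFAULT_STATE_LABELS = ("A", "I1", "I2")

#: rank below which the default selection criteria treat a compound as a hit;
#: the screening generator plants its decoys against this guard
_TOP_RANK_GUARD = 10


class GeneratorConfig(BaseModel):
    """Geometry and noise settings for synthetic state libraries."""

    model_config = ConfigDict(extra="forbid")

    n_states: int = Field(default=3, ge=1)
    n_res: int = Field(default=150, ge=4)
    n_conf: int = Field(default=20, ge=1)
    inter_state_displacement: float = Field(default=8.0, ge=0.0)  # Å
    intra_state_jitter: float = Field(default=0.3, ge=0.0)  # Å, per-coordinate sd
    prediction_noise: float = Field(default=0.2, ge=0.0)  # Å, sd
    seed: int  # mandatory

    def state_labels(self) -> tuple[str, ...]:
        if self.n_states == len(_DEFAULT_STATE_LABELS):
            return _DEFAULT_STATE_LABELS
        return tuple(f"S{k}" for k in range(self.n_states))


class PanelSpec(BaseModel):
    """A ligand panel with planted predominant states."""

    model_config = ConfigDict(extra="forbid")

    dominant_states: list[str] = Field(
        default_factory=lambda: ["A"] * 6 + ["I1"] * 2 + ["I2"] * 4
    )
    dominance: float = Field(default=0.7, gt=0.0, le=1.0)


class ScreeningConfig(BaseModel):
    """Shape of a synthetic screening library with planted passers."""

    model_config = ConfigDict(extra="forbid")

    n_compounds: int = Field(default=200, ge=1)
    n_models: int = Field(default=11, ge=1)
    n_passers: int = Field(default=12, ge=0)
    n_single_model_stars: int = Field(default=10, ge=0)
    functional_residues: list[str] = Field(default_factory=lambda: ["K745", "E762", "D855"])
    seed: int


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, serialized beside every dataset."""

    config: dict
    true_weights: dict = field(default_factory=dict)  # ligand id -> {state: w}
    planted_blocks: dict = field(default_factory=dict)  # state -> [start, stop)
    planted_passers: list = field(default_factory=list)

    def to_json(self, path=None):
        payload = asdict(self)
        if path is None:
            return json.dumps(payload, indent=1, sort_keys=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


# ---------------------------------------------------------------------------
# geometry


def _self_avoiding_chain(n_res: int, rng: np.random.Generator,
                         bond: float = 3.8, min_sep: float = 3.0) -> np.ndarray:
    """A random self-avoiding 3D bead chain (Cα-like spacing, Å)."""
    coords = np.zeros((n_res, 3))
    i = 1
    stuck = 0
    while i < n_res:
        step = rng.normal(size=3)
        step *= bond / np.linalg.norm(step)
        cand = coords[i - 1] + step
        if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) >= min_sep:
            coords[i] = cand
            i += 1
            stuck = 0
        else:
            stuck += 1
            if stuck > 200:  # back off one bead and retry
                i = max(i - 1, 1)
                stuck = 0
    return coords


def generate_state_library(
    cfg: GeneratorConfig,
) -> tuple[StateLibrary, list[StateEnsemble], SyntheticTruth]:
    """Build a multi-state synthetic ensemble set and its average-matrix library.

    A base self-avoiding chain is shared by all states; each state beyond the
    first rigidly displaces one planted contiguous residue block (recorded in
    the truth) by ``inter_state_displacement`` along a state-specific random
    direction.  Conformers add isotropic Gaussian jitter of sd
    ``intra_state_jitter`` per coordinate.
    """
    if cfg.n_states >= 2 and cfg.inter_state_displacement == 0:
        import warnings

        warnings.warn("zero inter-state displacement: states are indistinguishable",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    base = _self_avoiding_chain(cfg.n_res, rng)
    labels = cfg.state_labels()
    residue_ids = tuple(("A", i + 1, "ALA") for i in range(cfg.n_res))

    block_len = max(cfg.n_res // 5, 2)
    start = int(rng.integers(0, cfg.n_res - block_len + 1))
    block = (start, start + block_len)

    ensembles = []
    blocks = {}
    for k, label in enumerate(labels):
        coords = base.copy()
        if k > 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[block[0]: block[1]] += cfg.inter_state_displacement * direction
            blocks[label] = [block[0], block[1]]
        conformers = tuple(
            Conformer(
                residue_ids,
                coords + rng.normal(scale=cfg.intra_state_jitter, size=coords.shape),
            )
            for _ in range(cfg.n_conf)
        )
        ensembles.append(StateEnsemble(label, conformers))

    truth = SyntheticTruth(config=cfg.model_dump(), planted_blocks=blocks)
    return build_state_library(ensembles), ensembles, truth


# ---------------------------------------------------------------------------
# predicted matrices


def generate_predicted_matrix(
    lib: StateLibrary,
    true_w: Sequence[float],
    noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
    ligand_id: str = "ligand",
) -> tuple[PredictedDistanceMatrix, SyntheticTruth]:
    """Emulate a model-predicted distance matrix with known mixture weights.

    d̂ = Σ_s w_s d^s plus symmetric Gaussian noise (noise averaged with its
    transpose), truncated to the [1, 20] Å prediction range.  Entries clamped
    by the truncation are censored: they are masked out, since they no longer
    carry mixture information.  The diagonal stays 0 and unmasked.
    """
    w = np.asarray(true_w, dtype=float)
    if w.shape != (lib.n_states,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
        raise InputError(f"true weights must lie on the {lib.n_states}-state simplex")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mixed = np.tensordot(w, lib.stack(), axes=1)
    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=mixed.shape)
        mixed = mixed + 0.5 * (noise + noise.T)
    n = mixed.shape[0]
    off = ~np.eye(n, dtype=bool)
    clamped = np.clip(mixed, DISTANCE_LO, DISTANCE_HI)
    values = np.where(off, clamped, 0.0)
    mask = ~off | ((mixed > DISTANCE_LO) & (mixed < DISTANCE_HI))
    pred = PredictedDistanceMatrix(lib.residue_ids, values, mask)
    truth = SyntheticTruth(
        config={"noise_sd": noise_sd, "ligand_id": ligand_id},
        true_weights={ligand_id: {s: float(x) for s, x in zip(lib.states, w)}},
    )
    return pred, truth


def generate_ligand_panel(
    lib: StateLibrary,
    spec: PanelSpec,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, PredictedDistanceMatrix], SyntheticTruth]:
    """A panel of predicted matrices, one per ligand, with planted dominant states.

    Each ligand's true weights put ``dominance`` on its planted state and
    split the remainder evenly over the other states.
    """
    if spec.dominance <= 1.0 / lib.n_states:
        raise InputError("dominance must exceed 1/n_states to define a dominant state")
    for s in spec.dominant_states:
        if s not in lib.states:
            raise InputError(f"unknown dominant state {s!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(spec.dominant_states))
    panel: dict[str, PredictedDistanceMatrix] = {}
    truth = SyntheticTruth(config={"noise_sd": noise_sd, "seed": seed, **spec.model_dump()})
    rest = (1.0 - spec.dominance) / max(lib.n_states - 1, 1)
    for idx, (dom, child) in enumerate(zip(spec.dominant_states, children), start=1):
        w = np.full(lib.n_states, rest)
        w[lib.states.index(dom)] = spec.dominance
        lid = f"L{idx:02d}"
        pred, t = generate_predicted_matrix(
            lib, w, noise_sd, np.random.default_rng(child), lid
        )
        panel[lid] = pred
        truth.true_weights[lid] = t.true_weights[lid]
    return panel, truth


# ---------------------------------------------------------------------------
# screening libraries


def generate_screening_library(
    cfg: ScreeningConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """A synthetic screening table with planted passers and structured decoys.

    Returns ``(affinity, distances, activities, truth)``.  Planted passers
    predict strongly in every model and sit close to every functional
    residue.  Decoys are either mediocre everywhere or "single-model stars"
    — top-ranked in exactly one model, which exercises the conservative
    min-aggregate: stars pass the rank clause but are placed far from the
    functional residues, so the distance clause rejects them.
    """
    if cfg.n_passers + cfg.n_single_model_stars > cfg.n_compounds:
        raise InputError("more planted compounds than library size")
    rng = np.random.default_rng(cfg.seed)
    compounds = [f"C{i + 1:04d}" for i in range(cfg.n_compounds)]
    if cfg.n_models == 11:
        models = ["base"] + [f"FT{i}" for i in range(1, 11)]
    else:
        models = [f"M{i + 1}" for i in range(cfg.n_models)]

    passers = compounds[: cfg.n_passers]
    stars = compounds[cfg.n_passers: cfg.n_passers + cfg.n_single_model_stars]

    aff = rng.normal(loc=5.5, scale=0.8, size=(cfg.n_compounds, cfg.n_models))
    # every mediocre decoy dips low in at least one model, so the conservative
    # min-aggregate rejects it
    dip_models = rng.integers(cfg.n_models, size=cfg.n_compounds)
    aff[np.arange(cfg.n_compounds), dip_models] = rng.normal(
        loc=3.5, scale=0.3, size=cfg.n_compounds
    )
    aff[: cfg.n_passers] = rng.normal(loc=9.0, scale=0.15,
                                      size=(cfg.n_passers, cfg.n_models))
    for k, _ in enumerate(stars):
        row = cfg.n_passers + k
        star_model = int(rng.integers(cfg.n_models))
        aff[row] = rng.normal(loc=5.0, scale=0.3, size=cfg.n_models)
        aff[row, star_model] = rng.normal(loc=9.6, scale=0.05)

    n_func = len(cfg.functional_residues)
    dist = rng.uniform(5.0, 35.0, size=(cfg.n_compounds, n_func))
    dist[: cfg.n_passers] = rng.uniform(2.5, 4.5, size=(cfg.n_passers, n_func))
    # any decoy potent enough to claim a top rank in some model is planted far
    # from the functional residues, so only the distance clause can reject it
    order = np.argsort(-aff, axis=0)
    top_rows = set(order[: _TOP_RANK_GUARD - 1].ravel().tolist())
    far_decoys = sorted(r for r in top_rows if r >= cfg.n_passers)
    far_decoys += [cfg.n_passers + k for k in range(len(stars))]
    if far_decoys:
        far_decoys = sorted(set(far_decoys))
        dist[far_decoys] = rng.uniform(30.0, 40.0, size=(len(far_decoys), n_func))

    affinity = pd.DataFrame(aff, index=compounds, columns=models)
    distances = pd.DataFrame(dist, index=compounds, columns=cfg.functional_residues)

    measures = rng.choice(["Kd", "Ki", "IC50"], size=cfg.n_compounds)
    potency_m = np.where(
        np.arange(cfg.n_compounds) < cfg.n_passers,
        10 ** rng.uniform(-9.0, -7.0, size=cfg.n_compounds),  # nM-range actives
        10 ** rng.uniform(-6.5, -4.0, size=cfg.n_compounds),
    )
    activities = pd.DataFrame(
        {"compound": compounds, "measure": measures, "value_molar": potency_m}
    ).set_index("compound")

    truth = SyntheticTruth(config=cfg.model_dump(), planted_passers=list(passers))
    return affinity, distances, activities, truth


# ---------------------------------------------------------------------------
# fixture PDB writing


def write_fixture_pdb(ensemble: StateEnsemble, path) -> None:
    """Write a minimal multi-model PDB file of representative atoms.

    Non-glycine residues get a CB atom, glycine a CA atom — exactly what the
    parser reads back, so synthetic ensembles round-trip through the PDB path
    (to the format's 0.001 Å precision).
    """
    lines = []
    for m, conf in enumerate(ensemble.conformers, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for (chain, num, resname), xyz in zip(conf.residue_ids, conf.coords):
            atom = "CA" if resname == "GLY" else "CB"
            lines.append(
                f"ATOM  {serial:5d} {atom:^4s}{resname:>4s} {chain[:1]}{num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom[0]:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
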