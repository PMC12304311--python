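"""Multi-model structural ensembles and inter-residue distance matrices.

A conformational state of a protein (e.g. the active and inactive states of
a kinase, deposited as multi-model NMR ensembles) is represented as a
:class:`StateEnsemble` of conformers.  Each conformer keeps one
representative-atom coordinate per residue — the Cβ atom, or Cα for glycine,
the convention used for side-chain-aware residue–residue distances.  The
per-state average distance matrix over conformers is the object downstream
population reweighting consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InputError

logger = logging.getLogger(__name__)

#: (chain id, author residue number, residue name)
ResidueId = tuple[str, int, str]


def _as_residue_ids(ids: Iterable) -> tuple[ResidueId, ...]:
    out = []
    for r in ids:
        chain, num, name = r
        out.append((str(chain), int(num), str(name)))
    return tuple(out)


@dataclass(frozen=True)
class Conformer:
    """One model of a multi-model structure, reduced to representative atoms."""

    residue_ids: tuple[ResidueId, ...]
    coords: np.ndarray  # (n_res, 3), Å

    def __post_init__(self):
        object.__setattr__(self, "residue_ids", _as_residue_ids(self.residue_ids))
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] != len(self.residue_ids):
            raise InputError("one coordinate required per residue")
        if not np.all(np.isfinite(coords)):
            raise InputError("non-finite coordinates")
        # residue numbers strictly increasing within each chain
        seen_chain_last: dict[str, int] = {}
        for chain, num, _ in self.residue_ids:
            if chain in seen_chain_last and num <= seen_chain_last[chain]:
                raise InputError(
                    f"residue ids not strictly ordered within chain {chain!r} at {num}"
                )
            seen_chain_last[chain] = num
        object.__setattr__(self, "coords", coords)

    @property
    def n_res(self) -> int:
        return len(self.residue_ids)


@dataclass(frozen=True)
class StateEnsemble:
    """A cloud of conformers belonging to one conformational state."""

    state_label: str
    conformers: tuple[Conformer, ...]

    def __post_init__(self):
        conformers = tuple(self.conformers)
        if not conformers:
            raise InputError("ensemble must contain at least one conformer")
        ref = conformers[0].residue_ids
        for k, c in enumerate(conformers[1:], start=2):
            if c.residue_ids != ref:
                raise InputError(
                    f"conformer {k} of state {self.state_label!r} has a "
                    "different residue set from conformer 1"
                )
        object.__setattr__(self, "conformers", conformers)

    @property
    def n_conf(self) -> int:
        return len(self.conformers)

    @property
    def residue_ids(self) -> tuple[ResidueId, ...]:
        return self.conformers[0].residue_ids


@dataclass
class DistanceMatrix:
    """Symmetric residue–residue distance matrix in Å with a validity mask."""

    residue_ids: tuple[ResidueId, ...]
    values: np.ndarray
    mask: np.ndarray = None  # True = valid

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
        m = self.mask
        if not np.allclose(v[m & m.T], v.T[m & m.T], atol=1e-8):
            raise InputError("distance matrix is not symmetric")
        if not np.all(np.isfinite(v[m])):
            raise InputError("non-finite unmasked distances")
        self.values = v

    @property
    def n_res(self) -> int:
        return len(self.residue_ids)

    def index_of(self, key) -> int:
        """Map a residue id (index, (chain, num) or (chain, num, name)) to a row index."""
        return _resolve_residue(self.residue_ids, key)

    # ---- serialization -------------------------------------------------

    def to_tsv(self, path) -> None:
        headers = [f"{c}:{n}" for c, n, _ in self.residue_ids]
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(headers) + "\n")
            for h, row in zip(headers, self.values):
                fh.write(h + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        ids = []
        for h in header:
            chain, num = h.rsplit(":", 1)
            ids.append((chain, int(num), "UNK"))
        values = np.array([[float(x) for x in r[1:]] for r in rows])
        return cls(tuple(ids), values)

    def save(self, stem) -> None:
        """Compact binary container: <stem>.npy plus a JSON sidecar."""
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.values)
        sidecar = {
            "residue_ids": [list(r) for r in self.residue_ids],
            "units": "angstrom",
            "mask_true_fraction": float(self.mask.mean()),
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class StateLibrary:
    """Per-state average distance matrices sharing one residue index."""

    states: tuple[str, ...]
    matrices: tuple[DistanceMatrix, ...]

    def __post_init__(self):
        self.states = tuple(self.states)
        self.matrices = tuple(self.matrices)
        if len(self.states) != len(self.matrices):
            raise InputError("one matrix required per state")
        if len(set(self.states)) != len(self.states):
            raise InputError("state labels must be unique")
        if not self.states:
            raise InputError("library must contain at least one state")
        ref = self.matrices[0].residue_ids
        for s, m in zip(self.states, self.matrices):
            if m.residue_ids != ref:
                raise InputError(f"state {s!r} matrix has a different residue index")

    @property
    def residue_ids(self) -> tuple[ResidueId, ...]:
        return self.matrices[0].residue_ids

    @property
    def n_states(self) -> int:
        return len(self.states)

    def matrix(self, state: str) -> DistanceMatrix:
        return self.matrices[self.states.index(state)]

    def stack(self) -> np.ndarray:
        """(n_states, n_res, n_res) array of the state matrices."""
        return np.stack([m.values for m in self.matrices])


def _resolve_residue(ids: Sequence[ResidueId], key) -> int:
    if isinstance(key, (int, np.integer)):
        k = int(key)
        if not 0 <= k < len(ids):
            raise InputError(f"residue index {k} out of range 0..{len(ids) - 1}")
        return k
    key = tuple(key)
    for idx, r in enumerate(ids):
        if r == key or r[:2] == key:
            return idx
    raise InputError(f"unknown residue id {key!r}")


# ---------------------------------------------------------------------------
# parsing


def _representative_atom_name(resname: str) -> str:
    return "CA" if resname == "GLY" else "CB"


def parse_multimodel_structure(
    text: str,
    chains: Sequence[str] | None = None,
    state_label: str = "state",
) -> StateEnsemble:
    """Parse a (possibly multi-model) PDB record into a :class:`StateEnsemble`.

    One conformer is produced per MODEL block (a file with no MODEL records is
    a single implicit model).  The representative atom is Cβ for non-glycine
    residues and Cα for glycine; where several altlocs exist the
    highest-occupancy one wins, ties broken by altloc identifier.  Residues
    lacking their representative atom in any model are dropped from every
    model (and logged), so all conformers share one residue index.
    """
    import gemmi

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"malformed PDB record: {exc}") from exc
    if len(st) == 0:
        raise InputError("no models found in structure")

    if chains is None:
        chains = [_first_protein_chain(st[0])]
    chains = list(chains)

    per_model: list[dict[ResidueId, np.ndarray]] = []
    residue_order: list[ResidueId] = []
    missing: set[ResidueId] = set()
    for model in st:
        seen: dict[ResidueId, np.ndarray] = {}
        for chain_name in chains:
            chain = model.find_chain(chain_name)
            if chain is None:
                raise InputError(f"chain {chain_name!r} absent from model {model.num}")
            for res in chain:
                if not _is_amino_acid(res):
                    continue
                rid: ResidueId = (chain_name, res.seqid.num, res.name)
                if rid not in residue_order and len(per_model) == 0:
                    residue_order.append(rid)
                atom = _pick_representative(res)
                if atom is None:
                    missing.add(rid)
                else:
                    seen[rid] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        per_model.append(seen)

    # a residue dropped anywhere is dropped everywhere
    for seen in per_model:
        for rid in residue_order:
            if rid not in seen:
                missing.add(rid)
    kept = [rid for rid in residue_order if rid not in missing]
    if missing:
        logger.info(
            "dropped %d residue(s) lacking a representative atom: %s",
            len(missing),
            ", ".join(f"{c}:{n}:{r}" for c, n, r in sorted(missing)),
        )
    if not kept:
        raise InputError("no usable residues after representative-atom filtering")

    # residues present in later models but never in model 1 mean the models
    # genuinely disagree on the residue set
    extra = set().union(*(set(m) for m in per_model)) - set(residue_order)
    if extra:
        raise InputError(
            "models have inconsistent residue sets: "
            + ", ".join(f"{c}:{n}:{r}" for c, n, r in sorted(extra))
        )

    conformers = [
        Conformer(tuple(kept), np.array([seen[rid] for rid in kept]))
        for seen in per_model
    ]
    return StateEnsemble(state_label, tuple(conformers))


def _first_protein_chain(model) -> str:
    for chain in model:
        if any(_is_amino_acid(res) for res in chain):
            return chain.name
    raise InputError("no protein chain found")


def _is_amino_acid(res) -> bool:
    import gemmi

    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue name: treat as amino acid when a CA backbone atom exists
    return info is None and any(a.name == "CA" for a in res)


def _pick_representative(res):
    name = _representative_atom_name(res.name)
    candidates = [a for a in res if a.name == name]
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.occ, a.altloc))


# ---------------------------------------------------------------------------
# distance matrices


def conformer_distance_matrix(c: Conformer) -> DistanceMatrix:
    """Euclidean representative-atom distances for one conformer."""
    values = squareform(pdist(c.coords))
    return DistanceMatrix(c.residue_ids, values)


def average_distance_matrix(e: StateEnsemble) -> DistanceMatrix:
    """Elementwise mean of the per-conformer distance matrices of a state."""
    stack = np.stack([conformer_distance_matrix(c).values for c in e.conformers])
    return DistanceMatrix(e.residue_ids, stack.mean(axis=0))


def difference_distance_matrix(a: DistanceMatrix, b: DistanceMatrix) -> np.ndarray:
    """Signed elementwise difference a − b (Å); antisymmetric in its arguments."""
    if a.residue_ids != b.residue_ids:
        sa, sb = set(a.residue_ids), set(b.residue_ids)
        unmatched = sorted(sa.symmetric_difference(sb))
        raise InputError(
            "residue index mismatch; unmatched residues: "
            + ", ".join(f"{c}:{n}:{r}" for c, n, r in unmatched)
        )
    return a.values - b.values


def pair_distance_samples(e: StateEnsemble, i, j) -> np.ndarray:
    """Per-conformer representative-atom distances for one residue pair."""
    ii = _resolve_residue(e.residue_ids, i)
    jj = _resolve_residue(e.residue_ids, j)
    if ii == jj:
        raise InputError("residue pair must be two distinct residues")
    return np.array(
        [float(np.linalg.norm(c.coords[ii] - c.coords[jj])) for c in e.conformers]
    )


def build_state_library(ensembles: Sequence[StateEnsemble]) -> StateLibrary:
    """Average each state ensemble into its library matrix."""
    return StateLibrary(
        tuple(e.state_label for e in ensembles),
        tuple(average_distance_matrix(e) for e in ensembles),
    )
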