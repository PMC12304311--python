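"""Virtual-screening triage: activity harmonization, curation, consensus scoring.

Implements the multi-model candidate-selection strategy used for nominating
kinase inhibitors: activity labels (Kd/Ki/IC50) are harmonized onto a common
pKd-equivalent scale; per-model predicted affinities are normalized to [0, 1]
and aggregated conservatively as the per-compound minimum across models (the
overall affinity score); ligand-to-functional-residue distances are
normalized into distance scores (0 = closest); and a compound is selected
when it scores high by consensus (overall score above threshold, or a
top rank in any single model) while binding near every functional residue
(all distance scores below threshold).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import InputError

#: pIC50 → pKd-equivalent offset in log10 units (IC50 values divided by ~2.3)
IC50_PKD_OFFSET = 0.35

#: Curation limits for protein-ligand complex datasets
MAX_PROTEIN_RESIDUES = 384
MAX_LIGAND_ATOMS = 128

#: Distance-label truncation range (Å)
DISTANCE_LO = 1.0
DISTANCE_HI = 20.0


class Measure(str, Enum):
    KD = "Kd"
    KI = "Ki"
    IC50 = "IC50"


@dataclass(frozen=True)
class ActivityRecord:
    """One harmonized activity measurement (concentrations in molar units)."""

    compound_id: str
    measure: Measure
    value: float  # molar
    p_value: float  # −log10(value)
    harmonized_pkd: float  # pKd equivalent


def harmonize_activity(measure, value, compound_id: str = "") -> ActivityRecord:
    """Convert a Kd/Ki/IC50 measurement (molar) to a pKd-equivalent record.

    pIC50 values are shifted by +0.35 log units; Kd and Ki are used without
    distinction.  Passing an already-harmonized record is rejected.
    """
    if isinstance(value, ActivityRecord):
        raise InputError("value is already a harmonized ActivityRecord")
    try:
        measure = Measure(measure)
    except ValueError:
        raise InputError(f"unknown measure {measure!r}; expected Kd, Ki or IC50")
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InputError(f"activity value must be positive and finite (molar), got {value}")
    p = -math.log10(value)
    harmonized = p + IC50_PKD_OFFSET if measure is Measure.IC50 else p
    return ActivityRecord(compound_id, measure, value, p, harmonized)


def truncate_distance_label(d):
    """Clamp distance labels (Å) to the prediction range [1, 20] Å."""
    arr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("non-finite distance label")
    clamped = np.clip(arr, DISTANCE_LO, DISTANCE_HI)
    return float(clamped) if np.isscalar(d) or arr.ndim == 0 else clamped


# ---------------------------------------------------------------------------
# dataset curation


@dataclass(frozen=True)
class ComplexRecord:
    complex_id: str
    n_residues: int
    n_ligand_atoms: int
    n_ligands: int
    parseable: bool = True


def curate_complexes(
    records: Sequence[ComplexRecord],
) -> tuple[list[ComplexRecord], dict[str, list[str]]]:
    """Filter complex records by the training-set curation rules.

    Kept: exactly one parseable ligand, ≤128 ligand atoms, ≤384 protein
    residues (bounds inclusive).  Returns (kept, reasons) where ``reasons``
    maps each dropped complex id to every clause it failed.
    """
    kept, reasons = [], {}
    for rec in records:
        why = []
        if not rec.parseable:
            why.append("ligand not parseable")
        if rec.n_ligands != 1:
            why.append(f"{rec.n_ligands} ligands (exactly 1 required)")
        if rec.n_ligand_atoms > MAX_LIGAND_ATOMS:
            why.append(f"{rec.n_ligand_atoms} ligand atoms > {MAX_LIGAND_ATOMS}")
        if rec.n_residues > MAX_PROTEIN_RESIDUES:
            why.append(f"{rec.n_residues} residues > {MAX_PROTEIN_RESIDUES}")
        if why:
            reasons[rec.complex_id] = why
        else:
            kept.append(rec)
    return kept, reasons


# ---------------------------------------------------------------------------
# consensus scoring


def _minmax_columns(df: pd.DataFrame, invert: bool) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        x = df[col].astype(float)
        lo, hi = x.min(), x.max()
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise InputError(f"column {col!r} has no finite values")
        if hi - lo <= 0:
            warnings.warn(
                f"column {col!r} is constant; normalized to 0.5", stacklevel=3
            )
            out[col] = np.where(x.notna(), 0.5, np.nan)
        else:
            scaled = (x - lo) / (hi - lo)
            out[col] = 1.0 - scaled if invert else scaled
    return out


def normalize_model_scores(affinity: pd.DataFrame) -> pd.DataFrame:
    """Per-model min–max scaling of predicted affinities to [0, 1].

    Higher normalized value = stronger predicted binding.  Constant columns
    map to 0.5 with a warning; missing entries stay missing.
    """
    if affinity.empty:
        raise InputError("empty affinity table")
    return _minmax_columns(affinity, invert=False)


def overall_affinity_score(normalized: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-compound minimum of normalized scores across models.

    Returns ``(score, eligible)``; a compound with any missing model
    prediction is flagged ineligible (its min would be unreliable).
    """
    eligible = normalized.notna().all(axis=1)
    score = normalized.min(axis=1)
    score[~eligible] = np.nan
    return score, eligible


def model_ranks(affinity: pd.DataFrame) -> pd.DataFrame:
    """1-based competition rank within each model column (1 = strongest).

    Ties share the better rank: a column [8, 6, 8] ranks [1, 3, 1].
    """
    if affinity.empty:
        raise InputError("empty affinity table")
    return affinity.rank(axis=0, method="min", ascending=False)


def distance_scores(
    distances: pd.DataFrame,
    functional_residues: Sequence[str],
    per_residue: bool = True,
) -> pd.DataFrame:
    """Min–max normalized ligand-to-residue distances (0 = closest).

    Normalization is per functional residue by default; ``per_residue=False``
    pools the three columns and scales them on a common range.
    """
    missing = [r for r in functional_residues if r not in distances.columns]
    if missing:
        raise InputError(f"missing functional-residue columns: {missing}")
    sub = distances[list(functional_residues)].astype(float)
    if (sub < 0).any().any():
        raise InputError("negative ligand-residue distance")
    if per_residue:
        return _minmax_columns(sub, invert=False)
    lo, hi = sub.min().min(), sub.max().max()
    if hi - lo <= 0:
        warnings.warn("distance table is constant; normalized to 0.5", stacklevel=2)
        return sub * 0 + 0.5
    return (sub - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# selection


class SelectionCriteria(BaseModel):
    """Candidate-selection thresholds (defaults mirror the screening strategy)."""

    model_config = ConfigDict(extra="forbid")

    overall_score_min: float = Field(default=0.3, ge=0.0, le=1.0)
    rank_cutoff: int = Field(default=10, ge=1)
    distance_score_max: float = Field(default=0.5, ge=0.0, le=1.0)
    functional_residues: list[str] = Field(default_factory=lambda: ["K745", "E762", "D855"])


@dataclass
class CandidateSet:
    selected: list[str]
    rationale: dict[str, dict]
    criteria: SelectionCriteria

    def to_json(self, path=None):
        payload = {
            "selected": self.selected,
            "rationale": self.rationale,
            "criteria": self.criteria.model_dump(),
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def select_candidates(
    overall: pd.Series,
    eligible: pd.Series,
    ranks: pd.DataFrame,
    dist_scores: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> CandidateSet:
    """Apply the selection rule and record a per-candidate rationale.

    Selected iff (overall score > overall_score_min OR any model rank <
    rank_cutoff) AND every distance score < distance_score_max.  Compounds
    flagged ineligible or with missing distances are never selected.
    """
    idx = overall.index
    for other in (eligible.index, ranks.index, dist_scores.index):
        if not idx.equals(other):
            raise InputError("score/rank/distance tables have inconsistent compound indices")
    selected, rationale = [], {}
    for cid in idx:
        if not bool(eligible[cid]):
            continue
        row_ranks = ranks.loc[cid]
        row_d = dist_scores.loc[cid]
        if row_d.isna().any():
            continue
        score_clause = float(overall[cid]) > criteria.overall_score_min
        best_rank = float(row_ranks.min())
        rank_clause = bool((row_ranks < criteria.rank_cutoff).any())
        distance_clause = bool((row_d < criteria.distance_score_max).all())
        if (score_clause or rank_clause) and distance_clause:
            selected.append(str(cid))
            rationale[str(cid)] = {
                "overall_score": float(overall[cid]),
                "best_rank": best_rank,
                "clause": "overall_score" if score_clause else "model_rank",
                "distance_scores": {str(k): float(v) for k, v in row_d.items()},
            }
    return CandidateSet(selected, rationale, criteria)


def screen(
    affinity: pd.DataFrame,
    distances: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[CandidateSet, pd.DataFrame]:
    """Full triage: normalize → score → rank → select.

    Returns the candidate set and a per-compound summary table (overall
    score, best rank, per-residue distance scores, selected flag).
    """
    normalized = normalize_model_scores(affinity)
    overall, eligible = overall_affinity_score(normalized)
    ranks = model_ranks(affinity)
    dscores = distance_scores(distances, criteria.functional_residues)
    cands = select_candidates(overall, eligible, ranks, dscores, criteria)
    summary = pd.DataFrame(
        {
            "overall_score": overall,
            "eligible": eligible,
            "best_rank": ranks.min(axis=1),
        }
    )
    for r in criteria.functional_residues:
        summary[f"dist_score_{r}"] = dscores[r]
    summary["selected"] = summary.index.astype(str).isin(set(cands.selected))
    return cands, summary
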