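# Methods

## Model

A protein with K reference conformational states is summarised by per-state
average distance matrices d^s (s = 1..K), each the elementwise mean of the
representative-atom distance matrices of that state's N_conf conformers.
The representative atom is Cβ for non-glycine residues and Cα for glycine;
this keeps the matrix side-chain-aware while remaining defined for every
residue type.  A predicted distance matrix d̂ for a ligand-bound ensemble is
modelled as a convex mixture Σ_s w_s d^s plus prediction error, and the
populations w are the solution of

    min_w  MSE(w) = (1/N) Σ_(i,j) ( Σ_s w_s d^s_ij − d̂_ij )²
    s.t.   0 ≤ w_s ≤ 1,  Σ_s w_s = 1

where the sum runs over all ordered unmasked residue pairs including the
(identically zero) diagonal and N is the number of pairs actually summed —
so the normalizer matches the full-N² convention when nothing is masked and
stays an honest mean under masking.  The mixture-of-averages model discards
within-state heterogeneity by design: the K state means, not the K·N_conf
conformers, are the basis.

The bounds are implemented as the closed interval [0, 1] with interior
starting points.  Open bounds (0 < w < 1) have no attained minimum when the
truth sits at a vertex; closed bounds make vertex recovery representable
while interior multistart keeps the solver away from spurious boundary
stalls.

## Optimisation

MSE(w) is an explicit quadratic, MSE(w) = wᵀAw − 2bᵀw + c with
A_st = (1/N)Σ d^s d^t and b_s = (1/N)Σ d^s d̂, so the solver (SLSQP) is run
with the analytic gradient 2(Aw − b), equality constraint Σw = 1, tolerance
1e-10 and at most 500 iterations.  Multistart uses 1 + K points: the uniform
weight and, per state, a vertex-biased interior point (0.85 on that state,
the remainder split evenly).  The best iterate across restarts is reported;
`converged` is false only if every restart fails, in which case the best
iterate is still returned with a warning.  Tiny negative weights from
floating-point round-off are clipped and renormalised.

An exhaustive simplex-grid search over {w : w_s = k_s · step, Σ w_s = 1}
serves as an independent oracle: for steps of 0.05 and 0.01 the solver
objective is never worse than the lattice optimum (up to 1e-9).  When the
prediction and library residue indices differ, the fit uses their
intersection and reports the coverage fraction; fits below 50 % coverage are
refused, since a silently partial overlap corrupts the populations.

## State discrimination

Per residue pair, a one-way ANOVA across the K states treats the N_conf
conformers per state as independent samples (matching the n = 20-per-state
convention of the source ensembles) and reports the F statistic and its
unadjusted p value; no multiple-comparison correction is applied, which is a
deliberate property of the analysis, not an omission.  Zero-total-variance
pairs are degenerate (F = 0, p = 1, flagged); zero within-group variance
with nonzero between-group variance yields F = ∞, p = 0 (it cannot occur
with positive conformer jitter).  Top discriminative pairs are ranked by F
descending with lexicographic (i, j) tie-breaks.

Distance distributions use half-open bins [lo + k·w, lo + (k+1)·w), last bin
closed, default width 0.19 Å over [1, 20] Å (100 bins); samples are clamped
to the range before binning.  Distributions supplied on a different native
grid (e.g. 0.3 Å apo bins) are resampled by mass-conserving bin overlap onto
the requested edges.  Summary moments are computed over bin centers weighted
by bin mass; the mean is exact under bin refinement while the sd carries a
discretisation term bounded by width²/16 in variance — a property of the
center-weighted definition, accepted for comparability with the binned
display convention.  KDE curves use a Gaussian kernel with Scott's-rule
bandwidth on a 512-point grid spanning the data range ± 3 bandwidths (the
source analysis names KDE but no bandwidth; Scott's rule is the standard
default).

## Screening triage

Activity records in molar units are harmonized as p-values (−log₁₀):
pKd and pKi are used without distinction, and pIC₅₀ values receive a fixed
+0.35 log-unit offset to approximate pKd equivalents.  (The offset is stated
both as "divide IC₅₀ by 2.3" and as "+0.35 log units" in the literature this
follows; log₁₀ 2.3 ≈ 0.362, and exactly 0.35 is what is applied here.)
Distance labels are truncated to [1, 20] Å, the prediction range.  Complex
curation keeps records with exactly one parseable ligand, ≤ 128 ligand atoms
and ≤ 384 protein residues, bounds inclusive, logging every drop reason.

Predicted affinities are normalized per model by min–max over the screened
library (higher = stronger; a constant column maps to 0.5 with a warning —
it carries no ranking information).  The *overall affinity score* is the
per-compound minimum of the normalized scores across all models: a
conservative consensus that a single over-optimistic model cannot inflate.
Compounds with any missing model prediction are ineligible rather than
imputed.  Per-model ranks are 1-based competition ranks (ties share the
better rank).  Distance scores are min–max normalized per functional residue
(0 = closest; a global-range option exists).  Selection:

    (overall score > 0.3  OR  any model rank < 10)  AND  all distance scores < 0.5

with "rank < 10" read literally as ranks 1–9.  All thresholds are explicit
`SelectionCriteria` fields echoed into every run.  Note that min–max scores
are *relative to the screened library*: in a pathological library whose
compounds all sit equally close to the target site, the normalization
stretches negligible spread to [0, 1] and the distance clause loses meaning.
Real libraries (and the synthetic ones here) contain far-binding compounds
that anchor the scale.

## Synthetic data

Generation is geometry-first: a self-avoiding 3D bead chain (3.8 Å bonds,
3 Å exclusion — Cα-like spacing) is built per library; each state beyond the
first rigidly displaces one planted contiguous block (one fifth of the
chain) by the inter-state displacement along a state-specific direction, and
conformers add isotropic Gaussian jitter.  Because matrices derive from
coordinates, every synthetic distance matrix is exactly metric — direct
matrix perturbation could violate the triangle inequality.  Predicted
matrices are mixtures of the state means plus symmetrized Gaussian noise
(the emulated model predicts matrices, not coordinates), truncated to
[1, 20] Å.  Entries clamped by the truncation are *censored*: they are
masked out of the reweighting objective, since a clamped value carries no
mixture information — a synthetic chain, like a real kinase domain, has many
pairs beyond 20 Å, and keeping their clamped values would bias the fit.

Defaults mirror the study conditions this pipeline is built for: 3 states ×
20 conformers, 150 residues, 8 Å inter-state displacement, 0.3 Å conformer
jitter, 0.2 Å prediction noise; panels of 12 ligands grouped 6/2/4 over the
states with dominant weight 0.7; screening libraries of 200 compounds × 11
models with 12 planted passers.  Screening decoys are either mediocre (each
with at least one clearly weak model prediction, so the min-aggregate
rejects them) or "single-model stars" — top-ranked in exactly one model but
planted far from the functional residues, exercising the rank clause against
the distance clause.  Any decoy that claims a top-9 rank is planted far
(the potent-looking but mis-placed archetype); the exact-recovery guarantee
(selected = planted passers) additionally relies on the number of passers
being at least the rank cutoff, as in the defaults.

What the generator does *not* emulate: real backbone geometry and secondary
structure, correlated (non-isotropic) conformer fluctuations, systematic
(non-Gaussian) prediction error, and any chemistry of the ligands.  Passing
recovery tests therefore demonstrates the estimator's correctness and noise
robustness under the mixture model, not the accuracy of any real distance
predictor.

## Numerical choices and limitations

- Altloc handling during parsing: highest occupancy wins, ties by altloc
  identifier — deterministic.  Residues missing their representative atom in
  any model are dropped from every model and logged; numbering is never
  rewritten (author chain + residue numbers are the public identity).
- Predominant-state ties (weight gap < 1e-6) are flagged ambiguous and
  resolved by state order, deterministically.
- All generators are pure functions of their configuration including the
  seed; panel ligands draw from independently spawned child seed sequences,
  so partial reruns reproduce exactly.
- Problem sizes used in the test suite (40–150 residues, 20 conformers,
  50-trial noise studies, 200-compound screens) were chosen as the smallest
  sizes at which the statistical properties under test are stable; the whole
  suite runs in seconds.
- The reweighting basis is limited to the K state averages; ensembles whose
  true mixture lies outside the simplex spanned by those averages (e.g. a
  genuinely novel conformation) will be projected onto it, with the residual
  MSE as the only diagnostic.
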