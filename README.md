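# statepop

Population analysis of protein conformational states from predicted
inter-residue distance matrices, with a multi-model virtual-screening triage.

Kinases such as ABL interconvert between an active state (A) and distinct
inactive states (I₁, I₂), each deposited as a multi-model structural
ensemble.  Deep models that predict a residue–residue distance matrix for a
ligand-bound complex implicitly describe a *mixture* of these states.
`statepop` turns that observation into a quantitative pipeline:

1. **State libraries** — multi-model PDB ensembles are reduced to
   representative-atom coordinates (Cβ, or Cα for glycine) and averaged into
   per-state distance matrices d^s (one matrix per state, mean over the
   N_conf conformers).
2. **Population reweighting** — given a predicted matrix d̂, the state
   populations w = (w^A, w^I₁, w^I₂) are estimated by constrained least
   squares over the probability simplex:

   min over w of MSE(w) = (1/N) Σ_(i,j) ( Σ_s w_s d^s_ij − d̂_ij )²,
   subject to 0 ≤ w_s ≤ 1 and Σ_s w_s = 1,

   solved with SLSQP from an analytic gradient and multiple starts, with an
   exhaustive simplex-grid search as an independent oracle.  The state with
   the largest fitted weight is the *predominant state*; differences against
   an apo baseline give per-state population shifts.
3. **State statistics** — per-residue-pair one-way ANOVA F-maps across state
   ensembles (no multiple-comparison adjustment), discriminative-pair
   ranking, difference distance matrices, and distance distributions (KDE
   for measured ensembles; 0.19 Å-binned probability bars for predictions)
   with mean ± sd summaries and nearest-state calls for indicator pairs such
   as the αC-helix in/out distance.
4. **Screening triage** — activity harmonization (pIC₅₀ + 0.35 → pKd
   equivalent; Kd/Ki used without distinction), distance-label truncation to
   [1, 20] Å, complex-curation filters (single ligand, ≤128 ligand atoms,
   ≤384 residues), per-model min–max affinity normalization, the
   conservative *overall affinity score* (per-compound minimum across all
   models), per-model ranks, distance scores to functional residues, and the
   selection rule: (overall score > 0.3 **or** any model rank < 10) **and**
   all distance scores < 0.5.
5. **Synthetic data** — every input above can be generated with known ground
   truth (planted mixture weights, displaced residue blocks, planted
   screening passers), so parameter recovery and selection logic are
   testable without trained model weights or downloads.

## Worked example

Simulate a 3-state × 20-conformer synthetic system with a 12-ligand panel
(dominant weight 0.7, prediction noise 0.2 Å) and recover the populations:

```sh
statepop simulate --out demo/sim --seed 11
statepop reweight --library demo/sim \
    --prediction demo/sim/pred_L01.tsv --prediction demo/sim/pred_L07.tsv \
    --prediction demo/sim/pred_L09.tsv \
    --truth demo/sim/panel_truth.json --out demo/rw
statepop report --run demo/rw
```

prints

```
ligand      w_A     w_I1     w_I2      mse  coverage  converged predominant   margin  ambiguous planted  recovered
   L01 0.699545 0.150949 0.149506 0.019272       1.0       True           A 0.548595      False       A       True
   L07 0.151927 0.696063 0.152010 0.019041       1.0       True          I1 0.544052      False      I1       True
   L09 0.149085 0.151499 0.699416 0.019682       1.0       True          I2 0.547917      False      I2       True
recovered predominant state: 3/3
```

Each row is one ligand: the fitted simplex weights (here recovering the
planted 0.70/0.15/0.15 mixtures to ~0.005), the residual MSE in Å², the
fraction of library residues covered by the prediction, and the
predominant-state call with its margin over the runner-up.  The screening
stage works the same way:

```sh
statepop screen --affinity demo/sim/affinity.csv \
    --distances demo/sim/distances.csv --out demo/screen
# -> selected 12 / 200 compounds  (exactly the planted passers)
```

The same functionality is available as a library (`import statepop`); see
`docs/methods.md` for the model, parameter and normalization details.

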