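# exodep

Differential expression for label-free spectral-count proteomics: the
complete analysis chain used to compare two small groups of samples —
for example exosome proteomes harvested from treated versus control
tissue — from a peptide-evidence export down to significance calls,
set partitions and enrichment.

## Who this is for

Spectral counting is still a common quantification strategy when a
study has few samples and proteins are identified by a search engine
plus Scaffold-style validation. `exodep` packages that workflow as a
tested library and CLI:

1. **Evidence filtering** — retain peptide-spectrum records with
   peptide length > 5 residues, no singly-charged (MH+1) precursors,
   peptide probability > 0.80; retain proteins with ≥ 2 distinct
   peptides, protein probability > 0.99 and protein FDR < 0.01; tally
   retained records into a protein × sample count matrix.
2. **Normalization** — normalized spectral counts (N-SC): each sample
   column scaled to the mean library size, preserving the grand total.
3. **Differential testing** — for each protein with group means μ₁, μ₂
   and sample SDs δ₁, δ₂ of N-SC:
   * SAM-style weight **W = (μ₁ − μ₂)/(δ₁ − δ₂)** (a sum-denominator
     variant is available, see `docs/methods.md`);
   * one-tailed Welch *t*-test *p* (unequal variances,
     Welch–Satterthwaite df, tail in the direction of the observed
     difference);
   * signed fold change **FC** = μ₁/μ₂, reported as −μ₂/μ₁ when the
     ratio is below 1 so |FC| ≥ 1 and depletion is negative.

   A protein is significant only when **all three** tests pass:
   |W| > 0.8 **and** *p* < 0.05 **and** |FC| ≥ the fold-change
   threshold. Benjamini–Hochberg q-values are reported alongside.
4. **Fold-change calibration** — the FC threshold is chosen on
   [1.5, 2.0] empirically: split a group of replicates in half, compare
   mean N-SC on a ln–ln plot over the inner quartile by abundance, and
   take the smallest threshold covering ≥ 99 % of the ratios.
5. **Presence/absence partition** — proteins detected in only one group
   are classed group-unique (a Venn partition of the inventory) and
   bypass the gate.
6. **Enrichment** — one-sided hypergeometric over-representation of any
   query set against GMT annotations, BH-corrected.
7. **Reporting** — volcano table (log₂ FC vs −log₁₀ q), PCA sample
   scores (exact SVD of log₂(N-SC + 1)), average-linkage heatmap
   orderings.

A seeded synthetic-study generator (negative-binomial counts, planted
fold changes, structurally enforced group-unique proteins) makes the
whole pipeline runnable and testable without any external data, and
`evaluate_recovery` scores pipeline output against the generator's
ground truth.

## Worked example

```python
from exodep import SimulationConfig, simulate_counts, DifferentialSpectralCounts, evaluate_recovery

study = simulate_counts(SimulationConfig(seed=1))     # 506 proteins, 4 vs 7 samples
res = DifferentialSpectralCounts(study.counts).fit()  # statsmodels-style model/results
print(res.summary())
```

```
Differential spectral-count analysis (three-test conjunction)
==============================================================
proteins:   506    samples: 4 (A) vs 7 (B)
gate: |W| > 0.8  AND  one-tailed Welch p < 0.05  AND  |FC| >= 1.5
W variant: difference   pseudocount: 0.0
--------------------------------------------------------------
up:    40   down:    91   ns:   286   unique A:   48   unique B:   41
==============================================================
```

The default design carries 48 proteins unique to group A and 41 unique
to group B; both are recovered exactly (`res.venn()` gives 417 common /
48 / 41). `res.table` holds the per-protein statistics:

```
              mu_a   mu_b      w      p      q     fc  log2fc status
P00002       5.946  3.441 -3.015  0.046  0.147  1.728   0.789     up
P00053      11.968  4.603  2.182  0.026  0.109  2.600   1.379     up
P00056      15.513  5.332  2.108  0.032  0.117  2.910   1.541     up
```

Scoring the calls against the generator's truth:

```python
m = evaluate_recovery(study, res.table)
# TPR=0.591 FDR=0.328 venn_exact=True fc_rmse=0.892
```

At these realistic low spectral counts (median ≈ 4.5 per protein per
sample) the gate recovers 59 % of planted effects; with abundant
proteins (baseline ≥ 50 counts) power for |log₂FC| ≥ 1.5 exceeds 0.95
and the estimated log₂ FC regresses on truth with slope ≈ 1.00 (see
`scripts/acceptance.py` output).

The same pipeline runs from a shell:

```bash
exodep run --config demo.json          # simulate → … → report, with a manifest
exodep dep --counts counts.tsv --samples samples.tsv --out dep.tsv
```

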