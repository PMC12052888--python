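# Methods

This note documents the statistical procedure `exodep` implements, the
choices made where the workflow it reimplements is underspecified, and
what the synthetic benchmark does and does not demonstrate.

## The testing procedure

For each protein, on normalized spectral counts (N-SC), with group A of
size n₁ and group B of size n₂ (defaults 4 and 7):

* **Normalization.** N-SC is total-count scaling: column *j* is
  multiplied by (mean column total)/(total of column *j*). This is the
  common Scaffold-style between-sample normalization; it equalizes
  column totals and preserves the grand total. No length/NSAF or
  intensity normalization is attempted.
* **SAM-style weight.** W = (μ₁ − μ₂)/(δ₁ − δ₂) with μ the group means
  and δ the group sample SDs (n−1 denominator). The difference
  denominator is implemented as printed in the workflow this package
  follows, but it is non-standard and sign-unstable: when δ₁ ≈ δ₂ the
  weight explodes, and its sign carries no information about effect
  direction (the worked example in the README shows an upregulated
  protein with a negative W). The gate therefore uses only |W| > 0.8.
  A conventional sum denominator (δ₁ + δ₂), antisymmetric under group
  swap, is available via `GateThresholds(w_variant="sum")`. A
  denominator below 10⁻¹² in magnitude flags W as non-finite (with a
  warning) and the W gate fails for that protein. Neither variant is
  asserted as "the intended" statistic; the difference form is the
  default because it is the printed one.
* **Welch test.** t = (μ₁ − μ₂)/√(s₁²/n₁ + s₂²/n₂) with
  Welch–Satterthwaite degrees of freedom; p = P[T ≥ |t|], i.e. one
  tail in the direction of the observed difference, so p ≤ 0.5. Two
  constant, equal groups give t = 0 and p = 0.5 by convention; two
  constant, unequal groups give p = 0 (the infinite-separation limit).
  Note the family consequence: under the null, "p < 0.05 in the
  observed direction" admits 10 % of proteins across both directions —
  the conjunction with the W and FC gates reduces but need not halve
  this (see *Operating characteristics* below).
* **Fold change.** FC = μ₁/μ₂ reported as −μ₂/μ₁ when the ratio is
  below 1, so |FC| ≥ 1 and FC(A,B) = −FC(B,A). The default pseudocount
  is 0: proteins with a zero group mean are handled structurally as
  group-unique rather than numerically; a pseudocount of 0.5 is
  available for exploratory FC on sparse data.
* **Gate.** up ⇔ |W| > w_cut ∧ p < p_cut ∧ FC ≥ +fc_cut, down
  symmetrically; everything else is ns. Defaults w_cut = 0.8,
  p_cut = 0.05, fc_cut = 1.5 (the lower end of the calibratable band).
  Proteins detected in only one group (default detection rule: ≥ 1
  nonzero sample in that group, configurable) are classed
  unique_a/unique_b, bypass the gate, and are excluded from the BH
  family.
* **Multiplicity.** BH q-values are computed across the tested
  (non-unique) proteins and reported for the volcano display; the gate
  itself uses the raw p, matching the workflow reimplemented here. Both
  are in the output table.

## Fold-change calibration

The fc_cut is calibratable on [1.5, 2.0] from control (null)
comparisons: `split_control_pairs` halves one group's samples (seeded)
and averages N-SC per half; `calibrate_fc_threshold` takes the proteins
whose mean ln-abundance lies in the inner quartile [Q1, Q3]
("abundance" trim; a ratio-based trim is available), reports the
Pearson correlation of the (ln a, ln b) pairs, and returns the smallest
grid threshold t with ≥ 99 % of |ln(a/b)| ≤ ln t, clamping at 2.0 with
a warning when control noise exceeds the band. Zeros are excluded from
the ln-ln analysis and counted. Which samples form the control pair,
and whether the inner-quartile trim is by abundance or ratio, are not
recoverable from the source workflow; both choices here are explicit
and configurable.

## Synthetic studies

`simulate_counts` emulates the target study design: 506 proteins over
4 + 7 samples, 48 structurally unique to group A, 41 to group B, 79
planted up and 70 down (the printed inventory and call counts of the
emulated study). The noise model, which the source workflow does not
state, is the standard overdispersed-count choice:

* per-protein baseline means are log-normal, ln-mean 1.5 and ln-sd 1.0
  (median ≈ 4.5 spectra/protein/sample, i.e. ≈ 3,800 spectra per sample
  over 506 proteins — a realistic shallow spectral-counting depth with
  many 1–5-count proteins);
* counts are negative binomial with dispersion 0.1
  (variance m + 0.1 m²);
* per-sample library-size factors are log-normal with ln-sd 0.15,
  renormalized to mean 1;
* planted |log₂ FC| is uniform on [0.8, 2.0], applied multiplicatively
  to the group-A mean, so some effects straddle a 1.5-fold gate.

Presence classes are enforced structurally: group-unique proteins have
their other group's means set to zero, and any sampled row violating
its class (a "common" protein with an all-zero group, a unique protein
with no nonzero count) is redrawn from that protein's own spawned RNG
sub-stream, up to 100 attempts, then an error. This conditioning makes
the Venn partition of the output deterministic given the config and
slightly truncates the lowest-count tail of the null distribution;
it is the price of exact set-level assertions. All randomness derives
from `config.seed` through one `SeedSequence` (one study stream + one
sub-stream per protein), so identical configs give bit-identical
studies.

What the generator does **not** emulate: correlated proteins (complex
members co-varying), shared-peptide ambiguity, search-engine score
distributions, batch structure, or zero-inflation beyond NB sampling
zeros. Passing benchmarks here therefore demonstrates correctness of
the procedure and its operating characteristics under a clean
overdispersed count model, not performance on real acquisitions.

## Operating characteristics (computed by the test suite and script)

* **Venn recovery** is exact by construction: detection (≥ 1 nonzero
  sample) plus the partition recovers 417/48/41 on the default design
  at any seed.
* **Null false-positive rate.** Over 200 no-effect studies at the
  default (low-count) conditions the conjunction calls ≈ 8 % of null
  proteins up or down. This is below the directional t-test's 10 %
  family rate — the conjunction can only shrink it — but above 5 %:
  with medians of a few counts the |FC| ≥ 1.5 and |W| > 0.8 gates
  remove little of what the t-test admits. With abundant proteins
  (baselines ≥ 50 counts) the same gate measures ≈ 3.5 %. Users who
  need directional α = 0.05 should halve p_cut or gate on q.
* **Recovery.** At baselines ≥ 50 counts, estimated log₂ FC regresses
  on truth with slope 1.00 ± 0.02 and power for |log₂FC| ≥ 1.5 at
  n = 4 vs 7 exceeds 0.95.
* **Numeric agreement.** The Welch p matches an independent Welch-test
  implementation to < 10⁻¹⁰ over 1,000 random cases; hypergeometric
  enrichment p matches exact rational tail summation to < 10⁻¹²; PCA
  scores match a covariance eigendecomposition to < 10⁻⁸; average-
  linkage merge heights match an O(n³) re-agglomeration exactly.

## Numerical and degenerate-input conventions

* Strict inequalities as specified: peptide length > 5, probabilities
  > 0.80/> 0.99, FDR < 0.01, p < 0.05, |W| > 0.8; FC gates are
  inclusive (≥ fc_cut).
* Spectral count = number of retained peptide-spectrum records;
  distinct peptide sequences are used only for the ≥ 2-peptides rule
  (counted across the experiment by default, per-sample optionally).
* All-zero sample columns are an error at normalization, named by
  sample. Zero-variance rows z-score to 0 for euclidean heatmaps and
  are an error (named) under the correlation metric. PCA component
  signs are fixed by making each component's largest-magnitude loading
  positive. Hierarchical-clustering ties break toward lower original
  indices.
* The pipeline CLI validates fc_cut against [1.5, 2.0] and refuses
  out-of-band values without `--allow-nonpublished-thresholds`; exit codes
  distinguish invalid config (2), missing inputs (3) and stage errors
  (4).

## Known limitations

* The difference-denominator W is reported as printed; its sign is not
  interpretable and analyses should rely on FC for direction.
* Spectral counts below ~5 make FC and W extremely noisy; the gate's
  null behavior at such depths is the ≈ 8 % rate above.
* The over-representation step is database-agnostic: it tests whatever
  GMT it is given and makes no attempt to reproduce any specific GO or
  KEGG release, and no ontology propagation is performed.
* Problem sizes used by the test suite and acceptance script (200 null
  studies of 506 proteins; 5 recovery studies of 600 proteins; 1,000
  oracle cases) were chosen as the package's own benchmark scale; they
  complete in seconds on one CPU.
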