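# Methods

## The detection-score model

The package treats a miRNA microarray experiment as two coupled matrices
over the same miRNA × sample grid: log2 intensities ("detection levels")
and detection-above-background p-values. Binarization applies a strict
threshold, `present := p < α` with α = 0.05 by default; the boundary is
exclusive so that `p = α` is 'absent', and the α used is recorded in the
matrix provenance and in a JSON sidecar next to every written artifact.
Missing p-values are rejected rather than imputed: upstream array
pipelines emit a call for every probeset, and the synthetic generator
does too.

Everything downstream of binarization is set algebra over sample scopes.
For a scope S (a group, a compartment, a sex, or all samples):

- uniform-detection partition: miRNAs absent in every sample of S,
  present in every sample of S, and the variable remainder. The three
  blocks always partition the platform; enlarging S can only shrink the
  two uniform blocks.
- group-shared set: the uniformly-present block, i.e. detected in 100% of
  S. On a clustered detection map this is the small nested cluster of
  fully-colored rows; the algebraic definition is used for all statistics
  because it is deterministic and testable, while clustering serves only
  for visualization and row/column ordering.
- Venn decomposition between two shared sets A, B: (A\B, A∩B, B\A), with
  the conservation identities |A| = |A\B| + |A∩B| and |B| = |B\A| + |A∩B|
  enforced structurally.

A **discriminant signature** is the case-exclusive block
(case-shared) \ (control-shared). A sample *displays* the signature iff
every member is called present — a conjunctive rule with no weights or
thresholds. Consequences worth noting: the rule is antitone (growing a
signature can only lose positive calls), an empty signature is vacuously
displayed by everything (a warning is emitted), and evaluating a
signature on the samples it was derived from yields sensitivity 1.0 by
construction — such evaluations are flagged `in_sample` (resubstitution)
in every report. A k-of-n partial-match mode exists for exploration but
is off by default. Sensitivity/specificity with an empty denominator are
reported as undefined (`None`), never as 0.

Signature abundance is assessed by comparing each member's mean log2
level over the scope against the grand mean over all miRNAs × scope,
with a strict `>` so a constant matrix flags nothing.

## Clustering

Binary profiles are compared with Jaccard distance (default) or
normalized Hamming distance; the Jaccard distance between two all-absent
profiles is defined as 0. Agglomeration uses average linkage by default
(complete and single are available). Binary data produce many tied
distances, so determinism is handled explicitly: leaves are put into
canonical lexicographic order before the distance matrix is built, making
the output tree a pure function of the distance values rather than of
input order. Merge heights are non-decreasing for all supported linkages.
Dendrograms serialize to Newick with branch lengths equal to parent/child
height differences (so tip-to-tip distances are twice the cophenetic
merge heights); the reordered matrix plus the two Newick trees are the
contract of a detection map, and raster rendering (configurable two-color
scheme on black) is a convenience that is never a test surface.

## Moderated-t differential contrast

The two-group contrast on detection levels uses an empirical-Bayes
moderated t. With per-feature pooled variance s²_g on d = n₁+n₂−2 df and
a scaled-F prior s²_g ~ s₀²·F(d, d₀), the posterior variance
s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d) replaces s²_g in the ordinary pooled
statistic, which is then referred to t with d₀+d df. The prior is
estimated from the ensemble of log variances z = log s²_g by method of
moments:

    Var(z) = ψ′(d/2) + ψ′(d₀/2)        (solved for d₀ by Newton
                                        inversion of the trigamma)
    E(z)   = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)

When the observed spread of z does not exceed ψ′(d/2) the moments carry
no finite-information solution and the fit falls back to d₀ = 4, a
moderate default shrinkage; the fallback is flagged on the returned
prior. `prior_df=0` reproduces the textbook pooled t exactly (verified to
1e-9 in the tests); `prior_df=inf` with a fixed s₀² collapses the
ordering to |logFC|. Only the equal-variance, two-group, two-sided design
is implemented — no trend or robust variants, no paired or multi-factor
designs — and tables are sorted by |t̃| descending. Multiple testing uses
Benjamini–Hochberg step-up FDR; adjusted p-values are monotone and never
below the raw ones. logFC is (case mean − control mean) on the log2
scale and AveExpr the grand mean, so the columns read like a standard
topTable.

Selection reports both the raw `p < 0.05` list (which feeds the post-hoc
heatmap and volcano table) and the count surviving adjustment. On
detection-call-driven data these two tell opposite stories by design:
see the generator notes below.

## Normalizer screening

Candidates must be detected in every sample (the universal pool) or be
supplied explicitly; explicit candidates may be detected anywhere from 0
to all samples, since the point of the comparison is precisely that some
conventional normalizers are rarely detected in plasma. Stability is the
unbiased (n−1) variance of the log2 level across the scope — the
estimator choice is material at ≤ 23 samples, and is stated in the output
metadata; variance is always computed on the log2 scale, never on linear
intensities. Ranking is ascending by variance with ties broken by higher
mean level and then id, so ranks are a deterministic permutation
invariant to input order.

## The synthetic scenario

The generator emulates the statistical shape of a small paired
case/control liquid-biopsy miRNome study:

- **Platform and cohorts.** 2578 miRNAs; plasma 12 cases / 11 controls,
  EV 11 cases / 10 controls (one control pair excluded for QC and one
  case and one control EV sample short of RNA, mirrored as defaults).
  Sample sex and age-in-months follow a fixed roster with both sexes in
  every group × compartment cell.
- **Background.** 55% of non-planted miRNAs are uniformly undetected;
  the rest draw a per-miRNA detection probability from a U-shaped
  Beta(0.3, 0.3) and per-sample Bernoulli calls. Because the Beta puts
  appreciable mass near 1, raw sampling would leave hundreds of
  background rows present in every sample; each variable background row
  is therefore forced absent in at least one sample of every
  group × compartment cell and of each sex, so no background row is
  uniformly present in any analysis scope and the planted sets below are
  exactly identifiable.
- **Planted sets.** Case-exclusive signatures of 19 (plasma) and 13 (EV)
  members sharing 7; control-exclusive sets of 4 and 7; an all-EV set
  sized so the EV case∩control intersection is 23 including the 9
  universal miRNAs; sex-linked sets of 5 (F) and 4 (M); and the universal
  set of 9, which carries the published names of the nine universally
  detected miRNAs while all other planted ids are synthetic
  (`syn-miR-*`). A planted miRNA is present throughout its defining scope
  and receives only sparse absences outside it: one in each shared-set
  scope it must stay out of, plus — for signature members — a cyclic
  covering absence over the opposite group so that *every* control lacks
  at least one member. This makes the conjunctive classifier perfect
  (sensitivity = specificity = 1.0) while keeping per-group level means
  nearly identical.
- **Levels.** Detected values are Normal(μ_m, σ²_m) with μ_m ~
  Uniform(3, 11) log2 units, σ² = 4.0 for ordinary miRNAs and 0.1 for the
  universal/housekeeping set; undetected values sit at a near-floor
  Normal(1.2, 0.05²). Detected-level means are group-independent by
  default, so the signal lives entirely in presence/absence: the
  signature stage discriminates perfectly while the differential stage
  finds ~5% raw hits and nothing after FDR adjustment. A `level_shift`
  option adds a case-group mean shift to the planted signatures to give
  the differential stage real power when testing it.
- **Detection p-values.** Present calls draw Uniform(0, 0.9α), absent
  calls Uniform(1.1α, 1), so binarization at α is exact and call noise is
  studied separately through the `degrade` operation (independent
  present→absent dropout δ and absent→present ε flips) or the config
  noise rates, which apply to planted rows.
- **Randomness.** One seed feeds fixed counter-based substreams, with
  per-sample streams keyed by global sample index, so identical
  config+seed is bit-reproducible and enlarging a cohort never perturbs
  earlier samples' draws.

What the generator does **not** emulate: probe-level intensity synthesis
and array normalization, batch or hybridization effects, correlated
detection between related miRNAs, compartment-specific abundance shifts,
or realistic sequence content. Passing tests on this scenario therefore
demonstrate the correctness of the set algebra, the classifier, the
rankings and the statistics under the stated model — not robustness to
array artifacts in real data.

A companion roster (`detectome.studysets`) builds stand-in gene-set lists
with the same cardinality and overlap structure (plasma Venn 19/9/4, EV
13/23/7, a 142-member tumor-core reference containing 14 of the plasma
and 8 of the EV signature, sex Venn 5/9/4); it exists so the set-algebra
stages can be exercised through GMT I/O end to end, and every synthetic
id is marked as such.

## Numerical and edge-case choices

- Strict inequalities at every decision boundary (binarization,
  above-average abundance), chosen once and documented so results are
  bit-reproducible.
- IDs are whitespace-trimmed, case-preserved opaque strings; duplicate
  ids are errors naming the duplicate.
- Readers reject exactly what their contracts name (non-numeric cells
  with row/column address, p-values outside [0,1], unknown annotation
  enum tokens, GMT lines with fewer than two fields with line numbers);
  accepted inputs round-trip bit-identically for ids and to ≤ 1e-9 for
  numerics.
- Degenerate inputs: single-leaf dendrograms serialize as `label;`;
  single-sample scopes make every miRNA uniform; a zero-variance
  candidate ranks first; an all-absent pair has Jaccard distance 0.
- Dropout applied to case samples can only shrink a recovered signature;
  dropout in controls can *promote* universal miRNAs into the apparent
  signature (they drop out of the control-shared set), which is why noise
  robustness is stated and tested per side.

## Known limitations

- The conjunctive classifier is evaluated by resubstitution when derived
  and evaluated on the same cohort; no cross-validation or held-out
  estimate is provided, only honest flagging.
- BH adjustment controls FDR per contrast; with ~2600 features a single
  sub-2e-5 p-value — expected under a global null with probability about
  α per contrast — yields one adjusted discovery, so "zero adjusted
  significant" is a property of a specific dataset, not a guarantee of
  the procedure.
- The moderated-t prior assumes one variance ensemble; strongly bimodal
  ensembles (detected vs floor rows) yield a small d₀ and hence weak
  shrinkage.
- Clustering determinism is guaranteed for the canonical leaf order; it
  does not attempt to reproduce the ordering of any particular GUI
  clustering tool.
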