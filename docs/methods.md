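# Methods

## The screen and its assumptions

The pipeline models a paired cell-free co-incubation design: for each
biological replicate (one semen collection), a primed-control aliquot and an
extract-treated aliquot are profiled, together with vehicle-control sperm
and the oocyte extract itself, in triplicate at two co-incubation times
(4 h, 24 h). Spectral counts are treated as a semi-quantitative abundance
proxy; a protein absent from a sample's table is a count of 0, not missing
data, because spectral counting has no distinct missing code and the
presence/absence class logic reads non-observation as absence. Protein
identity is the accession string verbatim; no cross-version accession
mapping is attempted.

Detection uses the per-sample identification rule of the upstream search
(≥ `min_spectra` spectra per protein per sample, default 4), re-applied at
ingest as an explicit censoring filter so that synthetic data passes
through the same gate as search-engine exports. The rule is deliberately
per sample per replicate; whether it should instead act on
replicate-aggregated counts is ambiguous, and `presence_min` (below)
exposes the replicate-level half of that question.

## Normalization

Two stages, in a fixed order, computed independently within each
timepoint's batch:

1. **ODF stage** — sperm-containing samples (vehicle control, primed
   control, treated; the extract contains no sperm flagella) are scaled by
   `factor[s] = mean(T)/T[s]` with `T[s]` the summed counts of the
   reference accessions (default ODF1, ODF2, ODF3). The exact arithmetic
   behind "anchored to reference content" is a design choice here:
   equalizing the per-sample reference sum to its arithmetic mean is the
   simplest scheme consistent with the idea, and the factors are emitted so
   a run can be audited against any externally normalized table.
2. **Mean stage** — samples are scaled to a common mean abundance.
   `shared_only=True` (default) takes means over proteins detected in
   every target sample, so presence/absence differences cannot dominate the
   scaling. The default target set is the sperm samples only
   (`normalize_extract=False`): extract columns feed neither the paired
   test nor the detection patterns (patterns use censored raw counts), so
   forcing the oocyte-extract proteome to the sperm samples' mean would be
   meaningless — and, on synthetic data, it skews the shared-protein set
   because extract presence is random for unaffected proteins. Both
   choices are flags.

Mean normalization carries the standard assumption that most proteins are
unchanged between conditions. Both stages anchor to data-dependent means,
so rescaling one raw column rescales the whole normalized batch by one
common constant; relative abundances, and therefore all paired t
statistics, are invariant to that constant. The post-stage invariants
(equal reference sums after stage 1, equal shared-set means after stage 2)
hold to 1e-9 relative and are asserted per stage — stage 2 intentionally
re-scales samples unequally, so stage 1's equality is not preserved through
stage 2.

## Differential testing

Per protein and timepoint, a two-sided paired Student t-test on the
per-replicate differences of normalized abundance (sample SD, n − 1 df).
Direction is read from the sign of the mean difference separately from the
two-sided p. Proteins detected in neither compared condition are omitted;
non-detected cells enter as zeros (required for Class 1 proteins, whose
control vectors are all zero). Degenerate cases the small design can
produce (all differences equal) are defined rather than erroring: p = 1
and no direction when the common difference is 0, p = 0 with the sign's
direction otherwise. Raw p-values are used throughout, matching the
screen's exploratory character; a Benjamini–Hochberg column is available
for exports but never influences class assignment.

## Classification and inventory

A protein is "in" a condition when detected in ≥ `presence_min` of its
replicates (default 1: seen in any replicate — the least surprising
reading of presence at n = 3). Classes are evaluated in order:

* class 1: not in vehicle control, not in primed control, in extract, in
  treated, p &lt; `class1_alpha` (default 0.2). Detection in either sperm
  control vetoes Class 1 regardless of p.
* class 2: in primed control, direction increase, p &lt; `class23_alpha`
  (default 0.1).
* class 3: in primed control (extract presence optional — the literal
  "both gametes or only the spermatozoa" reading), direction decrease,
  p &lt; `class23_alpha`.

Each tested protein gets exactly one label per timepoint. Candidates whose
distribution pattern is extract-only but whose p fails `class1_alpha` stay
unclassified rather than being admitted on pattern alone. The merged
inventory keys on accession equality, stores both timepoints' classes
(a protein may legitimately change class between 4 h and 24 h), and its
union/intersection totals satisfy inclusion–exclusion as an integer
identity. Category tables report integer percentages, rounded half up,
of each (timepoint, class) cell against a user-supplied accession→category
map; the categorization itself is manual curation upstream of this
package.

## Synthetic experiments

The generator plants truth under the study design. Counts follow a
negative-binomial law (mean μ, variance μ + μ²/`dispersion`) realised as a
gamma–Poisson mixture: a gamma biological effect with shape `dispersion`
is drawn per protein × replicate and **shared between the primed-control
and treated aliquots of that replicate**, with independent Poisson
sampling on top. The sharing is what biological replication means in a
paired design — both aliquots derive from one collection — and it is
precisely the variance component the paired t-test cancels; with fully
independent draws the paired design would have materially less power at
n = 3. Marginally every count is exactly the negative binomial above
(verified by Monte Carlo at 10,000 draws). Per-sample loading variation is
an independent log-normal multiplier (`sample_scale_jitter`, default 0.1),
removed again by normalization.

Planted types: null (baseline in all sperm samples, extract presence with
probability 0.5), reference (20× baseline in sperm, absent from extract),
class 1 (hard zeros in both sperm controls; baseline in extract and
treated), class 2 (baseline ×`effect_fold` in treated), class 3 (baseline
/`effect_fold` in treated; extract presence with probability 0.5,
exercising the both-gametes branch).

Defaults and why:

* `baseline_mean` 50 — a comfortably detected sperm protein, well above
  the 4-spectra censoring floor, chosen from a power analysis of the
  3-pair design (noncentrality ≈ 4–5 at fold 4, dispersion 10).
* `effect_fold` 4, `dispersion` 10, `n_pairs` 3 — the strong-effect study
  conditions exercised by the recovery checks.
* composition `n_null=1000, n_class1=12, n_class2=25, n_class3=100` —
  a null-dominated proteome (~12% differential) with decreases
  outnumbering increases 4:1, matching the screen's inventories (roughly
  three quarters of candidates are Class 3). Keeping the differential
  fraction small respects mean normalization's own assumption; the 4:1
  ratio at fold 4 additionally balances total planted abundance across
  conditions (+150 counts per class-2 protein vs −37.5 per class-3),
  emulating the equal peptide load injected per MS run. Concentrated
  strong-effect compositions (say 20% differential, all one-sided) bias
  the mean stage and inflate one-sided null misclassification — a
  compositional property of mean normalization itself, demonstrated but
  not hidden by the tests.

What the generator does **not** emulate: peptide-level identification and
FDR, shared peptides, protein-size effects on spectral counts, correlated
co-regulation between proteins, batch drift within a timepoint, or real
accession namespaces. Passing tests therefore demonstrate the pipeline's
statistical behaviour under the declared noise model, not search-engine
artefacts.

## Calibration and recovery, as measured

On generated data the suite asserts (all computed at run time, fixed
seeds): type-I fraction of p &lt; 0.1 within the 99% binomial interval
around 0.10 at 2,000 null proteins; ≥ 90% pooled recovery of planted
class-2/3 proteins at the strong-effect conditions; class-1 admissions
confined to planted extract-only proteins; paired-t agreement with an
independent implementation to 1e-10 over 1,000 random vectors and with
direct numerical integration of the t density; byte-identical reruns.
Problem sizes (≈ 1,000–2,500 proteins, 24 samples) keep any single check
in seconds while leaving binomial intervals tight enough to be
informative.

## Numerical and formatting choices

Scale factors must be positive and finite; zero reference totals or zero
sample means abort the run naming the offending sample. Tables are written
with `%.10g` float formatting, which is what makes reruns byte-identical.
Thresholds are validated as 0 &lt; `class23_alpha` ≤ `class1_alpha` &lt; 1.
The pipeline computes everything before writing anything, so a failing
stage leaves no partial outputs.

## Limitations

Spectral counting saturates for very abundant proteins and is insensitive
near the detection floor; the paired t-test at n = 3 has only 2 degrees of
freedom, so single-replicate anomalies strongly influence p; raw-p
admission at 0.1/0.2 trades specificity for sensitivity by design (the
inventory is a candidate list, not a validated set); and the from-raw
normalization is one defensible reading of reference-content anchoring —
for data normalized elsewhere, the from-normalized entry mode plus
`compare_runs` quantifies how class memberships depend on that choice.
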