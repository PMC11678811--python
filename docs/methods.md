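# Methods

## The detection problem

Tumor-informed ctDNA detection restricts attention to SNVs first called in
the patient's own tumor and asks whether the patient's plasma shows more
alternate-read support at those sites than plasma from tumor-free
individuals does. At WGS depths (tens of ×) a single site is uninformative:
with a ctDNA fraction of 10⁻³–10⁻² and a heterozygous-scale tumor VAF, the
expected alternate count per plasma site is well below one read. The
statistic therefore integrates over the whole filtered variant set, and the
limit of sensitivity is set not by depth but by the residual per-site error
rate after filtering — the noise floor.

## Filters

Every filter is evaluated per variant against the unfiltered table, so a
variant's verdict is the *set* of filters it fails and composition is
order-independent (verified by a property test that runs the pool filter
before and after the PON and asserts identical survivors). Conventions:

- Basic thresholds are inclusive on the keep side: keep iff tumor AD ≥ 8,
  tumor DP ≥ 12, tumor VAF ≥ 0.2, normal DP ≥ 10, and normal AD ≤ 0
  (i.e. exactly zero alternate reads in the matched normal). All are
  `FilterConfig` fields; the defaults are the most stringent rung of the
  ladder the package ships.
- The population-AF filter removes a variant only when an AF is present and
  exceeds 10⁻⁵; absence from the population resource keeps the variant.
- The self-generated PON admits a site when it shows AD ≥ `pon_min_ad`
  (default 1) in at least `pon_min_samples` (default 2) distinct normal
  samples; the merged PON is the set union with the public panel. PON
  filtering is post-hoc site membership over the forced-call table.
- The plasma-pool filter removes a variant when *any* pool plasma shows
  AD strictly greater than 1 (AD ≥ 2 removes; a single stray read does
  not). The rule is deliberately depth-independent: it is a recurrence
  test, not a frequency test. Removal excludes the site from the signal
  *and* from the control-plasma noise model, since an artefact-prone
  position is equally wrong in both.

Methods: 1 = basic + population-AF + public PON; 2 = the same with the
merged PON; 3 = Method 2 plus the pool filter. Because all verdicts are
computed on the original table, survivors(3) ⊆ survivors(2) ⊆ survivors(1)
holds structurally.

## Noise model and statistics

For metric m ∈ {VAF, AD} over the kept set V:

- AveVarDet = mean of m in the patient plasma over V. By default the mean
  runs over all kept variants, zeros included; a `detected_only` switch
  restricts it to variants with plasma AD ≥ `detection_ad_min` (default 1).
- Each control plasma j contributes one summary value: the mean of m over V
  in control j. μ_noise and σ_noise are the mean and the sample (n−1)
  standard deviation of these per-control summaries.
- S2N = AveVarDet / μ_noise, z = (AveVarDet − μ_noise) / σ_noise.
- The binary variant replaces the summaries by detected-variant counts
  (AD ≥ `detection_ad_min`) in plasma and in each control.

Choosing per-control means (rather than pooling all variant × control
values) makes each control's summary an exact null replicate of AveVarDet:
σ_noise is then a between-sample standard deviation on n_controls − 1
degrees of freedom and automatically absorbs any between-library variation,
not just binomial counting noise. The pooled alternative is available via
`pooling="pooled"` for sensitivity analyses.

Significance is one-sided against the Student-t upper-α quantile. The
shipped default is α = 0.05 with df = 7, whose critical value is 1.895 to
three decimals; df is an explicit parameter because the effective degrees
of freedom of a plug-in z with σ estimated from n controls is a modeling
choice (df = n_controls − 1 = 8 would give 1.860; a normal approximation
1.645). With nine controls the null z is not standard normal: comparing one
plasma against the mean and SD of nine exchangeable controls gives
z / √(1 + 1/9) ~ t₈, hence Var(z) ≈ (1 + 1/9) · 8/6 ≈ 1.48. The null
calibration test asserts exactly this regime (mean ≈ 0, variance in
[0.7, 1.6], one-sided exceedance of 1.895 in [0.01, 0.08]).

Degenerate cases are explicit: an empty kept set raises an undefined-signal
error; σ_noise = 0 raises a degenerate-noise error rather than returning an
infinite z; μ_noise = 0 makes S2N +∞ with a warning. Zero-depth
observations have VAF 0 by convention (flagged in logs when parsed from
VCF), which biases averages toward zero rather than producing NaNs.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
sequencing reads:

| parameter | default | rationale |
|---|---|---|
| n_variants | 2000 | order of a high-burden tumor's somatic SNV load surviving calling |
| tumor / normal / plasma / control depth | 24 / 17 / 52 / 49× | WGS design depths of the assay the package targets |
| n_controls, n_pool | 9, 9 | nine-patient, nine-control study layout |
| tumor VAF v_t | Uniform(0.2, 0.8) | ≥75% tumor cell fraction; VAF_t ≥ 0.2 calling regime |
| tumor_fraction | 0.01 | plausible pretreatment ctDNA burden in advanced high-grade serous disease |
| error_rate e | 10⁻³ | per-base substitution error; site background = e/3 per alt base |
| artefact_fraction / artefact_vaf | 0.02 / 0.02 | a few % of sites carry recurrent position-specific error visible in every plasma |
| germline_leak_fraction / VAF | 0.01 / 0.5 | heterozygous germline calls leaking into the somatic set |

Counts are drawn as DP ~ Poisson(mean) (negative binomial behind
`depth_law="negbin"`) and AD ~ Binomial(DP, p) with p = tf·v_t + background
in the patient plasma and p = background in every control and pool plasma.
Artefact sites share their elevated background across *all* plasma samples
of a patient's table — that cross-sample recurrence is exactly what the
pool filter exploits, and what makes the noise-floor μ ≈ e/3 ≈ 3.3 × 10⁻⁴
recoverable after Method 3. Each patient's variants occupy disjoint
position blocks with per-variant Bernoulli artefact flags; the cohort truth
records the union of flagged sites.

What the generator does **not** emulate: trinucleotide-context error
profiles, strand/orientation artefacts, mapping error, CNV-driven VAF
distortion, fragment-length signal, caller-specific forced-calling quirks,
and germline contamination of the pool. Passing tests therefore demonstrate
the *internal* correctness and calibration of the statistics under the
assumed noise structure, not assay performance on real cfDNA.

Seeding: one master seed; per-patient and per-sample streams are spawned
deterministically (`numpy` SeedSequence), so cohorts are reproducible
file-for-file.

## Downsampling

Reduced sequencing depth is emulated at the count level: each alternate and
reference read is kept independently with probability f, i.e.
AD' ~ Binomial(AD, f), DP' − AD' ~ Binomial(DP − AD, f). This matches the
marginal per-site behavior of read-level random downsampling for SNV
counts. Only the patient plasma is thinned by default; controls keep their
original depth, so the noise model is untouched.

A consequence worth stating: conditionally on the thinned depth, the kept
reads are a uniform subsample, so the plasma VAF is unbiased under thinning
and the *mean* VAF-based z is essentially invariant at the count level
(only its variance grows). Depth sensitivity shows up mechanically in the
AD-based and binary statistics, whose plasma side scales with f while the
control side does not; the downsampling checks therefore measure the
AD-based z, where thinning to f = 0.4 cuts the mean z by roughly two-thirds
while the mean thinned depth lands within 1% of 0.4× the original.

## Filter accounting

Removed variants are grouped by their exact failed-filter set (UpSet
exclusive-intersection semantics). The counts partition the removed set, so
marginal(L) = Σ of exclusive counts of combinations containing L; the
display (text or plot) suppresses combinations below `min_count`
(default 15) but the serialized map is always complete. Inclusive
intersections are derivable from the map.

## Problem sizes and observed behavior

The test suite and `scripts/acceptance.py` run the pipeline end-to-end on
simulated cohorts at the design sizes: 500 null patients for calibration,
100 cohorts at tumor fraction 5 × 10⁻³ for the detection rate, and 50
replicates each for the pool-filter and downsampling comparisons (~2–3
minutes total on one CPU). Under the defaults the pool filter improves S2N
in essentially every replicate (removing shared-artefact sites lowers
μ_noise roughly twofold) and improves z in roughly nine of ten; without
artefact sites it removes only the occasional clean site and shows no
systematic S2N shift, while z can only lose slightly (discarding sites
inflates the estimated σ_noise) — the same asymmetry one expects on real
data when a cohort happens to be artefact-poor.

## Known limitations

- SNVs only; indels are skipped at parse time.
- The pool filter can in principle remove a true recurrent hotspot
  mutation shared across patients; at WGS scale this costs a negligible
  fraction of the signal, but for hotspot-driven cancers a whitelist would
  be a sensible extension.
- The df of the significance test is a parameter, not an estimate; users
  comparing cohorts with very different numbers of controls should set it
  deliberately.
- The simulator's uniform error model makes all clean sites exchangeable;
  real per-site error spectra are heavy-tailed, which is precisely why the
  pool filter earns its keep in practice.
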