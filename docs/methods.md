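# Methods

## Normalization model

qPCR reports a cycle threshold Ct per gene; one cycle corresponds to
one doubling of starting template, so Ct is linear in log2 expression
with slope −1. The package reduces each assay to Ct scores
`score = mean_hk(Ct) − Ct(target)`, oriented so the score rises with
expression and is exactly invariant to adding a constant to every Ct
in the assay (loading/efficiency offsets cancel; this invariance is
asserted by the test suite). The housekeeping set defaults to GAPDH,
HPRT1 and GUSB; a sample whose housekeeping gene is itself undetected
fails QC outright rather than being averaged over the survivors,
since its baseline is not trustworthy.

The detection threshold is 34 cycles and **inclusive**: Ct ≥ 34 is
flagged unexpressed. The strict variant (Ct > 34) is available behind
a flag (`flag_unexpressed(..., inclusive=False)`,
`normalize-qpcr --strict-threshold`); the two readings differ only on
exact-34 values. Censored measurements keep their raw Ct in files and
in `CtTable` objects — only the flag marks them — so threshold policy
can be revisited downstream without regenerating data.

Array input is assumed gene-level and log2 (RMA convention); no
re-logging or probeset collapsing is performed. It is referenced to
the same housekeeping mean, making the two platforms' scores
comparable up to per-probe constants.

## Calibration

Per-probe location/scale differences between platforms are absorbed by
scale-and-center against a reference cohort: per gene, the observed
score mean and sample SD (n−1 denominator) over non-missing entries.
Missing entries are excluded from estimation, never imputed. A
calibration table is platform-tagged and refuses cross-platform
application — the constants it absorbs (array probe affinity vs qPCR
assay intercept) are meaningless for the other technology. Genes need
at least two observations and nonzero variance; violations are errors
naming the gene. On noiseless synthetic data the calibrated z-values
of the two platforms coincide exactly, because per-gene intercepts
cancel and both transfer slopes are 1 in log2 units.

## Pathway indexes and reference placement

A pathway index is the unweighted mean of calibrated z-values over the
pathway's detected members; undetected genes are removed from the
denominator (a dropout shrinks n, it does not drag the index toward
zero). A pathway with no detected members has an absent index, flagged,
never zero. The aggregator is pluggable (`pathway_index(...,
aggregator=...)`) because weighted variants are plausible in risk-model
settings; the unweighted mean is the default and the only aggregation
the package's own analyses use.

Reference placement fits a normal (mean, sample SD) to each pathway's
reference-cohort indexes — reference index distributions are
approximately normal by construction here (sums of jointly normal
variables), and empirically bell-shaped in the cohorts this design
targets. An empirical-percentile fallback
(`build_reference_distribution(..., keep_values=True)`,
`map_to_reference(..., method="empirical")`) is provided for heavy
tails. The bias check is a per-pathway one-sample KS test of the
reference z-positions against N(0, 1); it needs at least three placed
samples and skips (with a warning) otherwise.

## Concordance

Missing data is handled throughout by pairwise-complete deletion,
matching the per-assay removal of undetected probes. Pooled
correlations are computed over all jointly observed (gene, sample)
pairs; per-sample correlations across genes are also reported, because
the pooled and averaged-per-sample views can differ and both are of
interest. LOWESS is the classic tricube-kernel, local-linear smoother
with zero robustness iterations and span 2/3 by default (span
exposed); the window is the ceil(span·n) nearest neighbours,
contiguous in sorted x. The implementation is deterministic and is
cross-checked in the test suite against both a single-point weighted
least-squares oracle and statsmodels' smoother. The all-pairs sample
correlation matrix keeps every value numerically; the display mask
(default r < 0.79 hidden) affects rendering only.

## Synthetic cohort generator

The generator emulates a matched-design study: per patient, one array
observation, one snap-frozen qPCR assay and one FFPE qPCR assay of the
same 91-gene, 10-pathway panel plus 3 housekeeping genes.

Generative model, per gene g and patient p:

- latent log2 expression x_gp ~ N(μ_g, σ_x²) with equicorrelation ρ
  within each pathway block and independence across blocks;
  μ_g ~ U(latent_mean_range);
- array: x_gp + N(0, τ_a²);
- frozen Ct: I_g − x_gp + N(0, τ_q²), I_g ~ U(qpcr_intercept_range);
- FFPE Ct: a fresh draw from the frozen model plus a patient-level
  shift δ_p ~ N(m_f, s_f²) and extra noise N(0, τ_f²);
- housekeeping genes: high baseline (U(14, 16) log2, Ct near 20) with
  near-zero biological SD (0.05 log2) — the stability assumption that
  makes ΔCt referencing meaningful;
- censoring: Ct ≥ 34 flagged unexpressed, raw value retained.

Defaults (the simulated study conditions): 18 patients, μ_g ∈ (3, 10),
σ_x = 1, ρ = 0.5, τ_a = τ_q = 0.3 , I_g ∈ (34, 38), δ ~ N(1.5, 0.5²),
τ_f = 0.4. These were chosen, once, to produce the qualitative
features a well-behaved matched cohort of this design shows: a few
low-expressing genes undetected in most assays and a modest tail of
occasional dropouts (dropout probability falls monotonically with
latent mean, since P(Ct ≥ 34) = Φ((34 − I_g + μ_g)/σ)); matched
frozen/FFPE profile correlations in the mid-0.9s that exceed every
cross-patient correlation; and a patient-level FFPE shift that cancels
exactly under ΔCt normalization, leaving only the extra FFPE noise —
the simplest mechanism consistent with high intra-patient concordance.
RQI values are emitted as uninterpreted metadata (frozen ≈ 6.5–9.8,
FFPE ≈ 1.9–3.1); no quantitative RQI→noise link is modeled.

What the generator does **not** emulate: gene-length/GC-dependent
degradation, storage-time effects, PCR efficiency differences per
probe beyond the constant intercept, intra-tumor heterogeneity
(frozen and FFPE share one latent sample), cross-pathway correlation,
or probe-level array artifacts. Passing tests therefore demonstrate
the pipeline's algebra and statistical behaviour under this model, not
performance on real tissue.

### A note on the attenuation identity

With unit biological SD and unit measurement noise on both channels,
the per-gene cross-platform correlation is
ρ = σ_x²/√((σ_x²+τ_a²)(σ_x²+τ_q²)) = 0.5. This identity describes the
two measurement channels (array intensity, negated Ct); the package's
attenuation check therefore standardizes each channel per gene without
housekeeping referencing. ΔCt referencing adds a shared
housekeeping-average noise term of variance τ_q²/3 per platform, which
lowers the referenced correlation to σ_x²/(σ_x²+τ_q²+τ_q²/3) ≈ 0.43 at
the same settings; a dedicated test verifies that extended form too.

## Numerical and design choices

- Text formats use Python's shortest-repr floats and a
  correctly-rounded reader, so every write/read cycle is lossless to
  the bit.
- Equicorrelation blocks are sampled via Cholesky factors; ρ is
  restricted to [0, 1), where every block size is positive definite.
- Seeding: a single integer seed drives one `numpy` Generator with a
  fixed draw order; identical configs give bit-identical cohorts.
- The pipeline's reference cohort is carved from the same seeded draw
  as the study cohort so both share per-gene parameters, as matched
  use of one gene panel implies; its size (default 200) trades
  reference-fit noise against runtime.
- Pipeline stages communicate through files, and the run manifest
  records seed, config hash and row counts.
- Problem sizes in the test suite (e.g. 100 seeded 18-patient cohorts
  for the separation rate, 200 held-out batches of 40 for the bias
  rate, 500-patient cohorts for attenuation) were sized to make the
  Monte-Carlo error a small fraction of each tested margin.

## Known limitations

- The unweighted-mean index ignores any gene weighting a fitted risk
  model might use; the pluggable aggregator is the extension point.
- The normal reference model misstates percentiles for non-normal
  index distributions; use the empirical fallback there.
- Cross-platform placement (qPCR indexes on an array-built reference)
  is only approximately unbiased when the platforms' noise scales
  differ; the KS bias test is the guardrail, not a correction.
- The bundled 10-pathway/91-gene panel is a synthetic stand-in for a
  curated panel: structure is realistic, membership is placeholder.
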