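# Methods

## Coordinate and measurement conventions

All genomic coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on load, BED is native. A miRNA locus's *center* is
`floor((start + end) / 2)` of the annotated pre-miRNA interval; every
analysis window is anchored there: the tiled array window (±2000 bp), the
regional-model window (±500 bp) and the capture-count window (±300 bp).
All windows are half-open `[center − w, center + w)` and membership is by
*any overlap* — a probe or read straddling the boundary is included. The
containment alternative is a function argument, not a second code path.

qPCR wells reported as "Undetermined" are censored at the 40-cycle
amplification bound and flagged; downstream contrasts involving censored
wells carry the flag forward rather than dropping the target. One log2 unit
of expression corresponds to −1 cycle (amplification efficiency fixed at 2;
no efficiency correction is attempted).

## Regional linear model

Per locus and assay, the probes overlapping the ±500 bp window are fit by
OLS of log2 intensity on probe indicators plus a PrEC/LNCaP condition
indicator. The condition coefficient is the average cancer-vs-normal change
with probe affinity absorbed; `t = effect / se` with
`df = n_obs − n_probes − 1`, and |t| ≥ 2 (boundary inclusive) calls a
region changed, with no multiplicity correction — the screen is a fixed-
threshold candidate generator, not an FDR-controlled test.

Numerical choices:

* Pipeline order is log2 → quantile normalization (per assay, across all of
  that assay's samples) → regional fits. Quantile normalization averages
  sorted columns into one reference distribution; ties within a column
  receive the mean of their tied quantile values, and with a single sample
  the operation is the identity (warned).
* Fits with numerically zero residual sum of squares (relative tolerance
  1e−20 of the response's sum of squares) report t = 0 rather than ±∞: a
  perfect fit on duplicate arrays is evidence of a degenerate design, not
  of infinite significance.
* A probe observed in only one condition would make the design rank
  deficient; it is dropped with a warning. Fewer than two usable probes
  yields an explicit unfitted result rather than a silent skip.
* Each locus and assay is fit independently (no information sharing across
  regions), matching the per-miRNA report granularity.
* MeDIP and H3K9Ac use the IP-channel intensities directly; an input-ratio
  correction is deliberately not applied by default because the regional
  model already absorbs probe-level affinity, the dominant bias term.

Note on normalization and exactness: quantile normalization forces all
samples of an assay onto a common distribution. When a large fraction of
probes genuinely shifts in one condition, that forcing slightly shrinks
the estimated effects; planted effects are therefore recovered *exactly*
only when normalization is bypassed (as the noiseless round-trip test
does), and recovered to within sampling error in the realistic regime
where planted loci are a minority.

## Moderated t-test and prior estimation

The TLDA analysis tests ΔCt values (not 2^−ΔCt quantities): Ct is the
measurement scale and its replicate noise is closest to Gaussian. For each
contrast the per-target pooled variance s²_g (d_g df) is shrunk toward an
ensemble prior, `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, and the moderated
statistic is referred to a t-distribution with d₀ + d_g df (standard
normal when d₀ = ∞). The prior is estimated per contrast over the whole
panel by the method of moments on z_g = log s²_g: after removing the known
sampling moments of a log chi-square (digamma/trigamma terms), excess
dispersion determines d₀ through the inverse trigamma (solved by Newton
iteration to 1e−10 relative tolerance) and the corrected mean determines
s₀². No excess dispersion gives d₀ = ∞ with the bias-corrected geometric
mean as s₀². With d₀ = 0 the procedure reduces to the classical pooled
two-sample t (verified to 1e−10), and an R limma run on the same panel is
used as an independent oracle in the test suite.

No multiple-testing correction is applied to the calls (a
Benjamini–Hochberg column is emitted for information only). Mature
differential expression requires p < 0.05 and fold change ≥ 1.5 (inclusive)
in either direction. The 5-Aza-CdR contrasts use p < 0.05 with any
induction (FC > 1) as the reactivation rule; on the bundled candidate table
this rule and a stricter FC ≥ 1.5 rule produce identical final sets, so
the looser rule is the default and the threshold is an argument.

pri-miRNA assays are summarized as group mean ± SD of 2^−ΔCt (18S
reference, n = 6 per group by default) with a pooled two-sided Student's t
on ΔCt; identical groups (zero pooled variance, zero difference) are
reported as p = 1.

## Concordance classifier

Tiers nest by construction: *expression-concordant* (tiling-RNA and mature
LvP both significant, same direction) → *one canonical mark* → *both marks
canonical* → *final* (adds reactivation in the cell line predicted to be
methylated: PrEC for activated loci, LNCaP for repressed loci). Design
choices that the evidence left open:

* A mark counts toward a tier only when its direction is concordant with
  the expression change (not merely significant); this is the only reading
  under which all bundled candidate rows reach the one-mark tier.
* A locus is flagged non-canonical only when at least one mark is
  significant-discordant *and no mark is canonical* — a mixed locus (one
  canonical, one discordant mark) stays in the canonical funnel.
* All counting is restricted to an explicit universe of miRNAs assayed on
  both platforms, preventing denominator drift; missing data caps a tier
  with a warning instead of silently dropping the miRNA.
* Funnel counts are reported cumulatively ("tier or better"), which makes
  the non-increasing property structural.

## Synthetic-data generator

The generator emulates the study geometry: 341 loci (the platform
intersection), 60-nt probes at 20-nt steps over ±2000 bp (the array's true
step is not published; 20 nt is a free choice giving 198 probes per locus),
biological duplicates, four qPCR conditions, and 36-bp capture reads.
Tiling intensities follow an additive log2 model — baseline 10 + per-probe
affinity N(0, 1) + planted condition effect + replicate noise N(0, 0.3) —
exponentiated to the raw scale. The affinity term mirrors the
multiplicative probe-binding behavior of hybridization arrays, and at the
default noise the simulated biological duplicates correlate at r > 0.9,
matching the reproducibility reported for the real arrays. Planted
epigenetic effects are confined to the ±500 bp analysis window; signal
outside it would be invisible to the regional model by design.

Planted classes fix sign patterns (activation: RNA +e, methylation −e,
H3K9Ac +e, mature +e, PrEC reactivation +e; repression mirrored with LNCaP
reactivation; non-canonical classes flip the marks; expression-only classes
zero them). The default effect size is 2.0 log2 (4-fold), default class
fractions 5% per class. Ct tables place target baselines uniformly in
22–30 cycles with N(0, 0.25)-cycle noise and a reference gene fixed at 20
cycles; because unregulated targets receive the same noise as the
reference, the reference is only as stable as the null band — the relevant
(and tested) property is that it is far more stable than any regulated
target. pri-miRNA tables reuse the transcription-level effects. Capture
reads are Poisson: IP counts at `depth · 2^(medip_log2fc)` in LNCaP and
`depth` in PrEC, inputs at `depth`, placed uniformly in the ±300 bp window.

A single master seed is split into per-stage substreams (numpy
`SeedSequence.spawn`), so any stage can be regenerated independently and
all outputs are byte-identical for identical parameters.

What the generator does **not** model: GC/CpG-density capture bias, probe
cross-hybridization, dye effects, amplification-efficiency variation,
censoring at high Ct, 5-Aza dose response, and correlated replicate
structure. Passing recovery tests therefore demonstrates that the
statistics invert the stated generative model at realistic noise — not
that they are robust to these real-data artefacts.

## Capture-read counting

Window counts use any-overlap semantics against the half-open window;
duplicates count (deduplication is a flag). Enrichment is
`(IP + 1) / (input + 1)` — the pseudocount keeps zero-coverage loci defined
at 1.0 — and a locus is flagged `input_explained` when the LNCaP/PrEC IP
ratio does not exceed the same ratio in the inputs. Counts are absolute by
default; per-million scaling is a flag.

## Problem sizes and tolerances in the test suite

The regional-model oracle compares 110+ random small designs (≤ 6 probes,
≤ 4 replicates per condition) against direct normal-equations OLS at 1e−8
relative error. Recovery is assessed on one simulated study at the default
scale (341 loci, 5% per class, seed fixed): ≥ 90% of planted canonical loci
at the both-marks tier, ≥ 85% at final, ≤ 2% of unregulated loci reaching
the both-marks tier. Moderated-t calibration uses a 5000-target null panel
(2 vs 2, type-I error within [0.03, 0.07] at p < 0.05) and prior recovery
uses 5000 variances drawn from the d₀ = 4, s₀² = 1 scaled inverse-χ² prior
observed with 4-df sampling noise (recovery windows d₀ ∈ [3, 5],
s₀² ∈ [0.9, 1.1]). Monte-Carlo checks of the capture simulator use 100
seeded replicates.
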