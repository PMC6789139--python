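# Methods

This note documents the models and procedures implemented in `raphequant`,
the defaults that matter, and what the synthetic benchmarks do and do not
demonstrate.

## Counting model for colocalization (cellcount)

A section is a set of co-registered channels with intensities normalized to
[0, 1] and a physical scale in µm/px. Somata are detected per channel as
connected components of a thresholded image whose area corresponds to a
diameter in [10, 25] µm; the lower bound is what rejects neurite clutter, the
upper bound rejects merged blobs and artifacts. Components touching the
border are kept; ordering is row-major by centroid so outputs are
deterministic.

Two threshold rules are available. The parameter-free default is Otsu per
channel per section, appropriate for real images of unknown brightness. For
the synthetic benchmarks the pipeline instead uses an absolute threshold at
the midpoint of the generator's background (0.05) and soma foreground (0.8)
levels, 0.425: a global Otsu cut on a soma-dominated image tends to land low
and leaves blur bridges between close neighbors, whereas the midpoint
threshold separates every pair the generator can produce (see the hard-core
note below). This is a statement about the benchmark geometry, not a claim
about real tissue.

Co-expression uses a mask-overlap rule: a detection co-expresses the marker
iff ≥ 50% of its pixels are marker-positive under the same threshold family.
Overlap is preferred to a centroid lookup because it tolerates ~1 px
registration error between channels. Subregion assignment is a
centroid-in-box test on half-open boxes (lower/left edges inclusive), so a
centroid on a shared boundary belongs to exactly one box and counts are
conserved. Percentages are reported to one decimal; a zero denominator is an
explicit error, never 0%. Group penetrance excludes animals with reporter
expression in fewer than 6 of 8 analyzed sections when section metadata is
present, mirroring standard practice for incomplete viral coverage.

## Input mapping (inputmap)

Pixel-count semantics are deliberate: the method counts label-positive
pixels, not objects, and therefore over-weights regions with dense
fluorescent neurites. The `validate_against_manual` regression exists to
quantify exactly that bias (slope = mean pixels per neuron; R² = how well
pixel counts track object counts). The processing order is fixed and
matters: segment at a per-brain scalar threshold → clear artifact polygons →
assign each positive pixel to its raster label (label 0 is reported
separately, never folded into a region) → drop excluded regions → sum counts
over sections → normalize once per brain. Fractions are therefore percent of
non-excluded positive pixels and sum to 100 exactly whenever any exist. The
default exclusion set is the injection site and its neighbors (DR, VTA, CLi,
RLi) plus olfactory bulb and cerebellum; the shipped
`data/region_groups.csv` provides an editable region → subdivision grouping.

## Axon density (axonmap)

Background subtraction is a white top-hat with a disk footprint (default
radius 5 px ≈ 5× the rendered fiber width), which removes constant offsets
and slowly varying background exactly while passing structures narrower than
the disk. Binarization uses a single scalar threshold that must be held
constant across all samples in a comparison set — the pipeline raises
`ThresholdMismatchError` otherwise, because between-group coverage
comparisons are meaningless across thresholds. Coverage is exact integer
pixel arithmetic reported to two decimals. Known limitation: in dense fields
(coverage ≳ 0.4) the top-hat begins to suppress the interiors of wide fiber
bundles and coverage saturates — a ceiling effect of the same kind expected
in strongly innervated regions of real data; recovery was verified at ±3
percentage points for coverage ≈ 0.25 (the regime the benchmarks model).

## EPSC analysis (ephys)

Cells are voltage clamped at −70 mV, so EPSCs are inward; amplitudes are
reported as magnitudes. The mean of the first 10 sweeps is baseline-
subtracted using the 50 ms pre-stimulus window (ending 1 ms before onset),
and the peak negative deflection is taken over the window open at stimulus
onset and closed at onset + 50 ms, ties broken to the earliest sample. The
5 ms light pulse lies inside the window; optional 1 ms artifact blanking is
off by default. The responder criterion is a fixed absolute 10 pA floor
(strict inequality), not per-cell sd-scaled, because the source procedure
states a single number. Drug-block comparisons pair amplitudes per cell and
delegate to the paired *t*-test in the stats layer.

## Statistics (stats)

`welch_t_from_summaries` computes t = (m₁ − m₂)/√(SEM₁² + SEM₂²) with
Welch–Satterthwaite df = (SEM₁² + SEM₂²)² / (SEM₁⁴/(n₁−1) + SEM₂⁴/(n₂−1)),
identical to a raw-data Welch test when the summaries come from the samples;
it exists because grouped anatomy data are often only available as
mean ± SEM. The variance gate is a Spearman rank correlation of |residuals|
against fitted values (tie-degenerate inputs report ρ = 0, p = 1). Box-Cox λ
is the profile-likelihood MLE found by a 0.01-step grid scan over [−3, 3]
followed by bounded local refinement; inputs must be strictly positive.
Two-way ANOVA uses Type-II sums of squares (configurable); for the balanced
designs this workflow produces, Type I/II/III coincide, and effect F is
reported as 0 when the effect sum of squares vanishes even if the residual
is also zero (noise-free constructions). Benjamini–Hochberg is the standard
step-up adjustment with output in input order; families are adjusted
together via `adjust_family`. Stars follow 0.05/0.01/0.001.

## Synthetic data (synth)

The generator emulates the structure of the study data, not its optics:

* **Sections** — somata are disks with diameter ~N(15, 1) µm clipped to
  ±3 sd, placed by dart-throwing with a hard-core minimum distance of
  1.2 × the *maximum* clipped diameter. The hard-core is deliberately set on
  the maximum rather than the mean: with sampled diameters, spacing somata
  by the mean still permits touching pairs of above-average cells, which
  produce merged components no threshold can split and make planted counts
  unrecoverable; spacing by the maximum guarantees a blur-separable gap, so
  counting benchmarks test the counting logic rather than a packing
  artifact. Each cell appears in the reporter channel and, with the planted
  per-subregion probability, in the marker channel. Rendering is disk →
  Gaussian blur (σ = 1 px, a PSF stand-in) → additive Gaussian noise
  (sd 0.02 on [0, 1]); Poisson shot noise is omitted because the
  threshold-based logic is insensitive to the noise family at these SNRs.
  Neurite clutter is rendered as 1–2 px random-walk strokes at intensity
  midway between background and foreground (0.2 strokes per 10⁴ µm² by
  default), so it is removable by the area gate, not only by threshold.
* **Brain series** — regions tile each section as 150 × 150 px blocks;
  planted neurons are split near-evenly across sections and placed only in
  their region; artifacts are bright squares with their true polygons
  reported so artifact removal can be tested exactly.
* **Axon fields** — strokes accumulate until the pre-blur mask reaches the
  coverage target; truth coverage is counted from that mask, so it is exact.
* **Sweeps** — EPSCs are difference-of-exponentials kernels
  (τ_rise 1 ms, τ_decay 10 ms) normalized analytically to unit peak, so the
  planted magnitude equals the waveform peak; defaults are 70 ± 10 pA
  amplitude, 5 ms latency, 5 pA baseline noise, 10 sweeps at 10 kHz, and a
  post-drug condition scaling amplitude by 0.05 (the scale of a strong
  AMPA-receptor block).

Determinism is a contract: one seed drives per-object `SeedSequence`
substreams, so identical specs reproduce byte-identical images and adding
objects does not shift unrelated draws.

What the generator does **not** model: 3-D stacks, realistic PSFs, channel
bleed-through, staining variability, section-to-atlas registration error,
series-resistance artifacts. Passing benchmarks therefore demonstrate that
the quantification logic is correct under its stated assumptions — not that
the thresholds transfer to any particular microscope.

## Benchmark sizes and seeds

The shipped benchmarks use problem sizes chosen to exercise the statistics
at the scale of the emulated study while staying desk-sized: cohorts of
2 genotypes × 5 animals × 2 sections (~320 vs ~165 planted double-labeled
cells per animal at co-expression 0.95 vs 0.92), 20 seeded replicates for
the power check; a 12-region brain with planted counts spanning 5–500 over
6 sections for the input-map validation; 200 cells for responder
classification. All enter through `raphequant.experiments` and every source
of randomness flows from one seed argument.
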