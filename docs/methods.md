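# Methods

`repeatmeth` reimplements, as tested library code, the quantification stack
used to study how cell density and adherens-junction signaling modulate DNA
methylation at α-satellite repeats: image-based quantification of a
fluorescence-complementation methylation sensor, single-particle chromatin
mobility analysis, MSRE-qPCR and RT-qPCR relative quantification,
flow-cytometry readouts, and the per-biological-repeat statistics that tie
them together. Because no public datasets accompany the original
measurements, the package ships a synthetic-data generator whose documented
presets encode the reported effect sizes; every analysis stage is validated
by recovering those presets end to end.

## Synthetic data generator (`synthgen`)

**Fixed-cell scenes.** Nuclei are discs with Gaussian-smoothed edges
(radius 15–25 px), placed by rejection sampling without overlap and fully
inside the field; each carries 2–3 reporter spots, rendered as 2-D Gaussians
(σ = 2 px, integer-pixel centres, ≥4σ mutual separation) with a Gaussian
axial profile (σ_z = 1.5 slices) across the 7-slice stack so a maximum
projection recovers the full amplitude. Channel levels (arbitrary units):
DNA stain 200 inside nuclei, reporter plateau 40 inside / 10 outside,
spot amplitude 300, Gaussian read noise σ = 5 per pixel and slice. The
default lateral calibration is 0.1 µm/px (high-NA confocal); the axial step
is 0.2 µm. Disc-shaped nuclei without chromatin texture are sufficient to
exercise the segmentation contract but say nothing about performance on
textured, clumped or overlapping real nuclei — a deliberate limitation.

**Condition presets** are multiplicative constants, not hard-coded branches:

| preset | effect | value |
|---|---|---|
| `sparse` / `mock` / `none` | baseline | ×1.0 |
| `dense`, `aza_treated` | reporter spot amplitude | ×0.5 |
| `bobcat_treated` | whole within-nucleus stain intensity | ×1.5 |

For qPCR plates the presets set the true methylated fraction *f*:
MCF10A mock 0.8, drug-treated 0.4; MCF7 mock 0.7, treated 0.35; sparse 0.8
vs dense 0.55. The ×0.5 drug effect and the ×1.5 TET-inhibition effect
mirror the reported ≈50 % changes; the absolute mock fractions and the
dense–sparse gap are not reported anywhere, so they are package choices
fixed once at plausible values for heavily methylated satellite repeats
(the comparison stages only consume ratios and directions).

**Spot motion.** Brownian per-axis increments with variance 2 D Δt at
Δt = 0.1 s; observed positions add i.i.d. localization noise σ_loc. The
confined variant reflects the radial excursion from the start position at a
confinement radius. This is a truth model for recovery testing, not a claim
about chromatin physics: ensemble MSD converges to 4Dτ + 4σ_loc², and the
confined plateau is bounded by 2R² + 4σ_loc². Anomalous (fractional)
diffusion is out of scope.

**qPCR plates.** Control-amplicon Ct ~ N(baseline 24, technical σ 0.2) per
technical replicate; the MSRE amplicon is delayed by log_E(1/f) cycles —
the digestion model is all-or-nothing protection of the amplicon with one
effective fraction *f*, which is exactly identifiable from one ΔCt. A
per-site option (amplifiable fraction f^k for k sites) exists but is not
default. A per-sample input-amount shift (σ 0.5 cycles) is shared by both
amplicons of a sample and cancels in ΔCt. f = 0 produces the
"undetermined" Ct sentinel (NaN). Expression rows use a reference gene at
baseline 18 and a target offset of +6 cycles shifted by −log_E(fold).

**Flow populations.** Reporter-positive events are log-normal (ln-mean 7,
ln-σ 0.5) scaled by a shift factor, mixed with 10 % autofluorescence-like
events (ln-mean 4); the paired parental control contains only the negative
component. 10⁴ events per sample by default.

All generators are pure functions of their seed; equal seeds give
byte-identical outputs.

## Image quantification (`imagequant`)

Projections over the 7 consecutive slices: **maximum** for segmentation and
spot work, **mean** for intensity comparisons. The distinction matters: the
per-pixel maximum of n noisy slices adds a constant noise order-statistic
offset (≈1.35 σ for n = 7), which is additive and therefore dilutes
multiplicative intensity effects; the mean projection is linear and
unbiased, so the 1.5× stain preset is recovered as ≈1.5 only on the mean
projection.

Nuclei are segmented on the projected DNA channel with a global Otsu
threshold and 8-connected components; objects under 200 px² are dropped and
border-touching objects are excluded (configurable). Touching nuclei are
not split (no watershed) — the synthetic scenes are non-overlapping by
construction.

Per nucleus, the reporter spot mask is the set of pixels above
mean + k·SD of the within-nucleus reporter intensity (k = 3 default). The
threshold is per-nucleus, not per-image, which makes it robust to
between-cell expression differences. The background mask is the nuclear
remainder, and the corrected signal is the per-cell spot *mean* minus the
per-cell background *mean* — means are subtracted cell by cell, not pixel
by pixel. The corrected signal is therefore invariant under additive
offsets and scales with multiplicative gain; nuclei with an empty spot mask
keep their record with a missing value and are excluded from condition
means.

Mean nuclear area: the projection is smoothed with a Gaussian whose FWHM
equals the 10-pixel artifact diameter (σ = 10/2.355 px — the FWHM reading
is an interpretation, stated once here). The smoothed image, thresholded at
its own Otsu level, defines and counts the objects and applies the border
rule; the stained area is then measured as raw-threshold pixels inside each
retained object. Re-deriving the outline from the smoothed image would
inflate disc areas by ~30 % at this kernel size; measuring the signal on
the raw projection keeps a radius-10 disc at its analytic ~314 px². Nuclei
whose smoothed outlines merge are counted once — a limitation for heavily
clumped fields.

Coordinates are pixel-centred, origin top-left, (y, x) order, 0-based;
µm values always derive from the stack's `pixel_size`.

## Mobility analysis (`motility`)

Movies are first smoothed by a trailing moving average over 5 adjacent
frames (output frame t = mean of input frames t…t+4; length N−4; the
alignment choice is recorded in the stack metadata). Tracking is greedy
nearest-neighbour linking of per-frame detections: candidate links between
consecutive frames are sorted by distance and assigned under a maximum
displacement, which resolves crossings by minimal displacement, with
remaining ties broken deterministically by detection order. No gap closing
or merge/split handling; short fragments are discarded.

MSD uses every ordered pair within a trajectory (overlapping time origins)
and pools pairs across trajectories for the ensemble profile, weighting
each lag by its pair count; lags with zero pairs are omitted rather than
reported as zero. The implementation is checked exactly against a
brute-force double loop.

Mobility is summarised at a 1 s lag. Because "short-lag mobility" admits
two readings, both the MSD value *at* 1 s and the mean MSD over lags ≤ 1 s
are reported per trajectory; comparisons default to the value at 1 s.
Outliers are removed with the scaled-MAD rule — flag x when
|x − median| > 3 × 1.4826 × MAD — applied per condition before
aggregation. The 1.4826 constant makes the MAD consistent for a normal
distribution; when the MAD is zero, any value different from the median is
flagged (degenerate rule, pinned by a test). Diffusion fits are ordinary
least squares of MSD(τ) = 4Dτ + offset; a negative fitted D is returned
with a warning flag, never clamped.

## Molecular readouts (`qpcr`)

Enzyme sites (AciI, CCGC) are counted by an explicit sliding-window scan;
since the motif is non-palindromic, a site on the opposite strand appears
as GCGG on the given strand, and both patterns are scanned with overlaps
counted by default. Amplicon validation enforces primer presence and
orientation, ≥1 site for the MSRE target, 0 sites for the control, and the
absence of the XbaI pre-fragmentation site (TCTAGA) — the fragmentation
step is modelled only as this validity check. The genomic α-satellite
amplicon is not bundled (the printed locus coordinates lack a chromosome
name); site logic is exercised on constructed synthetic amplicons with a
known site count.

Relative methylation is E^(−ΔCt) with ΔCt = Ct(MSRE target) − Ct(control
amplicon) and E the amplification efficiency (default 2.0, configurable; no
standard-curve fitting). Technical replicates are averaged on the Ct scale
*before* exponentiation — averaging after exponentiation would give a
different (Jensen-biased) estimate, and a test pins the chosen order.
Expression uses the efficiency-corrected ΔΔCt form against a reference
gene, paired within biological repeat. Condition-level normalization is
deliberately left to `compare`.

## Flow cytometry (`cytometry`)

The positive gate is the 99.5th percentile of the parental control by
default (the gating control is specified by the assay; the percentile is a
package choice, configurable), so ~0.5 % of control events gate positive by
construction. Median fluorescence intensity is computed over gated events
by default with an all-events option. Input is CSV event tables.

## Statistics (`compare`)

The biological repeat is the unit of analysis. For each repeat the two
condition means (A_i, B_i) are normalized to their own average
m_i = (A_i+B_i)/2, giving (A_i/m_i, B_i/m_i) whose mean is exactly 1 —
a conservation property tested on random inputs. Tests are classical:
paired t on differences, pooled-variance unpaired t (Welch by flag),
one-way between/within F. The statistics are computed from closed forms,
with scipy supplying only the t/F distribution tails, so scipy's own test
functions can act as independent oracles in the suite; under a simulated
null the paired test's type-I error at α = 0.05 is verified to sit in
[0.03, 0.07] over 2000 experiments. Raw p-values are reported with the
test name and the usual star mapping; no multiple-testing correction.
Zero-variance inputs yield flagged degenerate results rather than
exceptions. The choice of paired vs unpaired test is always explicit
configuration, never inferred.

`run_pipeline` chains generator → quantification → normalization → test for
named experiments (`aza_vs_mock`, `mcf7_aza_vs_mock`, `sparse_vs_dense`,
`sparse_vs_dense_msre`, `sparse_vs_dense_msd`, `bobcat_vs_mock`), writing
`summary.json` (with seed, config hash and package version), per-stage
CSVs, and an optional dot plot. Output is byte-identical for a fixed seed.

## Problem sizes

The validation suite and the recovery script use sizes chosen to make
Monte-Carlo error small relative to the tolerances while keeping runs
interactive: 40 independent 3-repeat plates for the qPCR recovery (the
per-plate design — 3 biological × 3 technical replicates, technical σ 0.2
cycles — matches the emulated assay; one such plate alone carries ≈4.6
percentage points of sampling error, the 40-plate mean <1), 50 nuclei per
condition for the image-intensity recovery, and 500 trajectories × 100
frames for diffusion recovery.

## Known limitations

Disc nuclei without texture or overlap; no watershed splitting; no gap
closing in tracking; all-or-nothing digestion as the default MSRE model;
no FCS parsing (CSV event tables only); no photobleaching, 3-D PSFs or
anomalous diffusion in the generators. Passing recovery tests demonstrate
that the analysis stages invert the stated generative models — not that
they are robust to real-microscopy artifacts outside those models.
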