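# Methods

This note records the models, algorithms, parameter choices and known
limitations behind each module, at the level of detail a maintainer or
reviewer needs to judge what a passing test does and does not show.

## Helical symmetry model

A one-start helical filament is generated from one asymmetric unit by a
screw operator: rotation by the twist Δφ about the z axis followed by
translation by the rise Δz along it. Conventions: z is the filament
axis, the origin lies on the axis, positive twist is right-handed, all
lengths are in Å (pixels are converted only at I/O boundaries). Twist is
normalized into (−180°, 180°]; +180° and −180° denote the same operator,
which is why a filament with two subunits per turn has experimentally
undetermined handedness — the search therefore reports |twist| together
with a handedness-ambiguity flag whenever the consensus lies within the
terminal tolerance of 180°.

Derived quantities: subunits per turn `360/|Δφ|`, pitch
`Δz·360/|Δφ|`, and the axial period of the 2D projection — for a twist
of `360/m` degrees (integer m) the projected density repeats every
`m·Δz` Å (two subunits per turn → period 2Δz), otherwise the pitch is
returned with an `exact=False` flag. An observed projection period *P*
constrains the rise to the candidates *P/n* for integer *n*, which seed
the parameter search.

## Synthetic data

All generators are pure functions of a specification plus a seed and are
bit-reproducible. Noise is additive white Gaussian everywhere; SNR means
signal sd / noise sd, with the signal sd measured on the noiseless
output. Contrast transfer, ice, dose and detector physics are
deliberately not modelled: every estimator in this package operates on
class-average-like images, for which white noise on a clean projection
is the appropriate abstraction. Consequently, passing recovery tests
demonstrate the correctness and statistical behaviour of the estimators,
not their robustness to CTF artefacts or to particle-picking errors.

* **Filament segments.** The asymmetric unit is a pseudo-atom model: a
  compact core hugging the axis plus a ~120 Å arm at 55° from the axis
  (the branch decoration that makes the front view tree-like and the
  side view zig-zag). Volumes are rasterized with trilinear deposition
  and a 6 Å Gaussian blob profile; projections can be taken either from
  the volume (rotate + sum, used to make "data") or analytically from
  the points (used for scorer templates). Both paths share one view-
  angle convention, verified by a cross-path correlation test. Default
  study geometry: 128 px segments at 3.125 Å/px (a 400 Å box), ~200
  segments, random views over 360°, axial offsets over one rise,
  SNR 0.5.
* **Sheets.** A unit-cell motif (seeded Gaussian blobs) is p2-
  symmetrized when requested (cell = motif + its two-fold image about
  the cell origin), tiled over an oblique basis (defaults 60 × 66 Å at
  3 Å/px), warped by a smooth zero-mean Gaussian-random displacement
  field, and degraded with noise. The distortion correlation length
  defaults to 120 px (≈ 6 cells): node-wise distortion correction
  assumes the field is locally constant across one cell, and a field
  that varies faster than that is outside the method's stated validity.
  Amplitude (default for the recovery study: 1.5 px rms) and length are
  both configurable.
* **Repeat filaments.** A vertical train of Gaussian density units at a
  fixed spacing with a transverse envelope; repeats below two pixels are
  rejected (sampling limit). Study conditions: 65 Å repeat at 5 Å/px,
  SNR 0.5, 100 classes.
* **Peak lists.** Each true composition draws its windowed component
  masses uniformly within their glycoform windows, adds one linker
  adduct per link (copies − 1) and optional Gaussian jitter.

## Twist/rise search

The search reproduces the published protocol logic: window centers tile
160–200° and 60–70 Å with ±5° / ±2.5 Å half-widths and 50% overlap; each
window is refined independently — grid-evaluate (11 × 11 samples), then
if the optimum is interior re-center on it and halve window and step,
else shift the window toward the edge at constant width (at most 8
shifts before the run is declared edge-stuck); refinement stops at
terminal half-widths ±0.5° / ±0.25 Å. Ties on the grid break toward the
window center (twist first), making results deterministic. The consensus
is the modal cluster of converged window results (clustered within twice
the terminal grid step), summarized by its median.

The score is an explicit surrogate for full Bayesian helical
reconstruction, which is out of scope: the mean, over segments, of the
best normalized cross-correlation between the segment and noiseless
projections of a candidate-symmetrized template filament, maximized over
a bank of 24 view angles and all axial shifts (segments are assumed
laterally centered and rotationally pre-aligned, which the generator
guarantees). Scoring uses up to 128 segments and runs on 2× binned
images (6.25 Å/px): the 6 Å blob width makes finer sampling pure cost,
and binning equalizes the interpolation footprints of the two rendering
paths. A template-free shift-mirror score (correlate each image shifted
by the candidate rise with its mirror about the axis) is provided for
the special geometry near |twist| = 180°, where it scores the rise only;
its validity domain is enforced.

Accuracy at the study conditions (200 segments, SNR 0.5): across seeds
the consensus lands within ±0.4° of the true twist magnitude and within
±0.1 Å of the true rise; the acceptance test requires ±0.5° / ±0.25 Å.
The layer-line estimator sums power over a narrow meridional band
(default h/16 columns) because layer-line signal concentrates there
while white noise does not; its peak must exceed 5× the median profile
level, which rejects pure-noise stacks.

## Correlation averaging and the phase residual

Unit cells are located by normalized cross-correlation against a
low-pass-filtered reference patch; peaks need to clear both half the
global maximum and a null floor of `8/sqrt(patch pixels)` (the null NCC
sd is ≈ `1/sqrt(patch pixels)`), with non-maximum suppression.
Lattice fitting seeds a basis from clustered nearest-neighbor difference
vectors, Lagrange-reduces it, and refines basis + origin by linear least
squares with iterative outlier rejection; the rejection cap derives from
the lower quartile of displacement norms so that up to half the peaks
may be spurious without corrupting the fit. Two failure modes of real
correlation maps are handled explicitly: (i) a near-centrosymmetric
motif produces secondary maxima halfway between nodes — if the first fit
is poor, small integer recombinations of the basis are tried and the one
that indexes the most peaks within 1 px wins; (ii) when correlation
heights are available, a pseudo-centered solution is detected by the
even/odd (i+j) index-parity split and resolved toward the stronger
class. Surviving per-node residuals are the distortion field.

Averaging re-samples each cell on an n × n grid of fractional lattice
coordinates centered at the *observed* (displaced) node position
(bicubic interpolation) — this is what corrects the smooth distortion —
and averages. The averaged cell is periodic by construction, so its DFT
samples the crystallographic reflections (h, k) directly; reflections
within the resolution limit (default 1/14 Å⁻¹) enter the phase residual:
the amplitude-weighted mean circular distance of phases from the nearest
centric value (0°/180°), minimized over a coarse-to-fine origin search
covering half the unit cell (two-fold points repeat every half period).
Amplitude weighting is the headline statistic because weak reflections
carry noise-dominated phases; the unweighted value is always reported
alongside. p2 symmetrization (averaging the cell with its two-fold image
about the refined origin, done exactly in Fourier space) is applied only
when the residual passes the acceptance threshold, 25° by default.

Calibration facts the tests pin down: a genuine p2 average scores ≈ 0–2°;
uniformly random phases score 45° in expectation at a fixed origin; the
full statistic on a phase-randomized cell sits lower (≈ 25–40°) because
origin refinement over a finite reflection set (~30 reflections at the
default geometry) can partially adapt to noise — the p2 decision is
nevertheless unambiguous because genuine symmetry scores more than an
order of magnitude below the random floor. The fitted lattice frame is
determined only up to the dihedral ambiguity of indexing (hand and axis
order), so comparisons against ground truth are taken over the eight
dihedral placements.

## Cross-link stoichiometry

A composition (integer counts per component) occupies the mass interval
`[Σ counts·lo + links·adduct, Σ counts·hi + links·adduct]` with
`links = total copies − 1`; a peak is feasible for a composition when it
falls inside the interval widened by the tolerance. Enumeration is
exhaustive over per-component count bounds (default 4 per component —
the largest assigned complex has five copies total), in lexicographic
order. Because the printed complexes never reveal *which* ZI-1,2 half
participates, "k halves" is modelled as the envelope interval
[k·17,846.13, k·18,706.26] Da; the exact two-component version (ZP-N
half, ZP-C half as point masses) is also provided and is what pins the
published heterotrimer interval 73,111.93–76,353.95 Da. The
cross-linker adduct mass defaults to 0 Da (configurable): the published
assignments absorb it into the ZI-3 glycoform window, and the DSS adduct
(~138 Da per link) is small against that window's ~3.2 kDa width.
Tolerance defaults to 0 Da when components carry windows. The printed
768,038.12 Da peak is taken as printed and reported as having no
feasible composition (its published interpretation, two ZI-3 copies,
corresponds to ~73–80 kDa; the entry is almost certainly a
typographical artefact, and silently correcting inputs is worse than
reporting the discrepancy). Spacing analysis expresses consecutive peak
differences as k × m with integer k ≥ 1 and m inside a reference window,
smallest k first.

## Repeat measurement

The image is rotated so the filament axis (from intensity second
moments, unless given) is vertical, and projected onto the axis with
columns weighted by the smoothed transverse intensity envelope — a
matched filter that stops empty background from diluting the repeat
signal. The repeat is the lag of the first off-origin local maximum of
the normalized autocorrelation above a prominence threshold (default
0.45, calibrated so that noise-only classes — whose spurious maxima stay
below ≈ 0.39 — are excluded while SNR-0.5 classes — whose true peaks stay
above ≈ 0.58 — are kept), refined to sub-sample precision by parabolic
interpolation. Aggregation reports mean, sd, and the number of excluded
classes; measuring by autocorrelation instead of manual peak-to-peak
picking in an image viewer is a deliberate methodological substitution
for reproducibility. The estimator carries a small negative bias
(≈ −0.5 Å at the study conditions, well within the one-pixel
acceptance), from the decaying autocorrelation envelope at finite
profile length.

## Interface metrics

SASA is Shrake–Rupley sphere sampling: each atom inflated by the probe
radius (default 1.4 Å), sampled with a Fibonacci point set (default 960
points, which keeps a single sphere within ~0.3% of the analytic area),
points covered by any neighboring inflated atom discounted. Standard
van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å);
unknown elements fall back to carbon. Buried area between selections is
the two-sided `SASA(A)+SASA(B)−SASA(A∪B)` (the headline number, matching
the published magnitude), with the one-sided half reported alongside.
Filament context is built by `expand_filament`, which places symmetry
copies of a reference selection with chain ids suffixed `@k`; the buried
fraction of the central subunit is `1 − SASA(central in context) /
SASA(central alone)`. Selections use author chain ids and inclusive
author residue numbering. For the published linker-belt interface the
default linker selection is chain A residues 430–465 — the 13-residue
α1β strand (D430–M442) through β1, bounded by the deposited chain split
at S444 and the ZP-C start P466 — configurable because the published
figure does not print the linker's residue bounds.

The deposited coordinates themselves (PDB 6TQK/6TQL, precursor 4WRN)
are not distributed with this repository; the machinery is exercised on
a synthetic interlocking subunit (a gently winding strand spanning just
over two rises, built so that |Δk| ≤ 2 symmetry copies make contacts
without clashes) and picks up the real model automatically from
`data/deposited/6tqk.cif` when present.

## Problem sizes

The recovery studies are desk-scale by design: ~200 segments for the
symmetry search (the published reconstruction pooled hundreds of
thousands of segments, but also ran its initial parameter search on a
small topology subset; what is reproduced here is the search protocol,
not the reconstruction), 100 classes for the repeat study (matching the
~100 published measurements), and one ≥ 15 × 15-cell sheet for the
averaging study. A full acceptance pass
(`python scripts/acceptance.py --seed 1 --out results/acceptance.json`)
runs in about a minute on one CPU.

## Known limitations

- The template scorer assumes laterally centered, rotationally
  pre-aligned segments and knowledge of the template shape; it is a
  parameter-recovery surrogate, not a reconstruction engine, and its
  absolute score values are not comparable across templates.
- White-noise images only; no CTF, so the layer-line estimator's
  contrast thresholds do not transfer to raw micrographs.
- Only plane groups p1 and p2 are supported; no tilt geometry.
- The stoichiometry solver treats glycoform windows as contiguous
  intervals, which is exact for feasibility but cannot rank candidate
  compositions by likelihood within a window.
- SASA ignores hydrogens unless present in the model and uses a single
  radius per element (no residue-specific typing).
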