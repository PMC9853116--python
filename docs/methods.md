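# Methods

## Ion chemistry and mass conventions

All catalog species are singly charged positive ions built from two neutral
molecules — the boron carrier drug BPA (C₉H₁₂BNO₄) and the MALDI matrix DHB
(C₇H₆O₄) — by a recipe of the form *bases − n·H₂O + charge carrier*. The
carriers are protonation (+H, charge), sodiation (+Na), potassiation (+K),
hydrogen–dipotassium exchange (−H+2K) and plain electron loss (for the
radical fragment [DHB−H₂O]⁺˙ and the bare Na⁺/K⁺ ions). The ion *m/z* is the
sum of principal-isotope atomic masses of the cation's atoms minus one
electron mass. Two consequences worth stating explicitly:

- Protonation therefore adds a *proton* mass (1.00728 Da), not a hydrogen
  *atom* mass; using the atom mass would shift every protonated species up
  by 0.55 mDa and round [BPA+H]⁺ to 210.094 instead of 210.093.
- "Monoisotopic" means the *most abundant* isotope of each element. For
  boron that is ¹¹B, which is the heavier of its two isotopes; summing
  lightest isotopes would misplace every boron species by ~1 Da.

Atomic masses and abundances are the standard IUPAC/CIAAW values, entered to
5–8 decimals. Potassium is carried as the full ³⁹K/⁴⁰K/⁴¹K triple so that
abundances sum to one exactly.

Two catalog entries ([BPA+2DHB−2H₂O+H]⁺ at 464.115 and [BPA+2DHB−H₂O+H]⁺ at
482.126) have published *m/z* values that plain base-sum − *n*·H₂O arithmetic
cannot reproduce (each matches its label with one extra water removed). They
are kept at their published values, flagged `printed`, and excluded from all
arithmetic checks and theory-table ratio output.

## Fine-structure isotope patterns and pooling

The fine-structure engine enumerates, per element, every multinomial isotope
composition of its *n* atoms and convolves the per-element distributions
across elements, keeping isotopologues down to 10⁻⁶ of the most probable
line (raw probabilities are preserved, so returned + pruned lines sum to 1).
For every catalog species this enumeration is exhaustive (≤ ~150 k states);
the probability floor only truncates the reported line list. An independent
per-atom enumeration oracle (outer product over individual atoms) checks the
engine to 10⁻¹² in the tests.

A finite-resolution instrument cannot separate isotopologues a few mDa
apart, and the ion images integrate a 0.02 Da window, so printable isotope
ratios pool fine-structure lines whose consecutive gaps are strictly less
than 0.02 Da (probability sum; probability-weighted centroid; base cluster
normalised to 100). This pooling is load-bearing for boron species: the
¹⁰B+¹³C isotopologue lies 7 mDa *above* the all-light line and merges into
the base peak, and for potassium adducts ¹⁰B+⁴¹K lands 1.7 mDa from ¹³C and
merges into M+1. With it, the calculated clusters come out 24/100/10 for
[BPA+H]⁺, 24/100/18 for the sodiated drug–matrix complex and 24/100/20 for
the potassiated one. Report tables round *m/z* half-up to 3 decimals and
ratios to integer percent.

## The synthetic section (phantom)

The phantom emulates the measured tissue section, not an idealised sample.
On a 40×30 grid of 60 μm pixels it defines nested regions (brain ellipse ⊃
cortex band ⊃ nothing; brain ⊃ tumor ellipse ⊃ hotspot ellipse; nesting is
validated) and gives every signal source a per-region abundance: BPA-bearing
species only inside the tumor with a 3× hotspot, matrix species brain-wide,
potassium-dependent species elevated in the tumor, sodium diffuse, and four
single-line isobars flanking the drug at 209.914 (brain-wide) and 210.026 /
210.063 / 210.098 (tumor-shaped, as their images trace the tumor outline).
The tumor-level drug apex is 1/3 of the tallest neighbouring interference
(100 vs 300 intensity units at 210.098).

**Apparent positions.** On tissue the drug species were observed displaced
from their calculated *m/z* (−9, −7, +6, +4 mDa for [BPA+H]⁺, [BPA−H₂O+Na]⁺
and the sodiated/potassiated complexes), an effect attributed to overlap
with adjacent peaks. The phantom renders each BPA species at that observed
position via a configurable apparent-shift (default −9.2 mDa for [BPA+H]⁺,
placing its pooled base cluster at 210.0840). Rendering at the *calculated*
position instead would put the drug 4.8 mDa below the 210.098 isobar — less
than half a peak width at *R* = 20,000 — and the five-peak cluster of the
measured spectrum could not exist. The displacement is therefore an input to
the simulation, not a prediction of it.

**Forward model.** Each line becomes a Gaussian of FWHM *m/R(m)* centred at
*line m/z × (1 + drift·10⁻⁶)*, height = abundance × relative line height.
The resolution model is *R(m) = R₀(m/210)^e* with *R₀* = 20,000; the default
acquisition range (*m/z* 205–550) uses *e* = 0 (constant *R*), the low-mass
preset (*m/z* 20–215, lock [DHB+K]⁺ 192.990) uses *e* = 1, i.e. constant
absolute width, so one uniform axis can carry Na⁺ at 23 and the 210 cluster
alike. The axis is uniform with spacing FWHM(range minimum)/10, giving ≥ 10
samples per peak width everywhere (the renderer refuses < 6). Per-pixel
drift is uniform in ±30 ppm — chosen to dwarf the ≤ 43 ppm scale of the
tissue observations so that correction is genuinely exercised — and a flat
chemical baseline (1 unit) plus scaled-Poisson noise (scale 0.04, SNR ≈ 50
at the tumor drug apex) complete the model. One seeded generator drives
drift and noise in row-major pixel order; a config + seed is
bit-reproducible. Datasets round-trip through continuous-mode imzML 1.1
(float64 axis, float32 intensities, 1-based coordinates on disk).

What the phantom does *not* model: matrix-crystal heterogeneity, ionization
suppression differences between tumor and cortex (the reason the source
study defers T/N quantification), peak-shape asymmetry, detector saturation,
and any molecular identity for the interferences. Passing tests therefore
demonstrate the correctness of the analysis chain on data obeying the stated
forward model, not instrument-grade robustness.

## Lock-mass recalibration

One matrix ion of known *m/z* per spectrum ([DHB−H+2K]⁺, or [DHB+K]⁺ in the
low-mass range) is located within ±0.2 Da — tallest local maximum above 3×
the window's median intensity; ties go to the candidate nearest the
theoretical position — and centroided by a three-point parabola on log
intensity (exact for sampled Gaussians). The correction is the single-point
multiplicative factor theoretical/observed applied to the axis, the minimal
model one lock ion supports and closed under composition; corrections beyond
±500 ppm are rejected as mis-identification. Corrected spectra are resampled
back onto the shared axis by linear interpolation (axis spacing is 10
points/FWHM, so interpolation error is far below noise). Spectra without a
credible lock peak are kept unchanged and flagged, never dropped. The lock
uses the *exact* theoretical mass (230.945637), not the printed 230.946:
using the 3-decimal print would bias every unit by 1.6 ppm. Both per-pixel
and per-ROI scopes are provided, since the source protocol calibrated
ROI-averaged spectra and either scope is defensible.

## Imaging and measurement

ROI mean spectra are arithmetic means over member pixels on the shared axis.
Peak picking takes local maxima above *min_snr* × a robust noise floor
(1.4826 × median |I| over a declared signal-free segment, default *m/z*
218–221 in the default scene), centroids by the log-parabola and measures
FWHM by linear interpolation at half apex. Ion images sum profile intensity
over half-open windows [c−w/2, c+w/2) — half-open so adjacent windows are
exactly partition-additive — with optional TIC normalisation (default none,
matching raw-contrast display). For centroiding a peak with known close
neighbours (the drug at 210.084 between isobars at 210.063 and 210.098), the
package provides an overlap-corrected estimator: least-squares fit of
fixed-width Gaussians (instrumental FWHM) at the known component positions
plus a flat base. The plain apex parabola carries a ~4 ppm pull from the 3×
taller isobar 14 mDa away; the multi-component fit reduces this below 2 ppm,
which is what per-pixel drift-recovery is measured with.

## Annotation

Assignment is nearest-|Δm| within a 10 mDa tolerance (covering the 9 mDa
worst case observed on tissue); when several species fall inside tolerance,
isotope-ratio agreement arbitrates, and if the two best isotope scores
differ by under 1 percentage point the peak is reported `ambiguous` rather
than silently resolved. Isotope verification compares windowed intensity
sums at each pooled line (≥ 1 % relative, the printed-table scale) against
the calculated pattern; < 3 points of deviation is the plausibility envelope
used for tissue-scale noise. MS/MS product lists are matched at ±0.5 Da —
product masses are reported nominally — against named fragment ions (Na⁺,
K⁺, [DHB−H₂O]⁺ at exact 136.0155, [DHB−H₂O+K]⁺, [BPA−H₂O+Na]⁺, [BPA−H₂O+K]⁺)
and, failing that, against precursor − loss for the two characteristic
neutral losses, dehydrated matrix (C₇H₄O₃, 136.016) and dehydrated drug
(C₉H₁₀BNO₃, 191.075).

## Problem sizes and reproducibility

The default scene simulates ~740 in-brain pixels over *m/z* 205–550 (337 k
axis points). The test suite runs the same scene restricted to *m/z* 205–235
— every analysis target (the 210 cluster, the 214/230 adducts, the lock at
230.946) lies in that span — and uses *m/z* 205–215 for the resolving-power
contrast (*R* = 2,000 vs 20,000) and the standard-spotting scenario; these
are the package's chosen test problem sizes. `scripts/acceptance.py`
recomputes the theoretical mass and isotope-ratio table values from the
molecular formulas alone; they are deterministic, and the `--seed` argument
seeds the (here unused) stochastic machinery for uniformity with the rest of
the tooling. All pipeline randomness flows from the single phantom seed.

## Known limitations

- The multiplicative single-point calibration cannot correct axis
  *nonlinearity*; with one lock ion per spectrum nothing richer is
  identifiable.
- Isotope-ratio verification uses fixed 0.02 Da windows and inherits any
  residual centroid displacement; the `mz_shift` argument compensates only
  when the displacement is known or measured.
- The assignment tolerance deliberately admits the 210.098 isobar as a
  (wrong) [BPA+H]⁺ match at +4.8 mDa when only mass error is available —
  with the tissue displacement, calculated 210.093 sits between the true
  drug peak and the isobar. The isotope-score arbitration and the spotting
  experiment, not mass error alone, are the discriminating evidence, as in
  the source protocol.
- Image PNG export scales each image to its own maximum (16-bit grayscale);
  quantitative comparisons should use the TSV values, not the PNGs.
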