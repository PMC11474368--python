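# Methods

## Angular geometry

All angles live on the TSNIT circle: 0° temporal, 90° superior, 180° nasal,
270° inferior, with every eye internally in right-eye format. This is the
only convention under which the canonical landmark angles (superotemporal
≈ 45°, inferotemporal ≈ 322.5°, vertical poles ≈ 75°–90° / 270°–285°) read
the same for both eyes. Device-native TSNIT exports are laterality-neutral
and load as-is; data in absolute screen orientation are mirrored about the
vertical axis (θ → 180° − θ) for left eyes.

The circumpapillary RNFL profile has 768 A-scans at 360/768 = 0.46875°
spacing; the 24 radial B-scans yield 48 BMO-MRW values at 7.5° spacing.
Each of the 48 sectors averages the 16 contiguous A-scans whose angles fall
in the half-open window [7.5k − 3.75°, 7.5k + 3.75°) centred on radial cut
k — a strict partition of the 768 A-scans. A-scan 0 is anchored at the
temporal cut (0°); whether the device applies an additional fovea–BMO axis
rotation is not documented, so the phase is exposed as
`SectorGrid(phase_offset_deg=...)` with default 0.

Analysis is restricted to the 37 sectors from 225° through temporal 0° to
135°, both endpoints inclusive (the temporal 180° plus the superonasal and
inferonasal 45°); the 11 nasal sectors 142.5°–217.5° are excluded as noisy
and less clinically relevant.

Missing A-scans (NaN) propagate to a per-sector missing flag with a count;
nothing is imputed, because silent fill would bias the screen. Sectors with
missing data are dropped per sector, not per eye — whole low-quality
sessions are already removed by QC.

## Normative percentile bands

Device normative databases are proprietary, so the package ships a
parametric stand-in and accepts per-angle threshold tables
(`angle_deg,p1_um,p5_um` CSV). The stand-in models the healthy population
at each sector angle as Gaussian with an angle-dependent mean and constant
dispersion:

* mean curve: level + Σ harmonics; the RNFL default is
  98 + 35·cos(2(θ − 90°)) µm — the double-hump TSNIT shape with ~63 µm
  temporal/nasal troughs and ~133 µm superior/inferior peaks; the BMO-MRW
  default is 300 + 30·cos(2(θ − 90°)) µm;
* dispersion: 16 µm (RNFL) and 50 µm (MRW) between-subject SD;
* thresholds: p = mean + z·SD with z at the 1st/5th standard-normal
  quantiles, clamped at a small positive floor;
* age: linear shift, slope −0.2 µm/yr (RNFL) and −1.0 µm/yr (MRW) about a
  reference age of 55 years.

These defaults reproduce the qualitative behaviour that motivates the
two-stage design: a 70 µm RNFL value classifies red (< 1st percentile) at a
superotemporal cut but green (> 5th) at a temporal cut. Classification
boundaries: red iff value < p1; a value exactly at p1 is "greater than
first percentile", hence yellow; green iff value ≥ p5. BMO-area or
refraction adjustment of the norms is out of scope.

## The two-stage screen

Stage 1 groups each analysed sector's pair by fixed cutoffs — RNFL high
≥ 65 / low ≤ 50 µm, MRW high ≥ 130 / low ≤ 100 µm; values inside the open
gaps (50, 65) and (100, 130) are deliberately ungrouped, so they are never
mismatch candidates. Only the discordant groups 2 (high MRW, low RNFL) and
4 (high RNFL, low MRW) reach stage 2, which confirms a true mismatch iff
the low member classifies red while the counterpart does not (yellow or
green). Both-red sectors — plausibly both at measurement floor — are never
mismatches, and the concordant groups are never re-examined: the design is
specificity-first. Classification uses the sector-averaged values.

## Prevalence and attribution

Prevalence maps count records per analysed angle; peak occurrence is
reported as a fraction *of that mismatch type* (not of all sectors), with
ties returned in TSNIT wedge order. Adjacency means consecutive 7.5°
sectors; separations are shortest circular arcs. Attribution is pure
bookkeeping over an annotation table (the cause judgement is a qualitative
image review and is not automated); retinoschisis and outer-retina
inclusion fold into "other" for the 3-column published view, and row
percentages are reported to one decimal.

## Synthetic cohort generator

The generator is a forward model of the mismatch mechanisms; its defaults
are the study conditions used by the tests and the acceptance script.

**Disease.** Stage mix 56/23/21% early/moderate/advanced, severity S drawn
uniformly within (0.15–0.5)/(0.5–0.75)/(0.75–0.98) per stage. Each eye gets
one or two arcuate wedge defects (centres von Mises around 67.5°/292.5°,
κ = 4; plateau half-width 15–45° with 10° raised-cosine shoulders; depth
S + U(0, 0.35) clipped to 1) plus a diffuse component of 0.3 × depth.
Thickness follows a floor model: floor + (mean − floor)(1 − sev)^γ with
floors 42 µm (RNFL) and 65 µm (MRW) and γ = 1.0 (RNFL) vs 1.6 (MRW) — the
rim collapses toward its floor faster, which is what makes deep defects
reach the MRW ≤ 100 µm band while vessel-supported RNFL stays high. The
plateau-shaped defects also keep clean sector values away from the screen's
numeric cutoffs except in narrow shoulder zones, which is what bounds the
noise-induced error rate below.

**Artifacts.** Large arcade vessels: one per vertical pole (trajectory von
Mises around 82.5°/277.5°, κ = 75) plus Poisson(0.5) extras; each adds a
Gaussian bump to the RNFL profile at its trajectory (peak 100–150 µm,
σ = 2–3°, i.e. the full vessel diameter enters the segmentation) and a
five-times-smaller bump to the MRW at its ONH insertion, offset by a signed
angular deviation of ~12 ± 4°. Small circumlinear vessels: one near 45° and
one near 322.5° (κ = 40) plus extras, adding an MRW-only bump
(peak 150–210 µm, σ = 6°). Retinoschisis (rate 0.06/eye) and outer-retina
inclusion (0.12/eye) add focal MRW-only thickening at uniform analysed
angles. Magnitudes are order-of-magnitude anatomical choices, all exposed
in `CohortConfig`.

**Noise and QC metadata.** Independent Gaussian noise per RNFL A-scan
(SD 2 µm; sector averaging reduces this to 0.5 µm) and per MRW cut
(SD 3 µm, a repeatability-level figure). 15% of eyes receive a contiguous
missing-data run of up to 14% of the circle (blink-like); quality factor
~ N(25, 5), ages ~ N(68.1, 9.1) clipped to 40–80, BMO area ~ N(1.92, 0.48)
mm², ~1.6 eyes per patient.

**Ground truth.** Expected mismatch labels are computed by running the
screen definition analytically on the *noiseless* sector values with the
same bands and the eye's age, so recovery tests separate screen defects
from noise effects. Under the defaults the full pipeline recovers ≥ 95% of
truth-labelled sectors with < 1% false positives (measured over screened
sectors: QC-passing eyes, non-missing sectors), detected peaks fall within
one sector of the injected centres, and the detected mismatch rate is
~4–5% of analysed sectors. Error budget: a sector's decision flips only
when noise carries a value across a boundary, so clean values were designed
(floors, bump magnitudes) to sit ≥ 3 noise-SD from every cutoff except in
the unavoidable wedge-shoulder transition zones.

**What the generator does not emulate.** Real vascular tree geometry,
B-scan-level segmentation errors, inter-eye correlation within patients,
BMO-area dependence of the norms, and the empirical prevalence of the
source cohort: the published 7.7% mismatch rate arises from unavailable
patient data, so passing recovery tests demonstrates correctness of the
screen and bookkeeping, not reproduction of cohort-level prevalence.

## Numerical choices and degenerate inputs

* Sector windows are half-open ([−3.75°, +3.75°)) so the 48 windows
  partition the circle with no ties.
* Ties at stage-1 cutoffs are inclusive exactly as printed (≥/≤); QC
  boundaries are strict as printed (reject iff QF < 15 or missing > 10%).
* Peak ties are returned in TSNIT wedge order rather than broken.
* A type with zero records yields zero fractions and an empty peak list;
  an empty post-QC cohort produces empty, well-formed reports.
* Band construction rejects non-monotone quantiles (p1 ≥ p5, e.g. zero
  dispersion) and floor-collapsed thresholds at configuration time.
* All randomness flows through one `numpy` Generator seeded from the
  user-supplied seed; cohorts are bit-identical for a fixed seed.

## Known limitations

* The parametric bands are a stand-in, not the device's normative data;
  absolute mismatch rates therefore depend on band configuration.
* Whether the device classifies percentiles at radial-cut resolution or on
  sector averages is unspecified upstream; this implementation classifies
  the sector-averaged values.
* Cause attribution requires an annotation table; no vessel detection is
  performed on images.
* Longitudinal (visit-over-visit) analysis is out of scope.
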