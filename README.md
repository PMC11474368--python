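# onhmismatch

Sectoral mismatch screening between the two OCT structural biomarkers used
to monitor glaucoma: circumpapillary retinal nerve fiber layer thickness
(RNFL) and Bruch's membrane opening minimum rim width (BMO-MRW).

## The problem

Both biomarkers track the loss of retinal ganglion cell axons, and in eyes
with established glaucoma they usually agree. But in a minority of sectors
around the optic nerve head (ONH) they disagree sharply — one parameter
sits below the 1st normative percentile while the other is still in the
normal range. These *true mismatches* matter for progression monitoring:
they are caused not by disease but by anatomy — large arcade vessels
thickening the RNFL near the vertical poles, small circumlinear vessels,
focal retinoschisis or outer-retinal-layer inclusion thickening the
BMO-MRW — and by the two parameters reaching different measurement floors.

This package implements the full analysis as a tested, reusable pipeline
for per-eye thickness exports (a 768-point circumpapillary RNFL profile and
48 radial BMO-MRW values, both in µm):

1. **geometry** — TSNIT angular convention (0° temporal, right-eye format),
   averaging the 768 A-scans into 48 sectors of 16 (centred on the radial
   cuts at 7.5° spacing), and the 37-sector analysis wedge from 225°
   through 0° to 135° that excludes the noisy nasal 90°;
2. **normative** — per-angle 1st/5th percentile bands (parametric stand-in
   or user-supplied tables) and red/yellow/green TSNIT classification;
3. **screening** — the two-stage screen: numeric grouping
   (group 1: RNFL ≥ 65 µm and MRW ≥ 130 µm; group 2: RNFL ≤ 50, MRW ≥ 130;
   group 3: both low; group 4: RNFL ≥ 65, MRW ≤ 100), then percentile
   confirmation: a sector is a true mismatch iff the low member of the pair
   is below the 1st percentile (red) while its counterpart is not;
4. **prevalence** — per-angle polar maps, peak angles and same-eye
   co-occurrence of the two mismatch types;
5. **attribution** — cause cross-tabulation (large/small vessels,
   retinoschisis, outer-retina inclusion, other) over annotation tables;
6. **synthetic** — a seedable cohort generator that forward-models the
   mismatch mechanisms with full ground truth, so every stage is testable
   without patient data;
7. **io / cli** — CSV contracts, session QC (reject if quality factor < 15
   or > 10% missing data), and an `onhmismatch` command-line driver.

The transform/predict-shaped stages are scikit-learn estimators
(`SectorAverager`, `TwoStageMismatchScreen`) and compose with sklearn
pipelines; module-level functions wrap them.

## Worked example

```python
import onhmismatch as om
from onhmismatch.prevalence import build_prevalence, peak_angles
from onhmismatch.screening import MismatchType

eyes, truth = om.generate_cohort(om.CohortConfig(n_eyes=100), seed=1)
kept, rejected = om.apply_qc(eyes)
bands_rnfl = om.build_default_bands("RNFL")
bands_mrw = om.build_default_bands("BMO_MRW")
results = [om.screen_eye(eye, bands_rnfl, bands_mrw) for eye in kept]
records = [r for res in results for r in res.records]
pmap = build_prevalence(records, cohort_size=len(kept))
```

Summarising these objects (counts, `peak_angles(pmap, t)`, and
`evaluate_recovery(results, truth)`) prints:

```text
eyes kept after QC : 97 of 100
mismatch sectors   : 134 of 3589 (3.7%)
high_mrw_low_rnfl     :  56 sectors, peak at 45.0 deg (21% of type)
high_rnfl_low_mrw     :  78 sectors, peak at 277.5 deg (21% of type)
truth recovery     : sensitivity 97.1%, false positives 0.03%
```

Three eyes failed session QC. Of the 3589 analysed sectors (37 per kept
eye), 3.7% are true mismatches. High-MRW/low-RNFL mismatches peak at 45° —
the superotemporal centre where the generator concentrates small
circumlinear vessels — and high-RNFL/low-MRW mismatches peak at 277.5°,
the inferior pole where the arcade vessels run. Screening the noisy
profiles recovers 97% of the ground-truth mismatch labels (computed on the
noiseless profiles) with almost no false positives.

The same run from the shell:

```bash
onhmismatch run-all --seed 1 --out runs/demo
```

writes the cohort, mismatch records, prevalence table, attribution tables
and a `report.json` under `runs/demo/`.

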