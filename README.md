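# petgtv

Delineating the gross tumor volume (GTV) of an esophageal tumor on PET
is a choice among algorithms: a **gradient-based edge detector** (find
the maximum negative radial SUV derivative along rays from a seed, with
an edge-continuity constraint), a **fixed 1.4-SUV threshold**, a
**30 %-of-SUVmax threshold**, or reading the **CT** by wall-size
criteria (wall ≥ 5 mm or diameter ≥ 10 mm). The choice matters twice:
it decides how well the contour tracks the true tumor extent, and — once
the contour is grown by clinical margins into a planning target volume
(PTV) and a 60 Gy plan is laid on it — how much lung and heart sit in
the dose bath.

`petgtv` implements all four delineation methods, the geometric
comparison measures (longitudinal length, volume, overlap index
OI = |GTV_PET ∩ GTV_CT|/|GTV_CT|), the planning chain
(CTV = GTV + 3 cm craniocaudal / 1 cm lateral-AP, PTV = CTV + 0.5 cm,
synthetic conformal dose, DVH metrics V_x / D_q / MLD / MHD,
HI = (D2−D98)/prescription × 100 %, CI = (Vt,ref/Vt)·(Vt,ref/Vref)) and
the cohort statistics (Pearson r, paired t-tests), and exercises them on
**synthetic digital phantoms with known ground truth**: PSF-blurred,
optionally noisy tubular tumors of known length in low-uptake
background, with an over-thickened CT wall analog. It is aimed at
readers who want the methodology of PET-vs-CT target delineation studies
as runnable, tested code.

## Worked example

```python
from petgtv import (PhantomSpec, make_tumor_phantom, segment_gradient,
                    SphereROI, segment_fixed_threshold, emulate_ct_delineation,
                    longitudinal_length, mask_volume, overlap_index)

pet, ct_like, truth = make_tumor_phantom(PhantomSpec(length_mm=60))
gtv_grad = segment_gradient(pet, pet.center())
gtv_14 = segment_fixed_threshold(pet, SphereROI(pet.center(), 50.0))
gtv_ct = emulate_ct_delineation(ct_like)

print(f"true length {truth.length_cm:.2f} cm, "
      f"gradient {longitudinal_length(gtv_grad):.2f} cm, "
      f"1.4 SUV {longitudinal_length(gtv_14):.2f} cm, "
      f"CT {longitudinal_length(gtv_ct):.2f} cm")
print(f"volumes: gradient {mask_volume(gtv_grad):.1f} cm3, "
      f"CT {mask_volume(gtv_ct):.1f} cm3, "
      f"OI(grad, CT) = {overlap_index(gtv_grad, gtv_ct):.2f}")
```

prints

```
true length 6.00 cm, gradient 5.95 cm, 1.4 SUV 6.80 cm, CT 6.80 cm
volumes: gradient 16.0 cm3, CT 42.8 cm3, OI(grad, CT) = 0.37
```

The gradient contour recovers the 6 cm tumor to within one 4.25 mm
slice; the fixed threshold (set near background) and the thickened-wall
CT reading both over-run it, and the CT volume is almost three times the
gradient volume — the over-estimation the wall-margin construction is
designed to produce.

## The analysis

Numbered drivers under `analysis/` run the study stages and write tables
under `results/`:

1. `01_generate_cohort.py` — the 10-case phantom cohort (lengths
   3.44–11.00 cm) with its ground truth.
2. `02_segment_gtvs.py` — all four delineations per case; lengths,
   volumes, overlap indices. On the default cohort the mean lengths come
   out `L_true 7.30 ± 2.41`, `L_GRAD 7.31 ± 2.44`,
   `L_1.4 = L_30%max = L_CT 8.16 ± 2.44` cm, with every gradient length
   within one slice of truth.
3. `03_plan_evaluation.py` — gradient-based vs CT-based plans per case
   on a 2.5 mm planning grid; every plan covers ≥ 95 % of its PTV at
   60 Gy with hotspot < 66 Gy.
4. `04_cohort_report.py` — the full summary: r(L_GRAD, L_true) = 0.992,
   and paired t-tests showing e.g. mean lung dose 9.85 vs 15.27 Gy and
   heart V30 19.9 % vs 40.2 % in favour of the gradient-based plan
   (p < 0.001 throughout).

The same pipeline is callable as a library (`petgtv.study.run_study`,
with YAML config support) and writes `cohort.csv`, `summary.json`,
`dvh_curves.csv` and bar-chart figure analogs.

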