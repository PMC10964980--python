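# ilamap

Automated **isochronal late activation mapping (ILAM)** for ventricular
tachycardia substrate characterization in repaired tetralogy of Fallot
(rTOF)-like right ventricles — as an open, tested pipeline over synthetic
electroanatomical maps.

## The problem

After surgical repair of tetralogy of Fallot, conducting corridors —
**anatomical isthmuses (AI)** — remain between non-conducting structures:
AI1 between the tricuspid annulus and the RV incision, AI2 between incision
and pulmonary valve, AI3 between VSD patch and pulmonary valve, AI4 between
VSD patch and tricuspid annulus.  Only *slow-conduction* isthmuses
(**SC-AI**, conduction velocity CV < 0.5 m/s) sustain re-entrant VT and are
ablation targets.  Measuring each corridor's CV is laborious; ILAM instead
annotates the **offset of the last deflection** of every bipolar
electrogram, splits the mapped activation range into **eight equal
isochrones**, and flags **deceleration zones (DZ)** — regions with **more
than 3 isochrones within a 1 cm radius** (isochronal crowding).  The claim
this package makes testable end-to-end: DZ presence identifies SC-AI.

The quantitative core, with T the total mapped activation time:

* local isochrone spatial width ≈ `v·T/8` for local speed `v`, so a 1 cm
  neighbourhood holds `> 3` isochrones roughly when `v < 6T⁻¹·80 mm/ms` —
  with T near 150 ms this lands at the 0.5 m/s SC threshold;
* corridor CV = axis length / conduction time, the conduction time being
  the LAT difference between the two sides of the isthmus (e.g. an 18 mm
  isthmus crossed in 14 ms conducts at 1.3 m/s);
* validation: confusion metrics with the F score (class imbalance),
  ROC/AUC of isochrones/cm, Spearman rho between isochrones/cm and CV.

Because no patient maps are distributable, the package ships a first-class
synthetic generator: labelled opened-RV sheets, first-arrival activation
with region-dependent CV (graph eikonal approximation), grid-catheter-like
sites with orthogonal bipole sets, multi-deflection electrograms with late
potentials, split potentials and scar attenuation, and full ground truth.

## Worked example

```python
>>> import ilamap as il
>>> il.report_cv(il.conduction_velocity(18.0, 14.0))   # 18 mm in 14 ms
1.3
>>> res = il.analyze_scenario(il.default_rtf_scenario(seed=1))
>>> res.summary["total_activation_time_ms"], res.summary["n_dz"]
(179.0, 1)
>>> il.isthmus_table(res.isthmuses)[["ai_type", "cv_m_s", "sc", "dz"]]
  ai_type  cv_m_s     sc     dz
0     AI1    1.43  False  False
1     AI2    0.47   True  False
2     AI3    0.35   True   True
3     AI4    0.79  False  False
```

The default map plants CVs of 1.25/0.4/0.15/0.8 m/s in AI1–AI4: the deeply
slow AI3 shows a deceleration zone and is classified SC; the borderline AI2
is SC by CV without crowding; the fast corridors are clean.  (Side-to-side
conduction times on multi-corridor maps are biased toward faster values
when a parallel path pre-excites the far side — see `docs/methods.md`.)

The analysis is organised as numbered drivers over the library:

| script | what it does |
| --- | --- |
| `analysis/01_simulate_map.py` | build the labelled default map + ground truth |
| `analysis/02_annotate_and_map.py` | annotate electrograms, build the 8-isochrone map |
| `analysis/03_detect_features.py` | DZs, block lines, collisions, post-ablation remap |
| `analysis/04_isthmus_table.py` | per-isthmus width/CT/CV/isochrones-per-cm table |
| `analysis/05_cohort_validation.py` | 28-corridor DZ-vs-SC validation cohort |

Each writes its tables under `results/`.  A `ilamap` CLI wraps the same
pipeline stage by stage (`ilamap run --config scenario.yaml --out dir/`).

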