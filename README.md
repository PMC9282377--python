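# tibiapipe

Micro-CT analysis of the mouse tibia for longitudinal preclinical bone
studies: rigid alignment, volume-of-interest selection below the growth
plate, densitometry with a 10×4 spatial bone-mineral-content map, standard
trabecular/cortical morphometry, voxel-based micro-finite-element
prediction of stiffness and failure load — and the precision statistics
(CV, PE, LSC, ICC) that tell you whether a measured treatment effect
exceeds what operator variability alone can produce.

It is aimed at researchers who process in vivo micro-CT scans of rodent
long bones and need a reproducible, scriptable version of the usual
operator-driven workflow, plus a way to validate every stage against known
ground truth. Since in vivo scans are rarely shareable, the package
includes a synthetic tibia phantom generator (curved superellipse shaft,
growth plate, trabecular lattice, fibula, known calibration and noise) and
an in-silico intra-operator experiment that reproduces the layout of a
reproducibility study: subjects × repetitions → PE/LSC/ICC per parameter.

## The measurements

For the VOI spanning 80% of the tibia length below the growth plate
(fibula excluded):

- **Densitometry** — TMD = slope·grey + intercept [mgHA/cc], per-voxel
  BMC = TMD·V_voxel; totals (BMC, BMD, TMD, BV, TV, BV/TV, cross-section
  areas) and BMC in 40 partitions (10 longitudinal sections × anterior/
  medial/posterior/lateral quadrants about the slice centroid).
- **Morphometry** — Tb.BV/TV, Tb.Th, Tb.Sp (inscribed-sphere), Tb.N,
  Conn.D (Euler characteristic of the cubical complex), DA (MIL fabric
  ellipsoid), Tt.Ar, Ct.Ar, Ct.Ar/Tt.Ar, Ct.Th.
- **Micro-FE** — 8-node hexahedron per bone voxel, E = 14.8 GPa, ν = 0.3;
  uniaxial compression (distal end fixed, 0.1 mm axial displacement on the
  proximal surface); apparent stiffness [N/mm] and failure load [N] from
  the criterion "10% of nodes reach ε₃ = −14 420 µε".
- **Precision** — per subject CV = SD/µ; PE = √(Σ CVⱼ²/m)·100%;
  LSC = PE·1.96·√(1/n₁+1/n₂) (= 2.4005·PE for n₁=1, n₂=2); ICC(2,1)
  (two-way random, absolute agreement, single measures).

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

```python
import numpy as np
from tibiapipe import PhantomSpec, generate_tibia
from tibiapipe.pipeline import AnalysisConfig, analyze_image

spec = PhantomSpec.coarse()            # 5.2 mm tibia, 0.040 mm voxels
image, truth = generate_tibia(spec, seed=1)

config = AnalysisConfig(junction_zrange=truth.junction_zrange,
                        closing_radius_px=3)
record = analyze_image(image, start_slice=truth.voi_start_slice, config=config)

d = record.densitometric
print(f"L        {d['L']:.2f} mm")
print(f"Tot BMC  {d['Tot BMC']:.4f} mg   (truth {truth.true_total_bmc:.4f})")
print(f"Tot BMD  {d['Tot BMD']:.1f} mgHA/cc, Tot BV/TV {d['Tot BV/TV']:.1f} %")
print(f"Stiffness    {record.fe_summary['stiffness_n_mm']:.1f} N/mm")
print(f"Failure load {record.fe_summary['failure_load_n']:.2f} N")
print("first/last partition rows (mg, A/M/P/L):")
print(np.round(record.partition_bmc_mg[0], 4), np.round(record.partition_bmc_mg[9], 4))
```

prints (seed 1):

```
L        5.24 mm
Tot BMC  1.3702 mg   (truth 1.3723)
Tot BMD  638.8 mgHA/cc, Tot BV/TV 59.0 %
Stiffness    801.5 N/mm
Failure load 43.41 N
first/last partition rows (mg, A/M/P/L):
[0.0633 0.0735 0.0632 0.0752] [0.024  0.0263 0.024  0.0259]
```

The measured total BMC sits within 0.2% of the generator's ground truth,
and the 40 partition cells sum to it exactly. The reproducibility
experiment is one call:

```python
from tibiapipe.experiment import ExperimentConfig, run_reproducibility_experiment
report = run_reproducibility_experiment(ExperimentConfig(seed=11))
print(report.precision["week18"].loc[["Tot BMC", "Stiffness", "Failure load"]])
```

```
              PE [%]  LSC [%]  ICC [-]
Tot BMC        1.339    3.215    0.881
Stiffness      2.313    5.553    0.362
Failure load   3.283    7.880    0.348
```

Densitometric parameters come out more reproducible than the FE stiffness
(whose alignment sensitivity the operator model exposes), and trabecular
morphometry least — the ordering reported for the in vivo protocol.

A CLI mirrors the workflow: `tibiapipe generate`, `tibiapipe prep`,
`tibiapipe analyze`, `tibiapipe repro` (see `--help`).

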