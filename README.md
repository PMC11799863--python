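# psitunnel

Virtual planning and accuracy evaluation of femoral bone tunnels for
collateral-ligament reconstruction (LCL, popliteal tendon, MCL, POL).

In multiligament knee surgery, femoral tunnels are drilled at prescribed
angulations — e.g. 30° anterior in the axial plane and 30° proximal in the
coronal plane — to hit the anatomical footprint while avoiding convergence
with neighbouring tunnels. Patient-specific instrumentation (PSI): a
3D-printed guide whose cannulas encode the planned directions, promises to
execute such plans more accurately than freehand drilling. `psitunnel`
implements the computational pipeline needed to plan such tunnels and to
quantify, on repositioned "post-operative" bone models, how accurately they
were executed:

- **anatomical frames** per knee and entry side (shaft axis → SI,
  orthogonalized transepicondylar axis → ML, AP completing the triad), the
  reference in which axial/coronal tunnel angles are defined;
- **tunnel planning** from per-ligament angle prescriptions
  (`d = normalize(ml + tan α·ap + tan γ·si)`), anchored at ligament
  footprints, with the standard four-tunnel prescription as default;
- **convergence checks** between tunnels modelled as capped cylinders
  (exact segment–segment minimum distance, wall thickness = axis distance −
  r₁ − r₂);
- **rigid registration** of post-operative onto pre-operative bone with an
  iterative-closest-point loop (point-to-surface correspondences, SVD/Kabsch
  rigid solve);
- **accuracy endpoints** per tunnel: the 3D angular deviation
  `θ = arccos(d̂_planned · d̂_achieved)` and the entry-point distance (mm)
  after overlay;
- **error simulation** calibrated to published per-ligament accuracy
  summaries: each (technique, ligament) cell is a log-normal magnitude
  distribution pinned to the reported median and interquartile ratio
  (`μ = ln m`, `σ = ln(Q3/Q1)/(2 z₀.₇₅)`);
- **exact small-sample statistics**: median [Q1–Q3] summaries, the exact
  two-sided Mann–Whitney U test (full null distribution of U, so that at
  n = 5 vs 5 the attainable minimum is exactly 2/252 ≈ 0.008), and Levene /
  Brown–Forsythe spread comparison;
- a **synthetic femur generator** (implicit primitive blend polygonized by
  marching cubes, tagged footprints and landmarks) so the whole pipeline
  runs end-to-end with known ground truth and no imaging data.

## Worked example

Run a complete in-silico study — 5 knees per group, four tunnels per knee,
freehand vs PSI execution error, noiseless repositioning — and print the
comparison table:

```sh
psitunnel run --seed 42 --outdir demo
```

```
outcome  stratum  control (freehand)     PSI                    p (MW)    p (Levene)
------------------------------------------------------------------------------------
angular  pooled   20.9 [17.5-28.4]       5.3 [3.7-7.2]          0.000     0.000
angular  LCL      16.2 [15.1-18.0]       5.6 [4.3-7.2]          0.008     0.515
angular  MCL      20.0 [19.8-24.1]       7.6 [7.4-9.6]          0.008     0.118
angular  POL      26.5 [25.8-27.8]       3.3 [2.2-5.0]          0.008     0.356
angular  PT       29.9 [19.7-30.1]       4.2 [3.9-6.3]          0.008     0.005
entry    pooled   5.1 [3.7-9.0]          3.9 [3.0-6.1]          0.102     0.008
entry    LCL      3.8 [3.3-7.2]          2.9 [2.6-3.9]          0.421     0.077
entry    MCL      4.6 [4.6-5.5]          3.1 [2.7-4.2]          0.151     0.076
entry    POL      10.4 [8.6-12.2]        6.3 [3.8-6.3]          0.008     0.296
entry    PT       4.5 [3.5-4.9]          6.0 [3.9-7.8]          0.310     0.058
```

Reading the output: angular deviation separates the groups completely —
every per-ligament comparison attains the exact 5-vs-5 two-sided minimum
p = 0.008, and the pooled 20-vs-20 comparison is far below 0.001 — while
entry-point distance mostly does not (the guide constrains *direction* much
more than it constrains the entry point). The run directory also reports
zero colliding tunnel pairs out of 60 checked, and a mean ICP overlay
residual of 0.001 mm (noiseless meshes; add `--noise-sd 0.3` for realistic
scan-segmentation noise, which raises the residual to ≈ 0.24 mm).

The same machinery is available as a library:

```python
from psitunnel import (FemurParams, generate_femur, plan_knee,
                       check_convergence, simulate_study, compare_study)

femur = generate_femur(FemurParams(), seed=7)
tunnels = plan_knee(femur)                    # LCL 30/0, PT 30/30, MCL 30/30, POL 30/30
reports = check_convergence(tunnels)          # 6 pairs, none colliding
records = simulate_study(n_knees_per_group=5, seed=42)   # tidy DataFrame
table = compare_study(records)                # pooled + per-ligament rows
```

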