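# aneuflow

Pulsatile non-Newtonian blood flow in an idealized side-wall aneurysm,
with and without an endovascular coil, as a tested desk-scale pipeline.

## The problem

Wall shear stress (WSS) and its cycle-to-cycle oscillation govern the
growth and rupture risk of saccular intracranial aneurysms, and coil
embolization changes both by damping the flow inside the sac.  `aneuflow`
is for people who want a small, fully reproducible computational model of
that situation: an unsteady laminar incompressible solver with Casson
blood rheology, a pulsatile cardiac inflow, a Darcy porous-medium model of
the coil pack, and the standard wall indices

* **TAWSS** — time-averaged WSS magnitude, `(1/T) ∫‖τ‖ dt` (Pa),
* **OSI** — oscillatory shear index, `½(1 − ‖∫τ dt‖/∫‖τ‖ dt) ∈ [0, ½]`,
* wall pressure statistics at peak systole (t = 0.24 s) and early
  diastole (t = 0.54 s) of the cardiac cycle,

computed over the final of three simulated cycles, with drivers for
hematocrit (HCT) and coiling-porosity sweeps and a mesh-refinement study.
The geometry is a deliberate 2D idealization — a 3 mm parent vessel with a
5 mm circular dome behind a 2.5 mm neck — so the whole pipeline runs in
CPU-minutes; see `docs/methods.md` for the model, the coil
porosity/permeability table, and what the planar case can and cannot say
about 3D patient anatomy.

The coil pack is characterized by its porosity
`ε = 1 − (π d_w² L_c/4)/V_sac`; the reference coil (0.254 mm wire, 30 cm,
103.87 mm³ sac) gives ε ≈ 0.85, and the Darcy sink `−(μ/k) u` uses the
reference permeabilities k(0.75) = 3.7×10⁻⁸ m², k(0.85) = 5.4×10⁻⁸ m².

## Worked example

Check the coil/permeability arithmetic:

```
$ aneuflow check-table1
porosity 0.75: k = 3.70e-08 m^2, 1/k = 2.7e+07 (reference 2.7e+07) OK
porosity 0.85: k = 5.40e-08 m^2, 1/k = 1.85e+07 (reference 1.85e+07) OK
coil porosity = 0.8537 -> 0.85 (reference 0.85) OK
```

Run the example case (coiled sac, HCT 0.40, three 0.8 s cycles at the
coarse fixture resolution) and inspect the wall indices:

```
$ aneuflow run --config examples/case.yaml --out results/
```

This writes per-facet and per-region CSVs, VTK snapshots of the final
cycle, a machine-readable residual log and a checkpoint.  In Python the
same thing reads:

```python
from aneuflow import coarse_case, run_transient, report

case = coarse_case().with_(porosity=0.75)      # tightly coiled sac
traj = run_transient(case)
rep = report(traj, rheology=case.rheology_params())
print(rep.region_frame()[["region", "avg_tawss", "avg_osi", "max_osi"]])
```

```
        region  avg_tawss   avg_osi   max_osi
0     WALL_SAC   0.021425  0.019134  0.144622
1  WALL_VESSEL   2.693747  0.000000  0.000000
```

Reading: the coil pack damps the sac flow (average sac TAWSS drops from
≈0.11 Pa uncoiled to ≈0.02 Pa), and the weak, direction-reversing residual
motion inside the pack raises the average sac OSI from ≈0 (uncoiled, the
shear never reverses) to ≈0.02 — the qualitative coiling effect the sweep
driver (`aneuflow sweep`) quantifies across HCT ∈ {0.35, 0.40, 0.45} and
porosity ∈ {0.75, 0.85, 1.0}.  The parent-vessel wall keeps
order-of-Pa TAWSS and zero OSI, as expected for unidirectional
channel flow.

A mesh-refinement study with the truncated percent-change column and the
sub-1% selection rule:

```
$ aneuflow gridstudy --config examples/case.yaml --sizes 0.6,0.45,0.34
```

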