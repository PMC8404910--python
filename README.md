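# tminav

Headless navigation library for **tool-mounted-interface (TMI) guidance** in
pedicle-screw placement. During spinal fusion, a screw must enter the
vertebral pedicle along a planned trajectory; navigation systems display the
instrument's deviation from that trajectory, traditionally on an external
monitor away from the surgical site. A TMI instead fixes a small circular
display on the instrument itself, and reduces the guidance to a single moving
element: the tool's current orientation mapped into polar coordinates centred
on the planned path.

`tminav` implements that guidance stack end to end, with no hardware and no
rendering: pose geometry, the display-state models, trial execution, the
usability-study metrics and statistics, and a synthetic operator so the whole
pipeline is testable.

## The model

A tracked pose is a world-from-tool rigid transform `(q, p)` (unit quaternion,
translation in mm). With tool-frame constants `tip_offset` and unit
`shaft_axis`, the world tool axis is `a = R(q)·shaft_axis`. Against a planned
trajectory with unit direction `d` and entry point `e`:

- **angular deviation** θ = ∠(a, d) ∈ [0°, 180°];
- **azimuth** φ = direction of the deviation in the plane ⊥ d, measured
  counter-clockwise (viewed against d) from a reference direction;
- **display projection** (equidistant azimuthal):
  r = R·min(θ, θ_max)/θ_max, (x, y) = (r cos φ, r sin φ);
- **insertion depth** = (tip − e)·d, in mm.

The **Circle** display places one element at (x, y); within tolerance
(θ ≤ 1° by default) it turns from yellow to blue with a centre highlight. The
**Grid** display partitions the face into 12 angular segments × 4 concentric
rings and flags the patch containing the offset in red; the centre turns
green within tolerance. A **depth** view lights rings in proportion to
depth/target, and an emulated **traditional external** view resamples a
volume on three planes through the tip with the planned path in red and the
current axis in green.

A trial **succeeds** when θ stays continuously within tolerance for the full
hold duration (2 s); the task time runs from stream onset to the success
event. The study metrics are the task time and the **Euclidean path**
Σᵢ‖xᵢ₊₁ − xᵢ‖ of the tracked handle, filtered per group by the mean ± 2·std
rule, compared across display conditions by one-way ANOVA (times) and
Kruskal–Wallis (distances, questionnaire scores), with D'Agostino's K² as
the normality screen. SUS and raw NASA-TLX scoring are included, as is
least-squares **pivot calibration** for verifying the tip offset.

The `tminav.simulate` module generates everything physical: a 14-trajectory
Th11–L5 spine fixture, a single-entry pyramid fixture, synthetic voxel
volumes, an exponential-convergence operator model with a closed-form success
time, and whole-study datasets drawn from the per-condition moments of the
two usability experiments (18 surgeons × 3 conditions; 42 volunteers × 4
conditions).

## Worked example

```python
from tminav import (OperatorModel, ToolGeometry, DisplayConfig, run_trial,
                    simulate_alignment, apply_tool_geometry, polar_offset,
                    update_circle, grid_cell, generate_study_dataset,
                    analysis_report)
from tminav.simulate import generate_spine_fixture

traj = generate_spine_fixture().by_id("Th12-L")
tool = ToolGeometry()
op = OperatorModel(gain=0.6, latency=0.3, seed=42)
stream = simulate_alignment(op, traj, theta0=15.0, tol=1.0, hold=2.0, tool=tool)
res = run_trial(stream, traj, tool, tolerance_deg=1.0, hold_duration=2.0)
print(res.success, round(res.task_time, 3), round(op.success_time(15, 1, 2), 3))
# True 6.82 6.813   <- measured success time matches ln(15)/0.6 + 0.3 + 2 s hold

_, axis = apply_tool_geometry(stream[0], tool)
off = polar_offset(axis, traj)
print(update_circle(off, DisplayConfig()), grid_cell(off, DisplayConfig()))
# CircleState(position=(0.333, 0.004), in_target=False, element_color='yellow',
#             highlight=False)  (0, 1)
# 15 deg of 45 -> one third of the way to the display edge, sector 0, ring 1

metrics, quest = generate_study_dataset("exp1", seed=1)
o = analysis_report(metrics)["metrics"]["task_time_s"]["omnibus"]
print(f"F={o['statistic']:.1f} p={o['p_value']:.3g}")
# F=34.6 p=1.24e-14  <- the Circle/Grid/external task-time difference
```

The CLI wraps the same workflows:

```sh
tminav --seed 1 fixtures --name spine --out fixtures
tminav --seed 1 simulate --experiment exp1 --out study
tminav analyze --metrics study/metrics.csv --questionnaires study/questionnaires.csv --out analysis
```

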