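# mlgait

Markerless 3D gait analysis downstream of a 2D pose detector: multi-view
triangulation of per-camera keypoint detections, trajectory filtering,
gait-event detection, spatio-temporal parameters, geometric joint-angle
curves, pose-estimation metrics (PCKh / MPJPE), and marker-vs-markerless
statistical comparison with scalar and 1D SPM paired t-tests.  A kinematic
gait simulator with exact ground truth (events, parameters, joint-angle
profiles, virtual camera renderings) makes every stage testable without any
external data.

## Modules

| module | purpose |
|---|---|
| `mlgait.cameras` | pinhole camera model, Brown-Conrady distortion, DLT + refined triangulation, calibration file I/O |
| `mlgait.trajectory_io` | skeletons (`h36m21`, `davis22`), 2D/3D trajectory containers, CSV formats, TRC export for OpenSim |
| `mlgait.preprocess` | zero-phase Butterworth low-pass, cubic-spline gap interpolation, differentiation, 101-point cycle normalization |
| `mlgait.gait_events` | heel-strike / toe-off detection from heel and toe speed (adaptive threshold, sub-frame refinement), cycle segmentation |
| `mlgait.gait_params` | the six per-cycle parameters: stance %, swing %, stride length, step width, stride time, speed |
| `mlgait.joint_angles` | hip flexion, knee flexion, ankle dorsiflexion, hip abduction, pelvis tilt per cycle (0-100%) |
| `mlgait.pose_metrics` | PCKh@tau (strict inequality) and MPJPE with per-keypoint breakdowns |
| `mlgait.spm_stats` | paired t-tests: scalar, and 1D over curves with RFT or sign-flip permutation thresholds |
| `mlgait.synthetic_gait` | ground-truthed walking simulator and virtual 3-camera rig |
| `mlgait.cli` | `mlgait` command-line interface and the full pipeline driver |

## CLI

```bash
# generate a synthetic walk (3D CSV, three 2D view CSVs, calibration, ground truth)
mlgait simulate --out sim/ --seed 1 --pixel-noise 0.5

# triangulate 2D views into 3D trajectories
mlgait triangulate --views sim/sim_2d_cam0.csv --views sim/sim_2d_cam1.csv \
    --views sim/sim_2d_cam2.csv --calibration sim/calibration.json --out tri.csv

# events / parameters / angle curves from a 3D CSV
mlgait events --series3d sim/sim_3d.csv --out events.csv
mlgait params --series3d sim/sim_3d.csv --out params.csv
mlgait angles --series3d sim/sim_3d.csv --out angles.csv

# pose metrics between an estimated and a reference 3D series
mlgait eval --estimate tri.csv --truth sim/sim_3d.csv --out metrics.json

# compare two measurement systems (paired scalar + 1D SPM tests)
mlgait compare --series-a marker.csv --series-b markerless.csv --out report.csv

# full pipeline from a YAML config
mlgait run config.yaml
```

A pipeline config names either 2D `views` plus a `calibration` file, or an
already-triangulated `series3d` CSV (the triangulation stage is then
skipped):

```yaml
output_dir: out/
input:
  views: [sim/sim_2d_cam0.csv, sim/sim_2d_cam1.csv, sim/sim_2d_cam2.csv]
  calibration: sim/calibration.json
event_cutoff_hz: 3.0        # gait-event detection filter
kinematic_cutoff_hz: 12.0   # parameter / angle filter
alpha: 0.05
seed: 0
```

Outputs: 3D trajectories, events CSV, per-cycle parameter CSV + summary,
101-sample angle curves, a TRC file (so the OpenSim scaling/IK route remains
available), and a run log with all effective settings.  Exit codes: 0
success, 2 config error, 3 data error.

## File formats

Trajectory CSVs are sparse `frame,keypoint,...` tables with `#` metadata
header lines (`# fps=`, `# camera_id=`, `# units=m|mm`, `# vertical_axis=`);
absent rows mean missing samples, and values round-trip bit-exactly.
Calibration files (JSON or YAML) list per-camera `K`, `dist` (k1,k2,p1,p2),
`R`, `t`, and `image_size`.  TRC output follows the OpenSim tab-delimited
layout.

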