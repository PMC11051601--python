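# holotrack

3D tracking of swimming microbes from inline digital holographic
microscopy (DHM) video — simulation, classical reconstruction,
bounding-box depth proxies, and track linking, in one testable Python
package.

## The problem

An inline hologram encodes the 3D position of a micro-swimmer in a
single 2D intensity image: a cell at depth *z* from the focal plane
produces a set of concentric diffraction rings whose geometry depends
on *z*. Classical DHM recovers positions by numerically refocusing the
hologram at many depths (angular-spectrum back-propagation) and
locating cells via the Gouy phase anomaly — accurate, but far too slow
for real-time work. A much faster route runs an object detector on the
normalized hologram and exploits a heuristic: with a finite-NA
objective the apparent extent of a cell's ring pattern — hence the side
*s* of a bounding box drawn around it — grows linearly with depth over
an intermediate range,

    s = m·z + c            (calibration)
    z_raw = (max(w, h) − c) / m   (longest-edge inversion)

followed by a 4th-order polynomial correction
`z_corr = Σ aₖ·z_rawᵏ` fitted on validation data to remove the
detector's systematic depth bias. Per-frame 3D localizations are then
linked into tracks by optimal assignment, which also rejects spurious
transient detections.

`holotrack` implements this entire pipeline with a synthetic-data
generator in place of a microscope: run-and-tumble swimmers rendered as
weak (Rayleigh–Gans) point scatterers through the same
angular-spectrum kernel the reconstructor uses, so every stage can be
validated as a round trip against exact ground truth. A classical
matched-filter detector stands in for a trained CNN; anything that
emits darknet-style boxes plugs into the same depth-mapping and
tracking stages.

Modules: `simulate` (scenes + holograms), `preprocess` (median
normalization), `reconstruct` (back-propagation, Gouy localization),
`annotate` (calibration + label files), `detect` (reference detector,
NMS, detection I/O), `depthmap` (box→z, polynomial correction),
`track` (linking, RMSE), `evaluate` (IoU, precision/recall, mAP),
`cli` (stage-per-subcommand pipeline). See `docs/methods.md` for the
models and numerical choices.

## Worked example

Simulate a short video, localize cells classically, and compare the
box-proxy track against ground truth:

```python
import numpy as np
from holotrack.config import OpticalConfig
from holotrack.simulate import MotionParams, simulate_scene, render_hologram
from holotrack.reconstruct import localize_frame
from holotrack import annotate, detect, depthmap, track

optics = OpticalConfig(chamber_depth=150.0)   # 512 px ≙ 360 μm, λ = 642 nm, NA 0.5
scenes, truth = simulate_scene(
    MotionParams(n_cells=5, n_frames=30, seed=4), optics)
frames = [render_hologram(s, optics, noise_sd=0.002, rng=i)
          for i, s in enumerate(scenes)]

# classical ground-truth engine on one frame
locs = localize_frame(frames[0], optics)
print(len(locs), "classical localizations")
print(f"first: x={locs[0].x:.1f} y={locs[0].y:.1f} z={locs[0].z:.1f} μm")

# calibrate the box-size↔depth heuristic from rendered patterns
pairs = annotate.calibration_pairs(optics, np.arange(20.0, 151.0, 10.0))
cal = annotate.fit_heuristic(pairs, sizes_are_radii=True)
print(f"heuristic: side = {cal.slope_m:.2f}·z + {cal.intercept_c:.1f} px")

# detect boxes, map to depth, link
bank = detect.TemplateBank(optics, cal)
dets = [d for i, f in enumerate(frames)
        for d in detect.detect_reference(f, cal, optics, bank=bank, frame_index=i)]
locs3d = [track.Localization3D(
              x=d.x_center * optics.pixel_pitch, y=d.y_center * optics.pixel_pitch,
              z=depthmap.z_from_box(cal, d), frame_index=d.frame_index,
              source="box_proxy")
          for d in dets]
tracks = track.link(locs3d, max_disp=30.0, min_length=5)
pred, ref = track.match_tracks(tracks, truth)[0]
print(len(tracks), "tracks; RMSE vs ground truth:",
      round(track.track_rmse(pred, ref), 2), "μm")
```

Output:

```
6 classical localizations
first: x=29.1 y=218.6 z=56.4 μm
heuristic: side = 1.13·z + 13.6 px
5 tracks; RMSE vs ground truth: 5.32 μm
```

The classical engine finds all 5 cells to sub-μm axial accuracy plus
one weak spurious signal — exactly the kind of transient the
track-linking stage's minimum-length filter rejects. The calibrated
slope (1.13 px/μm) is the geometric NA-cone slope of the optics.
Box-proxy tracks carry the few-μm depth quantization of the template
grid; the polynomial correction stage addresses the detector's
systematic bias in the full pipeline.

The same pipeline runs from the shell with a single YAML config:

```bash
holotrack --config config.yaml pipeline   # simulate → … → tracks.csv + evaluation.json
```

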