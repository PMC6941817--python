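# wormmri

Prospective motion-predicted MR microscopy of a freely crawling
*Caenorhabditis elegans*, as a fully simulated test bed.

MR imaging acquires the spatial-frequency domain (k-space) one line per
repetition time TR, so a sample that moves between lines — a crawling worm
covers about one body length in the ~5 s a 64-line gradient-echo image
takes — is smeared beyond recognition. This package implements and
quantifies the rescue strategy of steering the imaging gradient after the
moving target: an optical video of the worm is tracked in real-time
fashion, the body centerline is parametrised by normalized arc length
*s* ∈ [0, 1] (head = 0, tail = 1), and the future position of the slice of
interest is predicted from the observation that body segments travel along
the current body shape at the worm's speed *v*:

```
s_c = s − v·Δk          (clamped to the head, s = 0)
```

where Δk is the prediction horizon in frames. A Cartesian gradient-echo
acquisition simulator then fills one k-space line per video frame
(TR = 83 ms at 12 Hz), with the gradient centre G_C placed per line either
at the predicted slice position, held fixed (no prediction), or taken from
ground truth (oracle). Reconstructions are scored against the true
cross-sectional phantom with the structural similarity index s_xy
(1 = identical, ~0 = unrelated).

Because no public worm-video/TEM data accompany the original experiments,
the package ships a first-class synthetic generator: undulating crawls of a
1.2 mm worm at ≈0.13 mm/s recorded at 12 Hz for 10 s, with exact
ground-truth poses, plus a library of 50 MR-like 64×64 cross-section
phantoms (24 µm slabs) attached along the body.

Intended users: MR-microscopy and tracking-methods developers who want a
controlled environment for prospective motion-correction experiments.

## Worked example

```python
import numpy as np
from wormmri import (WormKinematics, generate_dataset, track_video,
                     evaluate_prediction, run_gre, reconstruct,
                     true_slice_image, ssim, SequenceParams)

kin = WormKinematics(seed=3)              # 1.2 mm worm, 0.13 mm/s, 12 Hz, 10 s
video = generate_dataset(kin)             # frames + ground truth + phantoms
track = track_video(video)                # detect, skeletonize, estimate v

v = np.mean(track.velocities[20:])
print(f"centerline speed: {v:.5f} s-units/frame "
      f"(ground truth {kin.speed / kin.frame_rate / kin.body_length:.5f})")

report = evaluate_prediction(track, s=0.9, delta_k=6)
print(f"POI prediction error at s=0.9, horizon 6: "
      f"{report.mean_prediction_error:.1f} um")

ref = true_slice_image(video, 0.52, 0)
for mode in ("prediction", "no_prediction"):
    ks = run_gre(video, SequenceParams(mode=mode, horizon=1), 0.52,
                 track=track)
    score = ssim(reconstruct(ks).magnitude, ref).s_xy
    print(f"slice s=0.52, {mode:>13}: SSIM = {score:.3f}")
```

prints

```
centerline speed: 0.00867 s-units/frame (ground truth 0.00903)
POI prediction error at s=0.9, horizon 6: 66.7 um
slice s=0.52,    prediction: SSIM = 0.812
slice s=0.52, no_prediction: SSIM = 0.073
```

The tracked speed matches the generator's ground truth to ~4 %; a point of
interest near the tail is predicted half a second ahead to within ~2.5
downsampled pixels; and steering the gradient by that prediction lifts the
image similarity of a mid-body slice from 0.07 (motion-ruined) to 0.81.

A command-line interface mirrors the library
(`wormmri generate | track | predict | simulate | evaluate | pipeline`),
e.g.

```bash
wormmri generate --out data/worm0
wormmri simulate --dataset data/worm0 --s 0.52 --mode prediction --out run0
```

## Layout

| module | role |
|---|---|
| `wormmri.synthgen` | synthetic worm videos with ground truth; slice-phantom library |
| `wormmri.detect` | downsampling, background model, segmentation, head, skeleton, velocity |
| `wormmri.predict` | COG extrapolation, POI coordinate prediction, error scoring |
| `wormmri.mrisim` | gradient-echo k-space acquisition with a moving gradient centre |
| `wormmri.evalsim` | structural similarity, simulation paradigms, imageability taxonomy |
| `wormmri.cli` | click-based command-line orchestration |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
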