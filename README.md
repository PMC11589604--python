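# cystomap

2D bladder-map construction from cystoscopic video: feature-based stitching of
sequential endoscope frames into a composite map, loop-closure drift
correction, and relocalization ("revisit") of frames from a later video inside
a previously built map, with navigation overlays.

The package also includes camera calibration from checkerboard views (pinhole
+ 5-coefficient radial/tangential distortion, built on numpy/scipy/
scikit-image — no OpenCV dependency) and a synthetic-scene module that renders
vessel-textured frame sequences with exact ground-truth poses, which is the
test substrate for everything else.

## Layout

| module                  | purpose                                                        |
| ----------------------- | -------------------------------------------------------------- |
| `cystomap.calibration`  | checkerboard detection, intrinsics/distortion estimation, undistortion |
| `cystomap.features`     | keypoint detection, brute-force matching, seeded-RANSAC similarity/affine estimation |
| `cystomap.mapper`       | pose chaining, canvas growth, compositing, the stitch loop     |
| `cystomap.drift`        | spatial-neighbor loop closures, residual measurement, pose re-calibration |
| `cystomap.revisit`      | global first-frame search, locality-prior tracking, overlay rendering |
| `cystomap.synthetic`    | vessel textures, scripted sweeps, frame rendering, checkerboard views |
| `cystomap.io` / `cli`   | frame ingestion (crop/stride/mask), map persistence, command line |

## CLI

```sh
cystomap simulate --pattern serpentine --frames 25 --seed 1 --out scene/
cystomap stitch --video scene/frames --out mapdir/
cystomap drift-correct --map mapdir/ --video scene/frames --out mapdir_dc/
cystomap revisit --map mapdir_dc/ --video revisit_frames/ \
    --out overlay.png --poses revisit_poses.json
cystomap calibrate --images boards/ --pattern 5x7 --square-mm 10 --out camera.json
```

`stitch`/`drift-correct`/`revisit` accept `--camera camera.json` to undistort
frames first, `--stride N` to subsample video, `--crop N` for a centered
square crop, and `--mask auto` to detect the circular endoscope field.

Transforms are 2x3 row-major affines acting on (x, y, 1) columns, origin at
the top-left. Maps are persisted as a directory: `canvas.png`,
`canvas_mask.png`, `poses.json` (versioned schema), `stats.json`, plus a
machine-parsable per-frame log (`frames.log`) with feature/match/inlier
counts and transform provenance.

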