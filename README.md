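# patmap

Phase-windowed activation-time (pAT) mapping for complex, high-frequency
and arrhythmic cardiac optical-mapping recordings.

Conventional activation-time mapping extracts one activation per pixel
from a fixed time window shared by all pixels, which falls apart during
reentry and fibrillation. `patmap` instead derives **pixel-independent
upstroke windows** from Hilbert-transform phase (with recursive trace
segmentation for non-periodic signals), detects one or two activation
components per upstroke from the signal derivative with an automated
FDR-based threshold, groups activations into **wave fronts** by
space-time connected components under a conduction-block delay
threshold, and characterises each front: repolarization/APD maps,
repetitive vs non-repetitive classification, activation-origin
(breakthrough vs passive) detection, dynamic map stacks that tile a
reentrant episode without per-pixel overwrites, and conduction-source
classification of the leading wave-front edge (breakthrough / passive /
myocardial reentry / tortuous / wave-front boundary).

A built-in two-variable excitable-sheet simulator (planar paced waves,
focal sources, S1S2S3S4 short-coupled trains, cross-field-induced spiral
reentry) plus an optical observation model (blur, inversion, drift,
SNR-calibrated noise) provides ground-truthed stacks for validation.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(spiral single-front, uAT-vs-pAT ordering, oracle equivalences, noise and
resolution robustness); the full suite takes a few minutes on one CPU.

## CLI

```bash
# generate a ground-truthed synthetic spiral recording
patmap simulate --kind spiral --snr 20 --out sim/

# full pipeline: preprocess -> windows -> threshold -> pAT -> wave fronts
#                -> RT/APD -> repetitiveness -> origins -> sources
patmap run --stack sim/stack.bin --config config.json --out run/

# individual stages
patmap preprocess --stack raw.tif --mask roi.png --out pre/
patmap detect     --stack pre/normalized.bin --out det/
patmap label      --events det/events.csv --detect-info det/detect.json --out lab/
patmap repolarize --stack pre/normalized.bin --labels lab/labels.csv --label-id 1 --out rep/
patmap classify   --stack sim/stack.bin --out classification.json

# compare uAT and pAT maps against simulated ground truth
patmap compare --stack pre/normalized.bin --truth sim/truth_eat.csv \
               --t0-ms 3700 --t1-ms 4460 --out compare.json
```

Stacks are multi-frame TIFF or raw little-endian float32/uint16 binary
with a JSON sidecar (`{nx, ny, nt, dt_ms, pitch_mm, dtype}`); masks are
TIFF/PNG (nonzero = inside ROI). Every run writes its fully resolved
configuration (automated thresholds included) beside the artifacts, and
re-running with that config reproduces the outputs bit-identically.

Key defaults (all overridable in the config JSON): 60 Hz zero-phase
Butterworth low-pass, 3×3 spatial and 3-frame temporal averaging,
128 ms minimum phase segment, FDR q = 0.01, 75% biphasic valley depth,
APD80 with 80–400 ms user limits, ERPmin fallback = 0.8 × minimum basal
APD.

## Package layout

| module | role |
|---|---|
| `patmap.preprocess` | filtering, inversion, per-pixel normalization, ROI masking, signal QC (SNR, dominant frequency, regularity) |
| `patmap.phase` | Hilbert-phase upstroke windows with recursive segmentation |
| `patmap.activation` | automated derivative threshold (FDR), mono/biphasic pAT detection, uniform-window uAT baseline |
| `patmap.wavefronts` | conduction-block threshold estimation, space-time connected-components labeling, per-front AT maps |
| `patmap.repolarization` | RT detection (amplitude crossing / min-derivative), refined APD limits, APD maps |
| `patmap.sources` | repetitiveness, activation origins, dynamic map stacks, conduction vectors and fields, source classification |
| `patmap.synthetic` | excitable-sheet simulator, optical observation model, map-agreement statistics |
| `patmap.io` | TIFF / raw-binary / mask / CSV / isochrone-PNG readers and writers |
| `patmap.pipeline`, `patmap.cli` | orchestration, resolved-config emission, artifact bundles, `patmap` command |
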