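# uitrans

Deep-learning restoration of light-sheet fluorescence microscopy (LSFM)
volumes, built for in vivo 4D (3D + time) imaging of the beating
zebrafish heart — together with the synthetic degradation simulator,
paired-volume preprocessing, quantitative evaluation and cardiac-cycle
synchronization that make the whole workflow testable end to end on
synthetic data.

## The problem

Live cardiac LSFM must use milliseconds of exposure at ~0.1 mW to avoid
motion blur and phototoxicity, so raw volumes are photon-starved (SNR
around 6 dB) and buried in a long-range scattering haze that extra light
cannot remove. Confocal line-scanning LSFM rejects the scattered light
and produces clean volumes — at roughly 3000x the light dose and 30x the
acquisition time, feasible only on fixed samples. This package trains a
network on pixel-aligned pairs (economical conventional-LSFM input,
line-confocal ground truth) and applies it to live acquisitions, so that
a volume costing < 0.03% of the ground-truth light exposure can be
restored to near-ground-truth quality.

## The model

`UITransNet` is a dual-branch hierarchical encoder with a U-type
convolutional decoder. At every encoder stage the volume passes through
a convolutional branch (double 3x3x3 convolution — local detail) and a
transformer branch in parallel; the transformer block holds two parallel
multi-headed self-attention modules whose outputs are concatenated to
match the convolutional width. Tokens come from interval extraction
(stride-s interleaved sub-sampling), so each token sees the whole field
of view — global scattering structure — rather than a local patch.
Branch outputs are concatenated channel-wise after each stride-2
down-sampling and serve as skip connections into the decoder. Training
minimizes

    L_total = L_MAE + 0.01 * L_perceptual

the mean absolute voxel error plus a per-z-slice perceptual (frozen
feature pyramid) distance averaged per volume, optimized with ADAM on a
seeded 9:1 train/validation split.

The package runs on plain numpy: it includes a small reverse-mode
autodiff engine (`uitrans.nn`) with numba-accelerated 3D convolution,
verified against finite differences in the test suite. See
`docs/methods.md` for the full model description, the forward
(degradation) model and all numerical choices.

## Worked example

```python
import numpy as np
from uitrans import (generate_pair_dataset, UITransModel, TrainConfig,
                     normalize_volume, otsu_masks, compute_snr_db)

# 40 aligned (low-dose input, line-confocal-quality GT) pairs at 32^3
pairs = generate_pair_dataset(n_pairs=40, shape=(32, 32, 32), seed=11)

model = UITransModel(pairs, train_config=TrainConfig.desk_scale(seed=11))
results = model.fit(seed=11)          # ~3 min on one CPU core
print(results.summary())

pair = results.val_pairs[0]
x = normalize_volume(pair.input.values)
y = normalize_volume(pair.ground_truth.values)
restored = results.restore(pair.input.values)
fg, bg = otsu_masks(y)
print(f"SNR input    {compute_snr_db(x, fg, bg):5.1f} dB")
print(f"SNR restored {compute_snr_db(restored, fg, bg):5.1f} dB")
```

Output from this exact run:

```
UI-Trans restoration results
============================================================
stages: 3   base channels: 8   heads: 4   token stride: 4
parameters: 668,713
branches: transformer=True conv=True
pairs: 36 train / 4 val
epochs run: 8   steps: 144
------------------------------------------------------------
final train L_total: 0.03224
final val   L_total: 0.03224
final val   NRMSE  : 0.05273
final val   Pearson: 0.96462
============================================================
SNR input      6.5 dB
SNR restored  15.3 dB
```

The restored validation volumes reach the SNR regime of the
high-light-dose ground truth (~15-16 dB) from ~6 dB inputs, cut NRMSE to
about a third of the input's, and raise voxelwise Pearson correlation
with the ground truth from ~0.67 to ~0.96 — while the simulated input
acquisition uses 1/3000 of the ground-truth light dose.

A beating 4D sequence is reconstructed from per-slice movies with
`estimate_period` and `synchronize_movies`, and arbitrarily sized
volumes are restored with `results.tiled_restore(volume)`.

## Command line

```
uitrans simulate --shape 64,64,64 --n-pairs 40 --seed 7 --out data/
uitrans train    --data data/ --out run/ --seed 7
uitrans align    --moving in.tif --reference gt.tif --max-shift 8 --out aligned.tif --report shift.json
uitrans evaluate --input in.tif --restored out.tif --gt gt.tif --report metrics.json
uitrans restore  --model run/final.npz --in vol.tif --out restored.tif --tile 32,32,32 --overlap 8
uitrans sync4d   --movies movies/ --period auto --out fourd/
```

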