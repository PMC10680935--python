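# biasfield

Deep-learning bias-field correction for T1-weighted brain MRI, with a
synthetic phantom engine so the estimator can be trained and validated
end-to-end on one CPU without any external data.

## The problem

Structural MRI suffers from *intensity inhomogeneity*: a smooth, low
spatial-frequency multiplicative shading ("bias field") caused by
magnetic-field imperfections. The acquired image factorizes voxelwise as

    a(r) = u(r) · b(r)

where `u` is the unbiased image and `b > 0` the bias field. Taking logs
makes the corruption additive, `log u = log a − log b`, so a network can
regress the signed quantity `log b` directly from the image:

    log b̂(r) = f(a(r))

Here `f` is a generic 3D U-Net (3×3×3 kernels, instance normalization,
leaky ReLU, transpose-convolution upsampling, skip connections, linear
1×1×1 head). Training minimizes, over a brain mask of `N` voxels,

    L = L_a + L_b
    L_a = (1/N) Σ (exp(log b̂) − b)²          (field fidelity)
    L_b = (1/N) Σ (a / exp(log b̂) − u)²      (corrected-image fidelity)

with Adam (learning rate 1e-4) and best-on-validation model selection.
The predicted field can be post-smoothed before division: not at all
(`NS`), with a truncated 19³ Gaussian of σ = 3 voxels (`G`), or with a
slicewise multilevel cubic B-spline fit of 5 levels (`B`).

Because no deep-learning framework is required, the estimator — layers,
backward passes and Adam — is implemented directly in NumPy and the
whole pipeline is differentiable end to end, including (optionally) the
Gaussian smoothing step inside the loss.

## Worked example

Train the estimator on synthetic phantoms and measure how much
correction improves held-out fidelity (the canned desk-scale experiment:
64 training / 8 validation / 16 held-out heads at 48³ voxels, fields
spanning ≈ [0.74, 1.35], noise SD 0.01, a 3-level 8-channel network,
10 epochs — about 9 minutes on one CPU):

```python
from biasfield.experiments import field_recovery_experiment

res = field_recovery_experiment(seed=1)
for k in ("median_psnr_acquired_db", "median_psnr_corrected_ns_db",
          "median_psnr_corrected_g_db", "median_psnr_corrected_b_db",
          "median_field_correlation"):
    print(f"{k}: {res[k]:.3f}")
```

Output from this exact script:

```
median_psnr_acquired_db: 30.959
median_psnr_corrected_ns_db: 34.107
median_psnr_corrected_g_db: 34.565
median_psnr_corrected_b_db: 34.297
median_field_correlation: 0.868
```

Reading the numbers: the biased inputs sit at a median 31.0 dB masked
PSNR against the ground-truth unbiased phantoms; dividing by the
predicted field lifts held-out fidelity by ≈ 3.1–3.6 dB depending on
the smoothing variant (raw prediction `NS`, Gaussian `G`, B-spline
`B` — practically equivalent, with `G` marginally ahead), and the
predicted log fields correlate with the true ones at a median Pearson
r of 0.87 inside the brain mask.

For a single volume the estimator API is:

```python
est.fit(train_samples, X_val=val_samples)      # or load_checkpoint(path)
log_field = est.predict(sample.acquired)       # log b̂, same shape
corrected = est.correct(sample.acquired, smoothing="G")
```

The same workflows are available from the shell:

```bash
biasfield simulate --n 64 --shape 48 --seed 7 --out data/
biasfield train --data data/manifest.json --levels 3 --base-channels 8 \
    --epochs 10 --checkpoint ckpt.npz --history history.csv
biasfield correct --input scan.nii.gz --checkpoint ckpt.npz \
    --smoothing G --out corrected.nii.gz
biasfield evaluate --truth-dir truth/ --mask-dir masks/ \
    --method deep=corrected/ --method none=raw/ \
    --out-csv percase.csv --out-json summary.json
```

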