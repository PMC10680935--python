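"""Canned desk-scale experiments used by the test suite and the
reproduction script.

The central one trains the field estimator end-to-end on synthetic
phantoms and measures, on held-out samples, (a) how much correction
improves masked PSNR against the ground-truth unbiased image and (b) how
well the predicted log field correlates with the true one — the method's
core claim in miniature.  Problem sizes (48-voxel cubes, 64 training
samples, a levels-3/8-channel network, 10 epochs) are chosen so the full
experiment runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .core import correct_with_field
from .evaluation import psnr
from .phantom import FieldSpec, PhantomSpec, generate_dataset
from .smoothing import smooth_field
from .training import TrainConfig, train_model
from .unet import UNetConfig

__all__ = ["field_recovery_experiment", "overfit_experiment"]


def field_recovery_experiment(seed: int = 0, n_train: int = 64, n_val: int = 8,
                              n_test: int = 16, shape: int = 48,
                              levels: int = 3, base_channels: int = 8,
                              epochs: int = 10, noise_sd: float = 0.01,
                              log_amplitude: float = 0.3,
                              verbose: int = 0) -> dict:
    """Train on synthetic phantoms, evaluate recovery on held-out ones.

    Returns a dict with median masked PSNR of the acquired and the
    corrected (NS/G/B variants) images against the ground-truth unbiased
    image, plus the median masked Pearson correlation between predicted
    and true log fields, and the training history.
    """
    pspec = PhantomSpec(shape=(shape,) * 3, noise_sd=noise_sd)
    fspec = FieldSpec(family="gauss_random_field", log_amplitude=log_amplitude,
                      correlation_length=shape / 4.0)
    n = n_train + n_val + n_test
    samples, _ = generate_dataset(n, pspec, fspec, seed=seed)
    train = samples[:n_train]
    val = samples[n_train:n_train + n_val]
    test = samples[n_train + n_val:]

    unet_cfg = UNetConfig(levels=levels, base_channels=base_channels, seed=seed)
    train_cfg = TrainConfig(epochs=epochs, seed=seed)
    est, history = train_model(train, val, unet_cfg, train_cfg,
                               verbose=verbose)

    psnr_acq, psnr_corr, field_corr = [], {"NS": [], "G": [], "B": []}, []
    for s in test:
        a = s.acquired.data
        u = s.corrected_truth.data
        m = s.mask
        logb = est.predict(a)
        psnr_acq.append(psnr(a, u, m))
        for mode in ("NS", "G", "B"):
            field = smooth_field(np.exp(logb), est.smoothing_spec(mode))
            psnr_corr[mode].append(psnr(correct_with_field(a, field), u, m))
        lt = np.log(s.field_truth.data[m.data])
        lp = logb[m.data]
        field_corr.append(float(np.corrcoef(lp, lt)[0, 1]))

    return {
        "median_psnr_acquired_db": float(np.median(psnr_acq)),
        "median_psnr_corrected_ns_db": float(np.median(psnr_corr["NS"])),
        "median_psnr_corrected_g_db": float(np.median(psnr_corr["G"])),
        "median_psnr_corrected_b_db": float(np.median(psnr_corr["B"])),
        "median_field_correlation": float(np.median(field_corr)),
        "per_case_psnr": {"acquired": psnr_acq, **psnr_corr},
        "per_case_field_correlation": field_corr,
        "history": history,
        "estimator": est,
        "test_samples": test,
    }


def overfit_experiment(seed: int = 0, shape: int = 32, levels: int = 2,
                       base_channels: int = 8, steps: int = 300,
                       learning_rate: float = 1e-3, verbose: int = 0) -> dict:
    """Drive training loss down on a single sample; a capacity/optimizer
    sanity check.  Returns initial and final total loss.

    Uses Adam's canonical 1e-3 step size: this diagnostic asks whether
    the network and backward passes can memorize one field quickly, not
    whether the conservative full-protocol learning rate converges in a
    given budget.
    """
    from .estimator import BiasFieldCorrector
    from .phantom import generate_sample

    pspec = PhantomSpec(shape=(shape,) * 3, noise_sd=0.0)
    fspec = FieldSpec(log_amplitude=0.3, correlation_length=shape / 4.0)
    sample = generate_sample(pspec, fspec, seed=seed)
    est = BiasFieldCorrector(levels=levels, base_channels=base_channels,
                             epochs=steps, seed=seed,
                             learning_rate=learning_rate, verbose=verbose)
    est.fit([sample])
    losses = [row["train_loss"] for row in est.history_]
    return {
        "initial_loss": losses[0],
        "final_loss": losses[-1],
        "ratio": losses[-1] / losses[0],
        "losses": losses,
        "estimator": est,
        "sample": sample,
    }
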