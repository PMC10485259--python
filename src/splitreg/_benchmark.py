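"""Shared desk-scale benchmark harness.

A single place defining the benchmark protocol used by both the acceptance
tests and the acceptance script: 20 training and 5 held-out synthetic 2-D
pairs (64x64, peak displacement 4 voxels, field smoothness sigma 4),
decoupled or baseline training for 1,500 iterations at learning rate 1e-3
with batch size 4, then held-out evaluation of label overlap, field-recovery
error and field smoothness.

The network profile is deliberately narrower than the package defaults so a
full run fits in a few CPU-minutes; it is part of the benchmark definition.
"""

from __future__ import annotations

import numpy as np

from .core import Hyperparams
from .evaluation import endpoint_error, multi_label_dice
from .networks import DenoiserNetSpec, SimilarityNetSpec
from .objectives import local_cross_correlation, smoothness_penalty
from .synthetic import SyntheticSpec, make_dataset
from .trainer import TrainingConfig, init_state, register, train
from .warping import warp_labels

__all__ = [
    "BENCH_SIM_SPEC",
    "BENCH_DEN_SPEC",
    "benchmark_datasets",
    "evaluate_state",
    "run_benchmark",
]

BENCH_SIM_SPEC = SimilarityNetSpec(
    encoder_channels=(8, 16, 16, 16),
    decoder_channels=(16, 16, 8, 8),
    head_channels=(8, 8),
)
BENCH_DEN_SPEC = DenoiserNetSpec(
    stem_channels=8, dilation_rates=(1, 2, 4), branch_channels=4, fusion_channels=8
)

HELD_OUT_SEED_OFFSET = 1000


def benchmark_datasets(seed: int):
    """The 20 training and 5 held-out pairs for a given benchmark seed."""
    train_set = make_dataset(SyntheticSpec(n_pairs=20, seed=seed))
    held_out = make_dataset(SyntheticSpec(n_pairs=5, seed=seed + HELD_OUT_SEED_OFFSET))
    return train_set, held_out


def evaluate_state(state, held_out, hp: Hyperparams) -> dict:
    """Held-out metrics for one trained (or freshly initialized) state."""
    dsc_before, dsc_after = [], []
    epe, epe_baseline = [], []
    joint, smooth_u, smooth_v = [], [], []
    for pair in held_out:
        u, warped, v = register(state, pair.fixed, pair.moving)
        _, before = multi_label_dice(pair.fixed_labels, pair.moving_labels)
        _, after = multi_label_dice(
            pair.fixed_labels, warp_labels(pair.moving_labels, u)
        )
        mean_err, _ = endpoint_error(u, pair.inverse_field)
        zero = np.zeros_like(pair.inverse_field.displacements)
        base_err, _ = endpoint_error(zero, pair.inverse_field)
        lcc = local_cross_correlation(
            pair.fixed, warped, window=hp.lcc_window, epsilon=hp.epsilon
        )
        smooth = smoothness_penalty(u)
        dsc_before.append(before)
        dsc_after.append(after)
        epe.append(mean_err)
        epe_baseline.append(base_err)
        joint.append(lcc + hp.lambda_ * smooth)
        smooth_u.append(smooth)
        smooth_v.append(smoothness_penalty(v) if v is not None else float("nan"))
    return {
        "dsc_before": dsc_before,
        "dsc_after": dsc_after,
        "mean_dsc_before": float(np.mean(dsc_before)),
        "mean_dsc_after": float(np.mean(dsc_after)),
        "mean_epe": float(np.mean(epe)),
        "mean_epe_baseline": float(np.mean(epe_baseline)),
        "epe_ratio": float(np.mean(epe) / np.mean(epe_baseline)),
        "mean_joint_objective": float(np.mean(joint)),
        "mean_smoothness_u": float(np.mean(smooth_u)),
        "mean_smoothness_v": float(np.mean(smooth_v)),
    }


def run_benchmark(
    mode: str,
    seed: int,
    iterations: int = 1500,
    datasets=None,
    hp: Hyperparams | None = None,
) -> dict:
    """Train one mode on the benchmark and evaluate it held-out.

    Returns initial ("at iteration 0") and final held-out metrics plus the
    training history.  ``datasets`` allows sharing generated pairs between
    modes trained on the same seed.
    """
    train_set, held_out = datasets if datasets is not None else benchmark_datasets(seed)
    hp = hp or Hyperparams()
    config = TrainingConfig(
        mode=mode,
        iterations=iterations,
        learning_rate=1e-3,
        batch_size=4,
        seed=seed,
        hyperparams=hp,
        checkpoint_every=max(1, iterations // 3),
    )
    ndim = len(train_set[0].fixed.shape)
    initial = evaluate_state(
        init_state(config, ndim, BENCH_SIM_SPEC, BENCH_DEN_SPEC), held_out, hp
    )
    state, history = train(train_set, config, BENCH_SIM_SPEC, BENCH_DEN_SPEC)
    final = evaluate_state(state, held_out, hp)
    return {"mode": mode, "seed": seed, "initial": initial, "final": final,
            "history": history}
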