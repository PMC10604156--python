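"""Fixed desk-scale benchmark protocols.

Two reusable study protocols, with all sizes fixed here so results are
comparable across runs:

* :func:`decoder_recovery_benchmark` — the MLP-vs-ridge neural decoding
  comparison on the full-structure synthetic dataset (1200 train / 50
  test, 2000 voxels, snr 5), in a linear and a tanh forward-model regime.
* :func:`ablation_benchmark` — the guidance-ablation comparison on a
  reduced dataset (240 train / 25 test, 150 voxels, 3 repeats) where
  decoding is deliberately imperfect, so removing a guidance channel has
  measurable consequences.
"""

from __future__ import annotations

import numpy as np

from .data_model import FeatureMatrix, VoxelMatrix, average_repeats
from .decoder import (
    BrainMlpSpec,
    TrainConfig,
    fit_ridge,
    predict_features,
    train_decoder,
)
from .metrics import RandomProjectionExtractor, evaluate_reconstructions
from .pipeline import (
    ABLATION_VARIANTS,
    PipelineConfig,
    make_mock_backends,
    run_full_pipeline,
    train_pipeline_decoders,
)
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "per_sample_pearson",
    "desk_mlp_spec",
    "select_ridge_l2",
    "decoder_recovery_benchmark",
    "ablation_benchmark",
]

RIDGE_L2_GRID = (1e-1, 1e1, 1e3, 1e5)


def per_sample_pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over samples of the Pearson correlation across feature dims."""
    rs = []
    for p, t in zip(np.asarray(pred), np.asarray(truth)):
        pc, tc = p - p.mean(), t - t.mean()
        denom = np.linalg.norm(pc) * np.linalg.norm(tc)
        rs.append(pc @ tc / denom if denom > 0 else 0.0)
    return float(np.mean(rs))


def desk_mlp_spec(in_dim: int, out_dim: int) -> BrainMlpSpec:
    """The desk-scale MLP architecture: 2 residual blocks of width 512."""
    return BrainMlpSpec(in_dim=in_dim, out_dim=out_dim, n_blocks=2, hidden_dim=512,
                        dropout_rate=0.15)


def select_ridge_l2(
    x: VoxelMatrix, z: FeatureMatrix, grid=RIDGE_L2_GRID, holdout_frac: float = 1 / 6
) -> float:
    """Pick the ridge penalty by recovery r on a held-out tail of the
    training split (a fair, tuned baseline)."""
    n = x.n_samples
    n_val = max(1, int(n * holdout_frac))
    tr = np.arange(n - n_val)
    va = np.arange(n - n_val, n)
    vm_tr = VoxelMatrix(x.values[tr], [x.sample_ids[i] for i in tr], x.voxel_ids)
    vm_va = VoxelMatrix(x.values[va], [x.sample_ids[i] for i in va], x.voxel_ids)
    z_tr = FeatureMatrix(z.values[tr], z.feature_kind)
    best_l2, best_r = grid[0], -np.inf
    for l2 in grid:
        dec = fit_ridge(vm_tr, z_tr, l2=l2)
        r = per_sample_pearson(predict_features(dec, vm_va).values, z.values[va])
        if r > best_r:
            best_r, best_l2 = r, l2
    return float(best_l2)


def decoder_recovery_benchmark(
    nonlinearity: str = "none", seed: int = 0, epochs: int = 50
) -> dict[str, float]:
    """Held-out latent recovery of the MLP vs the tuned ridge baseline.

    Returns mean per-sample Pearson r on the repeat-averaged test split
    for both decoders, under the full-structure synthetic conditions.
    """
    cfg = SyntheticConfig(snr=5.0, nonlinearity=nonlinearity, seed=seed)
    train, test, truth = generate_dataset(cfg)
    z = truth.true_latents["train"]
    z_test = truth.true_latents["test"].values
    x_test = average_repeats(test.fmri)

    l2 = select_ridge_l2(train.fmri, z)
    ridge = fit_ridge(train.fmri, z, l2=l2)
    r_ridge = per_sample_pearson(predict_features(ridge, x_test).values, z_test)

    spec = desk_mlp_spec(train.fmri.n_voxels, z.n_dims)
    mlp = train_decoder(train.fmri, z, spec, TrainConfig.desk(epochs=epochs, seed=seed))
    r_mlp = per_sample_pearson(predict_features(mlp, x_test).values, z_test)

    return {"r_mlp": r_mlp, "r_ridge": r_ridge, "ridge_l2": l2, "n_test": len(z_test)}


def ablation_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """Reduced study conditions for the ablation comparison: few voxels
    and few test repeats keep decoding imperfect, so the guidance channels
    carry real weight."""
    return SyntheticConfig(
        n_train=240,
        n_classes_train=30,
        images_per_class=8,
        n_test=25,
        n_test_repeats=3,
        n_voxels=150,
        latent_dim=32,
        visual_dim=64,
        text_dim=16,
        snr=5.0,
        seed=seed,
        image_size=32,
    )


def ablation_benchmark(seed: int = 0, epochs: int = 40) -> dict[str, dict[str, float]]:
    """Aggregate metrics of the four pipeline variants on the reduced
    synthetic benchmark; decoders are trained once and shared."""
    cfg = ablation_benchmark_config(seed)
    train, test, truth = generate_dataset(cfg)
    backends = make_mock_backends(cfg, train, test, truth)
    tcfg = TrainConfig(lr_init=3e-3, epochs=epochs, seed=seed)
    decoders = train_pipeline_decoders(train, backends, tcfg, hidden_dim=128)
    pcfg = PipelineConfig(output_size=cfg.image_size, seed=seed)
    extractors = [RandomProjectionExtractor("proj", dim=64, seed=seed)]
    out: dict[str, dict[str, float]] = {}
    for variant in ABLATION_VARIANTS:
        res = run_full_pipeline(
            train, test, backends, pipeline_cfg=pcfg, decoders=decoders, variant=variant
        )
        report = evaluate_reconstructions(test.images, res.final, extractors, size=cfg.image_size)
        out[variant] = report.aggregate
    return out
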