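"""Neural decoders mapping voxel responses to feature vectors.

Two decoder families share one surface: a residual MLP trained by AdamW
with a combined MSE + cosine-similarity loss and cosine-annealed learning
rate, and a closed-form multi-output ridge regression baseline.  Both store
the training-set feature statistics needed for the renormalization trick:
after prediction, each feature dimension's mean and standard deviation are
replaced by the training-set values, correcting the distribution shift that
regression-to-the-mean induces in decoded features.

One decoder is trained per subject and per feature kind (hierarchical
latents, visual embedding, text embedding).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _mlp
from .data_model import FeatureMatrix, ValidationError, VoxelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BrainMlpSpec",
    "TrainConfig",
    "FeatureStats",
    "TrainedDecoder",
    "DegenerateCosineError",
    "DivergenceError",
    "combined_loss",
    "build_brainmlp",
    "train_decoder",
    "predict_features",
    "renormalize",
    "fit_ridge",
    "save_decoder",
    "load_decoder",
]


class DegenerateCosineError(ValueError):
    """A sample with zero norm makes the cosine term undefined."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class BrainMlpSpec:
    """Architecture of the residual MLP decoder.

    The network is: input projection (linear in_dim->hidden_dim, GELU,
    dropout), then ``n_blocks`` residual linear blocks (linear
    hidden->hidden, LayerNorm, GELU, dropout, additive skip spanning the
    block), then a plain linear head hidden->out_dim.
    """

    in_dim: int
    out_dim: int
    n_blocks: int = 2
    hidden_dim: int = 4096
    dropout_rate: float = 0.15
    layernorm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.in_dim < 1 or self.out_dim < 1 or self.hidden_dim < 1:
            raise ValidationError("dims must be positive")
        if self.n_blocks < 1:
            raise ValidationError("need at least one residual block")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")

    @property
    def n_parameters(self) -> int:
        return _mlp.param_count(self.in_dim, self.out_dim, self.n_blocks, self.hidden_dim)


@dataclass
class TrainConfig:
    """Optimization recipe.

    Defaults follow the full-scale recipe (AdamW, initial lr 1e-4 with
    cosine annealing to 0, batch 64, 240 epochs, loss weights alpha1=0.9 on
    MSE and alpha2=-0.1 on cosine similarity).  ``desk()`` returns the
    reduced configuration used for CPU-scale runs and tests.
    """

    lr_init: float = 1e-4
    batch_size: int = 64
    epochs: int = 240
    alpha1: float = 0.9
    alpha2: float = -0.1
    weight_decay: float = 0.01
    standardize_voxels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValidationError("lr_init must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")

    @classmethod
    def desk(cls, epochs: int = 50, seed: int = 0) -> "TrainConfig":
        """Reduced desk-scale recipe: same optimizer and loss, fewer epochs,
        a larger initial lr (1e-3) so the shorter cosine schedule still
        reaches the converged regime on small synthetic problems."""
        return cls(lr_init=1e-3, epochs=epochs, seed=seed)


@dataclass
class FeatureStats:
    """Per-dimension mean and (population) standard deviation of the
    training-set features, used by the renormalization trick."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.std = np.asarray(self.std, dtype=np.float64).ravel()
        if self.mean.shape != self.std.shape:
            raise ValidationError("mean and std must have equal length")
        if np.any(self.std < 0):
            raise ValidationError("std entries must be >= 0")

    @classmethod
    def from_features(cls, z: FeatureMatrix | np.ndarray) -> "FeatureStats":
        vals = z.values if isinstance(z, FeatureMatrix) else np.asarray(z, dtype=np.float64)
        return cls(vals.mean(axis=0), vals.std(axis=0))  # population convention


@dataclass
class TrainedDecoder:
    """A fitted voxel->feature decoder (residual MLP or ridge)."""

    kind: str  # "mlp" | "ridge"
    spec: BrainMlpSpec | dict
    parameters: dict[str, np.ndarray]
    history: list[float] = field(default_factory=list)
    feature_stats: FeatureStats | None = None
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None
    config: TrainConfig | None = None
    feature_kind: str = "latent"
    layout: list[tuple[int, ...]] | None = None
    # stats of the decoder's own predictions on its training set; used by
    # the pipeline to calibrate renormalization without touching test data
    train_pred_stats: FeatureStats | None = None

    @property
    def in_dim(self) -> int:
        if self.kind == "mlp":
            return self.spec.in_dim
        return self.parameters["coef"].shape[0]

    @property
    def out_dim(self) -> int:
        if self.kind == "mlp":
            return self.spec.out_dim
        return self.parameters["coef"].shape[1]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt((a * a).sum(axis=1))


def combined_loss(
    z: FeatureMatrix | np.ndarray,
    z_hat: FeatureMatrix | np.ndarray,
    alpha1: float = 0.9,
    alpha2: float = -0.1,
) -> float:
    """Weighted sum of mean per-sample squared L2 error and mean cosine
    similarity:

        L = alpha1 * (1/N) sum_i ||z_i - zhat_i||^2
          + alpha2 * (1/N) sum_i cos(z_i, zhat_i)

    With alpha2 < 0 the cosine term rewards directional alignment.  A
    sample with zero norm in either argument makes its cosine undefined and
    raises; the training loop masks such samples instead.
    """
    zv = z.values if isinstance(z, FeatureMatrix) else np.asarray(z, dtype=np.float64)
    hv = z_hat.values if isinstance(z_hat, FeatureMatrix) else np.asarray(z_hat, dtype=np.float64)
    if zv.shape != hv.shape:
        raise ValidationError(f"shape mismatch: {zv.shape} vs {hv.shape}")
    nz, nh = _row_norms(zv), _row_norms(hv)
    if np.any(nz == 0) or np.any(nh == 0):
        raise DegenerateCosineError("zero-norm sample makes cosine similarity undefined")
    mse = ((zv - hv) ** 2).sum(axis=1).mean()
    cos = ((zv * hv).sum(axis=1) / (nz * nh)).mean()
    return float(alpha1 * mse + alpha2 * cos)


def _loss_and_grad(
    zv: np.ndarray, hv: np.ndarray, alpha1: float, alpha2: float
) -> tuple[float, np.ndarray]:
    """Loss and dL/dz_hat for a batch; zero-norm samples are masked out of
    the cosine term (with a warning logged once by the caller)."""
    n = zv.shape[0]
    diff = hv - zv
    mse = (diff * diff).sum(axis=1).mean()
    grad = alpha1 * 2.0 * diff / n

    nz, nh = _row_norms(zv), _row_norms(hv)
    ok = (nz > 0) & (nh > 0)
    cos_vals = np.zeros(n)
    if ok.any():
        zs, hs = zv[ok], hv[ok]
        nzs, nhs = nz[ok], nh[ok]
        c = (zs * hs).sum(axis=1) / (nzs * nhs)
        cos_vals[ok] = c
        dcos = zs / (nzs * nhs)[:, None] - (c / (nhs * nhs))[:, None] * hs
        grad[ok] += alpha2 * dcos / n
    loss = alpha1 * mse + alpha2 * cos_vals.mean()
    return float(loss), grad


# ---------------------------------------------------------------------------
# MLP build / train / predict
# ---------------------------------------------------------------------------


def build_brainmlp(spec: BrainMlpSpec, seed: int = 0) -> TrainedDecoder:
    """Instantiate an untrained decoder with seeded initialization."""
    rng = np.random.Generator(np.random.PCG64(seed))
    params = _mlp.init_params(spec.in_dim, spec.out_dim, spec.n_blocks, spec.hidden_dim, rng)
    return TrainedDecoder(kind="mlp", spec=spec, parameters=params)


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def train_decoder(
    x: VoxelMatrix,
    z: FeatureMatrix,
    spec: BrainMlpSpec,
    cfg: TrainConfig,
) -> TrainedDecoder:
    """Train a residual MLP decoder by mini-batch AdamW.

    The learning rate follows cosine annealing over the configured epochs;
    per-epoch mean loss is recorded in ``history``; the training-set
    feature statistics are stored for later renormalization.  Fully
    reproducible under ``cfg.seed`` on a single thread.
    """
    if x.n_samples != z.n_samples:
        raise ValidationError("voxel and feature rows must align")
    if x.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    if spec.in_dim != x.n_voxels or spec.out_dim != z.n_dims:
        raise ValidationError(
            f"spec dims ({spec.in_dim}->{spec.out_dim}) do not match data "
            f"({x.n_voxels}->{z.n_dims})"
        )

    xv = x.values
    input_mean = input_std = None
    if cfg.standardize_voxels:
        input_mean, input_std = _standardize_fit(xv)
        xv = (xv - input_mean) / input_std
    zv = z.values

    if np.any(_row_norms(zv) == 0):
        logger.warning("zero-norm target rows present; they are masked from the cosine term")

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    params = _mlp.init_params(spec.in_dim, spec.out_dim, spec.n_blocks, spec.hidden_dim, rng)
    opt = _mlp.AdamW(params, lr=cfg.lr_init, weight_decay=cfg.weight_decay)

    n = xv.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = _mlp.cosine_annealed_lr(cfg.lr_init, epoch, cfg.epochs)
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, zb = xv[idx], zv[idx]
            pred, cache = _mlp.forward(
                params, xb, spec.n_blocks, spec.dropout_rate, spec.layernorm_eps, rng
            )
            loss, dpred = _loss_and_grad(zb, pred, cfg.alpha1, cfg.alpha2)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}; reduce the learning rate"
                )
            grads = _mlp.backward(params, cache, dpred, spec.n_blocks)
            opt.step(params, grads)
            total += loss * len(idx)
            count += len(idx)
        history.append(total / count)

    dec = TrainedDecoder(
        kind="mlp",
        spec=spec,
        parameters=params,
        history=history,
        feature_stats=FeatureStats.from_features(z),
        input_mean=input_mean,
        input_std=input_std,
        config=cfg,
        feature_kind=z.feature_kind,
        layout=z.layout,
    )
    dec.train_pred_stats = FeatureStats.from_features(predict_features(dec, x))
    return dec


def predict_features(dec: TrainedDecoder, x: VoxelMatrix) -> FeatureMatrix:
    """Evaluation-mode forward pass (dropout off); deterministic."""
    if x.n_voxels != dec.in_dim:
        raise ValidationError(f"decoder expects {dec.in_dim} voxels, got {x.n_voxels}")
    xv = x.values
    if dec.input_mean is not None:
        xv = (xv - dec.input_mean) / dec.input_std
    if dec.kind == "mlp":
        pred, _ = _mlp.forward(
            dec.parameters, xv, dec.spec.n_blocks, 0.0, dec.spec.layernorm_eps, rng=None
        )
    elif dec.kind == "ridge":
        pred = xv @ dec.parameters["coef"] + dec.parameters["intercept"]
    else:
        raise ValidationError(f"unknown decoder kind {dec.kind!r}")
    return FeatureMatrix(pred, feature_kind=dec.feature_kind, layout=dec.layout)


def renormalize(
    pred: FeatureMatrix, stats: FeatureStats, pred_stats: FeatureStats | None = None
) -> FeatureMatrix:
    """Replace each predicted dimension's mean/std with the training stats.

    out[:, j] = (pred[:, j] - mean_pred_j) / std_pred_j * stats.std[j]
                + stats.mean[j]

    By default the predicted mean/std are the batch's own statistics, so
    the output's per-dimension mean and std equal ``stats`` exactly.
    ``pred_stats`` optionally supplies an external estimate of the
    prediction distribution (e.g., statistics of the decoder's predictions
    on its training set), which leaves perfect predictions untouched.

    A predicted dimension with zero variance cannot be standardized; it is
    set to the training mean and a warning is logged.
    """
    if pred.n_dims != stats.mean.shape[0]:
        raise ValidationError(
            f"stats cover {stats.mean.shape[0]} dims, predictions have {pred.n_dims}"
        )
    vals = pred.values
    if pred_stats is not None:
        mu, sd = pred_stats.mean, pred_stats.std
    else:
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)  # population convention, matching FeatureStats
    zero = sd == 0
    if zero.any():
        logger.warning(
            "renormalize: %d zero-variance predicted dims set to training mean", int(zero.sum())
        )
    sd_safe = np.where(zero, 1.0, sd)
    out = (vals - mu) / sd_safe * stats.std + stats.mean
    out[:, zero] = stats.mean[zero]
    return FeatureMatrix(out, feature_kind=pred.feature_kind, layout=pred.layout)


# ---------------------------------------------------------------------------
# Ridge baseline
# ---------------------------------------------------------------------------


def fit_ridge(x: VoxelMatrix, z: FeatureMatrix, l2: float = 1.0, standardize_voxels: bool = True) -> TrainedDecoder:
    """Closed-form multi-output ridge regression with intercept.

    With ``l2=0`` the system must be non-singular (ordinary least squares);
    otherwise a numerical error advises choosing ``l2 > 0``.
    """
    if x.n_samples != z.n_samples:
        raise ValidationError("voxel and feature rows must align")
    if l2 < 0:
        raise ValidationError("l2 must be >= 0")
    xv = x.values
    input_mean = input_std = None
    if standardize_voxels:
        input_mean, input_std = _standardize_fit(xv)
        xv = (xv - input_mean) / input_std

    xc = xv - xv.mean(axis=0)
    zc = z.values - z.values.mean(axis=0)
    if l2 == 0:
        if np.linalg.matrix_rank(xc) < xc.shape[1]:
            raise np.linalg.LinAlgError(
                "singular system with l2=0; use l2 > 0 for a regularized solution"
            )
        coef, *_ = np.linalg.lstsq(xc, zc, rcond=None)
    else:
        # SVD form of the ridge solution: numerically exact on the data
        # subspace even for vanishing l2 and rank-deficient designs
        U, S, Vt = np.linalg.svd(xc, full_matrices=False)
        shrink = S / (S * S + l2)
        coef = (Vt.T * shrink) @ (U.T @ zc)
    intercept = z.values.mean(axis=0) - xv.mean(axis=0) @ coef

    dec = TrainedDecoder(
        kind="ridge",
        spec={"l2": float(l2)},
        parameters={"coef": coef, "intercept": intercept},
        history=[],
        feature_stats=FeatureStats.from_features(z),
        input_mean=input_mean,
        input_std=input_std,
        feature_kind=z.feature_kind,
        layout=z.layout,
    )
    dec.train_pred_stats = FeatureStats.from_features(predict_features(dec, x))
    return dec


# ---------------------------------------------------------------------------
# Checkpoint serialization (single-file npz archive)
# ---------------------------------------------------------------------------


def save_decoder(dec: TrainedDecoder, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "kind": dec.kind,
        "feature_kind": dec.feature_kind,
        "layout": [list(s) for s in dec.layout] if dec.layout else None,
        "history": dec.history,
        "spec": dec.spec.__dict__ if isinstance(dec.spec, BrainMlpSpec) else dec.spec,
        "config": dec.config.__dict__ if dec.config else None,
    }
    arrays = {f"param.{k}": v for k, v in dec.parameters.items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if dec.feature_stats is not None:
        arrays["stats.mean"] = dec.feature_stats.mean
        arrays["stats.std"] = dec.feature_stats.std
    if dec.train_pred_stats is not None:
        arrays["predstats.mean"] = dec.train_pred_stats.mean
        arrays["predstats.std"] = dec.train_pred_stats.std
    if dec.input_mean is not None:
        arrays["input.mean"] = dec.input_mean
        arrays["input.std"] = dec.input_std
    np.savez(path, **arrays)
    return path


def load_decoder(path: str | Path) -> TrainedDecoder:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        params = {k[len("param.") :]: z[k] for k in z.files if k.startswith("param.")}
        stats = None
        if "stats.mean" in z.files:
            stats = FeatureStats(z["stats.mean"], z["stats.std"])
        pred_stats = None
        if "predstats.mean" in z.files:
            pred_stats = FeatureStats(z["predstats.mean"], z["predstats.std"])
        input_mean = z["input.mean"] if "input.mean" in z.files else None
        input_std = z["input.std"] if "input.std" in z.files else None
    spec = meta["spec"]
    if meta["kind"] == "mlp":
        spec = BrainMlpSpec(**spec)
    cfg = TrainConfig(**meta["config"]) if meta.get("config") else None
    layout = [tuple(s) for s in meta["layout"]] if meta.get("layout") else None
    return TrainedDecoder(
        kind=meta["kind"],
        spec=spec,
        parameters=params,
        history=list(meta.get("history", [])),
        feature_stats=stats,
        input_mean=input_mean,
        input_std=input_std,
        config=cfg,
        feature_kind=meta.get("feature_kind", "latent"),
        layout=layout,
        train_pred_stats=pred_stats,
    )
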