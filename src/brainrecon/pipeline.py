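"""Three-stage dual-guided reconstruction pipeline.

Stage I decodes hierarchical codec latents from test fMRI and decodes them
to a coarse initial-guess image.  Stage II captions the training images so
text embeddings can serve as decoder targets.  Stage III generates the
final reconstruction from the initial guess under dual guidance: a decoded
visual embedding (weight 0.7 by default) and a decoded text embedding
(weight 0.3), via a pluggable guided generator.

Three decoders are trained per subject — one per feature kind (latent,
visual, text) — and every stage is deterministic under its seed, so two
runs with identical inputs produce bit-identical reconstructions.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np

from .backends import (
    Captioner,
    GuidedGenerator,
    LatentCodec,
    MockCaptioner,
    MockFeatureEncoder,
    MockGuidedGenerator,
    MockLatentCodec,
    StageBackends,
)
from .data_model import (
    CaptionSet,
    FeatureMatrix,
    ImageSet,
    PairedDataset,
    ValidationError,
    VoxelMatrix,
    average_repeats,
    flatten_latents,
)
from .decoder import (
    BrainMlpSpec,
    TrainConfig,
    TrainedDecoder,
    fit_ridge,
    predict_features,
    renormalize,
    train_decoder,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ReconstructionResult",
    "ABLATION_VARIANTS",
    "stage1_initial_guess",
    "stage2_captions",
    "stage3_reconstruct",
    "train_pipeline_decoders",
    "run_full_pipeline",
    "run_ablation",
    "make_mock_backends",
]

ABLATION_VARIANTS = ("full", "without_initial_guess", "without_clip_text", "without_clip_vision")


@dataclass
class PipelineConfig:
    """Generation-stage knobs.

    Guidance intensities default to 0.7 (visual) and 0.3 (text); 50
    inference steps and 512x512 output match the full-scale generator
    (the mock generator accepts but ignores the step count).
    """

    guidance_visual: float = 0.7
    guidance_text: float = 0.3
    inference_steps: int = 50
    output_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.guidance_visual < 0 or self.guidance_text < 0:
            raise ValidationError("guidance weights must be >= 0")
        if self.inference_steps < 1:
            raise ValidationError("inference_steps must be >= 1")


@dataclass
class ReconstructionResult:
    initial_guess: ImageSet
    captions: CaptionSet  # train-side captions used for text targets
    final: ImageSet
    provenance: dict


def _decoder_checksum(dec: TrainedDecoder) -> str:
    h = hashlib.sha1()
    for k in sorted(dec.parameters):
        h.update(k.encode())
        h.update(np.ascontiguousarray(dec.parameters[k]).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage1_initial_guess(
    dec_latent: TrainedDecoder, x_test: VoxelMatrix, codec: LatentCodec
) -> ImageSet:
    """Decode codec latents from test fMRI and render the initial guess.

    predict -> renormalize (stored training stats, calibrated by the
    decoder's train-set prediction stats) -> reshape to the codec's
    hierarchical layout -> codec.decode, per stimulus.
    """
    flat_dim = int(sum(np.prod(s) for s in codec.layout))
    if dec_latent.out_dim != flat_dim:
        raise ValidationError(
            f"latent decoder emits {dec_latent.out_dim} dims but codec expects {flat_dim}"
        )
    pred = predict_features(dec_latent, x_test)
    pred = renormalize(pred, dec_latent.feature_stats, dec_latent.train_pred_stats)
    pred = FeatureMatrix(pred.values, "latent", [tuple(s) for s in codec.layout])
    from .data_model import reshape_latents

    images = [codec.decode(layers) for layers in reshape_latents(pred)]
    return ImageSet(images, list(x_test.sample_ids))


def stage2_captions(images: ImageSet, cap: Captioner) -> CaptionSet:
    """Caption every (training) image; these captions feed the text-feature
    target extraction."""
    if len(images) == 0:
        raise ValidationError("empty image set")
    captions = []
    for iid, img in zip(images.image_ids, images.images):
        try:
            captions.append(cap.caption(img))
        except Exception as exc:
            raise RuntimeError(f"captioner failed on image {iid!r}: {exc}") from exc
    return CaptionSet(captions, list(images.image_ids))


def stage3_reconstruct(
    init: ImageSet,
    c_vision_hat: FeatureMatrix,
    c_text_hat: FeatureMatrix,
    gen: GuidedGenerator,
    cfg: PipelineConfig,
) -> ImageSet:
    """Generate the final reconstruction per stimulus under dual guidance."""
    if c_vision_hat.n_samples != len(init) or c_text_hat.n_samples != len(init):
        raise ValidationError("guidance features must align with initial guesses")
    out = []
    for i, (iid, img) in enumerate(zip(init.image_ids, init.images)):
        out.append(gen.generate(img, c_vision_hat.values[i], c_text_hat.values[i], cfg))
    return ImageSet(out, list(init.image_ids))


# ---------------------------------------------------------------------------
# Decoder training over backends
# ---------------------------------------------------------------------------


def compute_targets(
    train: PairedDataset, backends: StageBackends
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix, CaptionSet]:
    """Extract the three training target matrices from the backends:
    flattened codec latents, visual embeddings, and text embeddings of the
    stage-II captions."""
    codec, enc = backends.codec, backends.encoder
    z_latent = flatten_latents([codec.encode(im) for im in train.images.images])
    c_vision = FeatureMatrix(
        np.stack([enc.encode_image(im) for im in train.images.images]), "visual"
    )
    captions = stage2_captions(train.images, backends.captioner)
    c_text = FeatureMatrix(np.stack([enc.encode_text(c) for c in captions.captions]), "text")
    return z_latent, c_vision, c_text, captions


def train_pipeline_decoders(
    train: PairedDataset,
    backends: StageBackends,
    train_cfg: TrainConfig | None = None,
    decoder_kind: str = "mlp",
    hidden_dim: int = 256,
    n_blocks: int = 2,
    dropout_rate: float = 0.15,
    ridge_l2: float = 10.0,
) -> dict[str, TrainedDecoder]:
    """Train the three per-feature-kind decoders on the training split."""
    if decoder_kind not in ("mlp", "ridge"):
        raise ValidationError(f"unknown decoder kind {decoder_kind!r}")
    train_cfg = train_cfg or TrainConfig.desk()
    z_latent, c_vision, c_text, _ = compute_targets(train, backends)
    decoders = {}
    for offset, (name, target) in enumerate(
        [("latent", z_latent), ("visual", c_vision), ("text", c_text)]
    ):
        if decoder_kind == "ridge":
            decoders[name] = fit_ridge(train.fmri, target, l2=ridge_l2)
        else:
            spec = BrainMlpSpec(
                in_dim=train.fmri.n_voxels,
                out_dim=target.n_dims,
                n_blocks=n_blocks,
                hidden_dim=hidden_dim,
                dropout_rate=dropout_rate,
            )
            cfg_k = replace(train_cfg, seed=train_cfg.seed + offset)
            decoders[name] = train_decoder(train.fmri, target, spec, cfg_k)
        logger.info("trained %s decoder (%s), out_dim=%d", name, decoder_kind, target.n_dims)
    return decoders


# ---------------------------------------------------------------------------
# Full pipeline and ablations
# ---------------------------------------------------------------------------


def _mid_gray_like(images: ImageSet) -> ImageSet:
    gray = [np.full_like(im, 0.5) for im in images.images]
    return ImageSet(gray, list(images.image_ids))


def run_full_pipeline(
    train: PairedDataset,
    test: PairedDataset,
    backends: StageBackends,
    train_cfg: TrainConfig | None = None,
    pipeline_cfg: PipelineConfig | None = None,
    decoders: dict[str, TrainedDecoder] | None = None,
    decoder_kind: str = "mlp",
    average_test_repeats: bool = True,
    variant: str = "full",
    **decoder_kwargs,
) -> ReconstructionResult:
    """Train (or reuse) the three decoders and run stages I-III on test fMRI.

    ``variant`` selects an ablation: ``without_initial_guess`` replaces the
    stage-I image with mid-gray, ``without_clip_text``/``without_clip_vision``
    zero the corresponding guidance weight.  Reproducible under seed.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    if decoders is None:
        decoders = train_pipeline_decoders(
            train, backends, train_cfg, decoder_kind=decoder_kind, **decoder_kwargs
        )

    x_test = test.fmri
    if average_test_repeats and x_test.repeat_of is not None:
        x_test = average_repeats(x_test)
    logger.info("stage I: decoding initial guesses for %d stimuli", x_test.n_samples)
    init = stage1_initial_guess(decoders["latent"], x_test, backends.codec)

    logger.info("stage II: captioning %d training images", len(train.images))
    captions = stage2_captions(train.images, backends.captioner)

    logger.info("stage III: dual-guided generation (variant=%s)", variant)
    cfg = pipeline_cfg
    if variant == "without_clip_text":
        cfg = replace(cfg, guidance_text=0.0)
    elif variant == "without_clip_vision":
        cfg = replace(cfg, guidance_visual=0.0)

    v_hat = renormalize(
        predict_features(decoders["visual"], x_test),
        decoders["visual"].feature_stats,
        decoders["visual"].train_pred_stats,
    )
    t_hat = renormalize(
        predict_features(decoders["text"], x_test),
        decoders["text"].feature_stats,
        decoders["text"].train_pred_stats,
    )

    init_for_gen = _mid_gray_like(init) if variant == "without_initial_guess" else init
    final = stage3_reconstruct(init_for_gen, v_hat, t_hat, backends.generator, cfg)

    provenance = {
        "variant": variant,
        "pipeline_config": asdict(cfg),
        "decoder_checksums": {k: _decoder_checksum(d) for k, d in decoders.items()},
        "n_test_stimuli": len(final),
    }
    return ReconstructionResult(
        initial_guess=init_for_gen, captions=captions, final=final, provenance=provenance
    )


def run_ablation(
    variant: str,
    train: PairedDataset,
    test: PairedDataset,
    backends: StageBackends,
    **kwargs,
) -> ReconstructionResult:
    """Run one named ablation variant (``full`` reproduces the unablated
    pipeline bit-exactly)."""
    return run_full_pipeline(train, test, backends, variant=variant, **kwargs)


# ---------------------------------------------------------------------------
# Mock backend wiring for synthetic datasets
# ---------------------------------------------------------------------------


def make_mock_backends(
    cfg,
    train: PairedDataset,
    test: PairedDataset,
    truth,
    gallery: str = "train+test",
) -> StageBackends:
    """Build coherent mock backends for a synthetic dataset.

    The codec decodes latents through the synthetic renderer and encodes
    registered stimulus images back to their true latents; the captioner
    returns the known captions; the feature encoder is the same seeded
    projection that defined the dataset's true visual/text features.  The
    generator's gallery stands in for the pretrained generator's image
    manifold; by default it contains the train and test stimuli so that a
    perfectly decoded test stimulus is producible.
    """
    from .synthetic import latent_layout, render_toy_images

    layout = latent_layout(cfg.latent_dim)

    def decode_fn(flat: np.ndarray) -> np.ndarray:
        return render_toy_images(flat[np.newaxis, :], cfg.image_size).images[0]

    codec = MockLatentCodec(layout, decode_fn, cfg.image_size)
    codec.register(train.images, truth.true_latents["train"].values)
    codec.register(test.images, truth.true_latents["test"].values)

    captioner = MockCaptioner()
    captioner.register(train.images, train.captions.captions)
    if test.captions is not None:
        captioner.register(test.images, test.captions.captions)

    encoder = MockFeatureEncoder(
        visual_dim=cfg.visual_dim,
        text_dim=cfg.text_dim,
        vocabulary=truth.vocabulary,
        seed=truth.feature_seed,
    )

    if gallery == "train+test":
        imgs = ImageSet(
            train.images.images + test.images.images,
            list(train.images.image_ids) + list(test.images.image_ids),
        )
        feat_v = np.vstack([truth.true_visual["train"].values, truth.true_visual["test"].values])
        feat_t = np.vstack([truth.true_text["train"].values, truth.true_text["test"].values])
    elif gallery == "train":
        imgs = train.images
        feat_v = truth.true_visual["train"].values
        feat_t = truth.true_text["train"].values
    else:
        raise ValidationError(f"unknown gallery choice {gallery!r}")
    generator = MockGuidedGenerator(imgs, feat_v, feat_t)

    return StageBackends(codec=codec, captioner=captioner, encoder=encoder, generator=generator)
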