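"""Pluggable generative-stage backends.

The three-stage reconstruction pipeline is expressed over four interfaces:

* ``LatentCodec`` — hierarchical image autoencoder (the full-scale system
  uses a pretrained VDVAE, flattening the first 31 layers of latents into a
  91168-dimensional vector);
* ``Captioner`` — image-to-text captioning (full scale: BLIP);
* ``FeatureEncoder`` — image and text embedding (full scale: CLIP ViT-L/14,
  visual grid 257x768, text grid 77x768);
* ``GuidedGenerator`` — image-to-image generation conditioned on visual and
  text guidance (full scale: Versatile Diffusion, 50 inference steps,
  512x512 output).

The pretrained systems are GPU-scale downloads; this module ships seeded,
deterministic mock implementations with the same contracts so the whole
pipeline runs and is testable at desk scale.  Adapters for the pretrained
models plug into the same interfaces (stubs below document the expected
shapes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .data_model import ImageSet, ValidationError

__all__ = [
    "LatentCodec",
    "Captioner",
    "FeatureEncoder",
    "GuidedGenerator",
    "StageBackends",
    "MockLatentCodec",
    "MockCaptioner",
    "MockFeatureEncoder",
    "MockGuidedGenerator",
    "image_fingerprint",
    "VDVAECodecStub",
    "BLIPCaptionerStub",
    "CLIPEncoderStub",
    "VersatileDiffusionStub",
]


def image_fingerprint(img: np.ndarray) -> str:
    """Stable identifier of an image's 8-bit content (PNG-round-trip safe)."""
    arr = np.round(np.asarray(img, dtype=np.float64) * 255.0).astype(np.uint8)
    h = hashlib.sha1(arr.tobytes())
    h.update(str(arr.shape).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Interfaces
# ---------------------------------------------------------------------------


@runtime_checkable
class LatentCodec(Protocol):
    """Hierarchical latent image codec."""

    layout: list[tuple[int, ...]]

    def encode(self, img: np.ndarray) -> list[np.ndarray]: ...

    def decode(self, latents: list[np.ndarray]) -> np.ndarray: ...

    @property
    def n_layers_used(self) -> int: ...


@runtime_checkable
class Captioner(Protocol):
    def caption(self, img: np.ndarray) -> str: ...


@runtime_checkable
class FeatureEncoder(Protocol):
    visual_dim: int
    text_dim: int

    def encode_image(self, img: np.ndarray) -> np.ndarray: ...

    def encode_text(self, text: str) -> np.ndarray: ...


@runtime_checkable
class GuidedGenerator(Protocol):
    def generate(self, init: np.ndarray, v: np.ndarray, t: np.ndarray, cfg) -> np.ndarray: ...


@dataclass
class StageBackends:
    """The four pluggable backends consumed by the pipeline."""

    codec: LatentCodec
    captioner: Captioner
    encoder: FeatureEncoder
    generator: GuidedGenerator


# ---------------------------------------------------------------------------
# Mocks
# ---------------------------------------------------------------------------


class MockLatentCodec:
    """Registry-backed codec over a known rendering function.

    ``decode`` renders an image deterministically from flattened latents;
    ``encode`` looks up the exact latents an image was rendered from
    (registered at construction).  This makes encode/decode a true inverse
    pair on the registered stimulus domain, which is what the full-scale
    pretrained codec provides approximately on natural images.
    """

    def __init__(
        self,
        layout: list[tuple[int, ...]],
        decode_fn: Callable[[np.ndarray], np.ndarray],
        image_size: int,
    ) -> None:
        self.layout = [tuple(s) for s in layout]
        self._decode_fn = decode_fn
        self.image_size = image_size
        self._registry: dict[str, np.ndarray] = {}

    @property
    def n_layers_used(self) -> int:
        return len(self.layout)

    @property
    def flat_dim(self) -> int:
        return int(sum(np.prod(s) for s in self.layout))

    def register(self, images: ImageSet, flat_latents: np.ndarray) -> None:
        flat_latents = np.asarray(flat_latents, dtype=np.float64)
        if flat_latents.shape[0] != len(images):
            raise ValidationError("latent rows must align with images")
        for iid, img, row in zip(images.image_ids, images.images, flat_latents):
            fp = image_fingerprint(img)
            if fp in self._registry and not np.array_equal(self._registry[fp], row):
                raise ValidationError(
                    f"image {iid!r} renders identically to an already-registered "
                    "stimulus with different latents; the codec cannot invert it"
                )
            self._registry[fp] = row

    def _split(self, flat: np.ndarray) -> list[np.ndarray]:
        out, offs = [], 0
        for shape in self.layout:
            size = int(np.prod(shape))
            out.append(flat[offs : offs + size].reshape(shape))
            offs += size
        return out

    def encode(self, img: np.ndarray) -> list[np.ndarray]:
        fp = image_fingerprint(img)
        if fp not in self._registry:
            raise KeyError("image not in the mock codec's registered stimulus domain")
        return self._split(self._registry[fp])

    def decode(self, latents: list[np.ndarray]) -> np.ndarray:
        flat = np.concatenate([np.asarray(a, dtype=np.float64).ravel() for a in latents])
        if flat.shape[0] != self.flat_dim:
            raise ValidationError(
                f"latents flatten to {flat.shape[0]} dims, codec expects {self.flat_dim}"
            )
        return self._decode_fn(flat)


class MockCaptioner:
    """Registry-backed captioner: returns the known caption of a registered
    image (the full-scale captioner generates one from pixels)."""

    def __init__(self) -> None:
        self._registry: dict[str, str] = {}

    def register(self, images: ImageSet, captions: list[str]) -> None:
        if len(captions) != len(images):
            raise ValidationError("captions must align with images")
        for img, cap in zip(images.images, captions):
            self._registry[image_fingerprint(img)] = cap

    def caption(self, img: np.ndarray) -> str:
        fp = image_fingerprint(img)
        if fp not in self._registry:
            raise KeyError("image not in the mock captioner's registered domain")
        return self._registry[fp]


class MockFeatureEncoder:
    """Seeded random-projection image/text embedder.

    Images are bilinearly downsampled to ``input_size`` and linearly
    projected to ``visual_dim``.  Text is embedded as a seeded projection
    of its bag of words (class names are tokenized on underscores), so
    captions sharing attribute words — e.g. the same shape or color —
    land nearby, the way a real text encoder places semantically similar
    captions close together; this is what lets a text decoder generalize
    to captions of classes never seen in training.  Unknown words
    contribute deterministic hash-seeded vectors.  Both maps are
    deterministic and fixed-dimension.
    """

    def __init__(
        self,
        visual_dim: int = 128,
        text_dim: int = 32,
        vocabulary: list[str] | None = None,
        seed: int = 0,
        input_size: int = 16,
    ) -> None:
        self.visual_dim = visual_dim
        self.text_dim = text_dim
        self.vocabulary = list(vocabulary or [])
        self.input_size = input_size
        rng = np.random.Generator(np.random.PCG64(seed))
        d_in = input_size * input_size * 3
        self._proj_v = rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, visual_dim))
        words = sorted({w for name in self.vocabulary for w in self._tokenize(name)})
        self._word_index = {w: i for i, w in enumerate(words)}
        n_words = max(1, len(words))
        self._proj_t = rng.normal(0.0, 1.0, (n_words, text_dim))

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        return [w for w in text.replace("_", " ").lower().split() if w]

    def encode_image(self, img: np.ndarray) -> np.ndarray:
        from .metrics import _bilinear_resize

        small = _bilinear_resize(np.asarray(img, dtype=np.float64), self.input_size)
        return small.ravel() @ self._proj_v

    def _word_vector(self, word: str) -> np.ndarray:
        idx = self._word_index.get(word)
        if idx is not None:
            return self._proj_t[idx]
        # deterministic hash-seeded vector for out-of-vocabulary words
        h = hashlib.sha256(word.encode()).digest()
        rng = np.random.Generator(np.random.PCG64(int.from_bytes(h[:4], "big")))
        return rng.normal(0.0, 1.0, self.text_dim)

    def encode_text(self, text: str) -> np.ndarray:
        # stop words and bare numerals (class-name disambiguation
        # suffixes) carry no semantics and are dropped
        stop = {"a", "photo", "of"}
        tokens = [w for w in self._tokenize(text) if w not in stop and not w.isdigit()]
        if not tokens:
            tokens = self._tokenize(text)
        out = np.zeros(self.text_dim)
        for w in tokens:
            out += self._word_vector(w)
        return out / np.sqrt(len(tokens))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


class MockGuidedGenerator:
    """Retrieval-and-blend stand-in for the guided diffusion generator.

    The gallery plays the role of the pretrained generator's image
    manifold.  Each gallery image g is scored

        guidance_visual * cos(v, feat_v(g)) + guidance_text * cos(t, feat_t(g))

    and the output is the pixel blend ``beta * argmax + (1 - beta) * init``
    (ties broken by lowest gallery index).  ``inference_steps`` and the
    seed are accepted for interface parity but have no effect here: the
    mock is fully deterministic.
    """

    beta: float = 0.8

    def __init__(
        self,
        gallery: ImageSet,
        gallery_visual: np.ndarray,
        gallery_text: np.ndarray,
        beta: float = 0.8,
    ) -> None:
        if len(gallery) == 0:
            raise ValidationError("gallery must be non-empty")
        self.gallery = gallery
        self.gallery_visual = np.asarray(gallery_visual, dtype=np.float64)
        self.gallery_text = np.asarray(gallery_text, dtype=np.float64)
        if self.gallery_visual.shape[0] != len(gallery) or self.gallery_text.shape[0] != len(
            gallery
        ):
            raise ValidationError("gallery features must align with gallery images")
        self.beta = beta

    def score_gallery(self, v: np.ndarray, t: np.ndarray, cfg) -> np.ndarray:
        gv, gt = float(cfg.guidance_visual), float(cfg.guidance_text)
        if gv == 0.0 and gt == 0.0:
            raise ValidationError("both guidance weights are zero; nothing to condition on")
        scores = np.zeros(len(self.gallery))
        if gv > 0.0:
            scores += gv * np.array([_cosine(v, f) for f in self.gallery_visual])
        if gt > 0.0:
            scores += gt * np.array([_cosine(t, f) for f in self.gallery_text])
        return scores

    def generate(self, init: np.ndarray, v: np.ndarray, t: np.ndarray, cfg) -> np.ndarray:
        from .metrics import _bilinear_resize

        scores = self.score_gallery(v, t, cfg)
        best = int(np.argmax(scores))  # np.argmax returns the lowest tied index
        chosen = self.gallery.images[best]
        init = np.asarray(init, dtype=np.float64)
        if init.shape != chosen.shape:
            init = _bilinear_resize(init, chosen.shape[0])
        out = self.beta * chosen + (1.0 - self.beta) * init
        size = int(getattr(cfg, "output_size", chosen.shape[0]))
        if size != out.shape[0]:
            out = _bilinear_resize(out, size)
        return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Pretrained-adapter stubs (documented shapes; not implemented)
# ---------------------------------------------------------------------------

_STUB_MSG = (
    "{name} requires GPU-scale pretrained weights and is provided as an "
    "interface stub only; use the mock backends for desk-scale runs."
)


class VDVAECodecStub:
    """Adapter stub for a pretrained 75-layer hierarchical VAE codec.

    Expected contract: the first 31 layers of latents flatten to a
    91168-dimensional vector; images are 64x64 RGB.
    """

    n_layers_used = 31
    flat_dim = 91168

    def encode(self, img):  # pragma: no cover - stub
        raise NotImplementedError(_STUB_MSG.format(name="VDVAECodecStub"))

    def decode(self, latents):  # pragma: no cover - stub
        raise NotImplementedError(_STUB_MSG.format(name="VDVAECodecStub"))


class BLIPCaptionerStub:
    """Adapter stub for a pretrained BLIP captioner."""

    def caption(self, img):  # pragma: no cover - stub
        raise NotImplementedError(_STUB_MSG.format(name="BLIPCaptionerStub"))


class CLIPEncoderStub:
    """Adapter stub for a pretrained CLIP ViT-L/14 encoder.

    Expected contract: visual grid 257x768 (flattened: 197376 dims), text
    grid 77x768 (flattened: 59136 dims).
    """

    visual_dim = 257 * 768
    text_dim = 77 * 768

    def encode_image(self, img):  # pragma: no cover - stub
        raise NotImplementedError(_STUB_MSG.format(name="CLIPEncoderStub"))

    def encode_text(self, text):  # pragma: no cover - stub
        raise NotImplementedError(_STUB_MSG.format(name="CLIPEncoderStub"))


class VersatileDiffusionStub:
    """Adapter stub for a pretrained dual-conditioned latent diffusion
    image-to-image generator (50 inference steps, 512x512 output)."""

    def generate(self, init, v, t, cfg):  # pragma: no cover - stub
        raise NotImplementedError(_STUB_MSG.format(name="VersatileDiffusionStub"))
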