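"""Sequence-representation backends.

A backend maps a protein sequence to an L x D per-residue representation
matrix; the predictor consumes the column-wise mean of that matrix (mean
pooling).  Three interchangeable backends are provided:

* :class:`OneHotEncoder` — indicator rows, D = 20;
* :class:`EmbeddingEncoder` — a trainable 20 x D token-embedding table,
  learned jointly with the prediction head;
* :class:`PrecomputedEncoder` — matrices loaded from a portable ``.npz``
  archive keyed by canonical variant string, so real protein-language-model
  embeddings (e.g. L x 1280) drop in without code changes.

Note that mean pooling of a context-free per-token representation reduces to
amino-acid composition; positional information only enters through the
precomputed backend.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .variants import AA_ALPHABET, Variant, apply_variant

AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


class EncoderError(ValueError):
    pass


def pool(representation: np.ndarray) -> np.ndarray:
    """Mean-pool an L x D representation matrix to a length-D vector."""
    rep = np.asarray(representation, dtype=float)
    if rep.ndim != 2 or rep.shape[0] < 1:
        raise EncoderError(f"expected a non-empty L x D matrix, got shape {rep.shape}")
    return rep.mean(axis=0)


def _sequence_indices(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[aa] for aa in seq], dtype=np.intp)
    except KeyError as exc:
        raise EncoderError(f"non-standard residue {exc.args[0]!r} in sequence") from None


class EncoderBackend:
    """Contract: deterministic map sequence -> L x D matrix with finite entries."""

    name: str = "base"
    dim: int

    def encode(self, seq: str) -> np.ndarray:
        raise NotImplementedError

    def encode_variant(self, variant: Variant, wild_type: str) -> np.ndarray:
        return self.encode(apply_variant(variant, wild_type))

    def pooled(self, variant: Variant, wild_type: str) -> np.ndarray:
        return pool(self.encode_variant(variant, wild_type))

    # trainable backends override these
    trainable: bool = False

    def feature_matrix(self, variants, wild_type: str) -> np.ndarray:
        """Stack pooled vectors for a batch of variants into (n, D)."""
        return np.stack([self.pooled(v, wild_type) for v in variants])


class OneHotEncoder(EncoderBackend):
    """Indicator representation; row for residue a is the one-hot vector of a."""

    name = "one-hot"
    dim = 20

    def encode(self, seq: str) -> np.ndarray:
        if not seq:
            raise EncoderError("empty sequence")
        idx = _sequence_indices(seq)
        rep = np.zeros((len(seq), 20))
        rep[np.arange(len(seq)), idx] = 1.0
        return rep


class EmbeddingEncoder(EncoderBackend):
    """Trainable token-embedding table (20 x D), seeded Gaussian init.

    The pooled vector is ``composition @ table`` where composition is the
    normalized amino-acid count vector, so the table can be updated by the
    head's optimizer (see StabilityModel with ``finetune_encoder=True``).
    """

    name = "embedding"
    trainable = True

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        rng = np.random.default_rng(seed)
        self.table = rng.normal(0.0, 1.0, size=(20, dim))

    def encode(self, seq: str) -> np.ndarray:
        if not seq:
            raise EncoderError("empty sequence")
        return self.table[_sequence_indices(seq)]

    @staticmethod
    def composition(seq: str) -> np.ndarray:
        """Normalized amino-acid count vector (length 20, sums to 1)."""
        idx = _sequence_indices(seq)
        counts = np.bincount(idx, minlength=20).astype(float)
        return counts / len(seq)


class PrecomputedEncoder(EncoderBackend):
    """Per-variant representation matrices stored in a ``.npz`` archive.

    Archive keys are canonical variant strings (``"WT"``, ``"L6P/D17V"``,
    ...); values are L x D float arrays.  This is the drop-in slot for real
    protein-language-model embeddings.
    """

    name = "precomputed"

    def __init__(self, path):
        self.path = Path(path)
        self._store = np.load(self.path)
        keys = list(self._store.keys())
        if not keys:
            raise EncoderError(f"{path} contains no arrays")
        first = self._store[keys[0]]
        if first.ndim != 2:
            raise EncoderError(f"array {keys[0]!r} is not an L x D matrix")
        self.dim = first.shape[1]

    def encode(self, seq: str) -> np.ndarray:  # pragma: no cover - keyed by variant
        raise EncoderError(
            "precomputed backend is keyed by variant string, use encode_variant"
        )

    def encode_variant(self, variant: Variant, wild_type: str) -> np.ndarray:
        key = str(variant)
        if key not in self._store:
            raise EncoderError(f"no precomputed embedding for variant {key!r}")
        rep = np.asarray(self._store[key], dtype=float)
        if not np.all(np.isfinite(rep)):
            raise EncoderError(f"non-finite entries in embedding for {key!r}")
        return rep

    @staticmethod
    def save(path, matrices: dict[str, np.ndarray]) -> None:
        """Write a variant-keyed embedding archive readable by this backend."""
        np.savez(path, **{k: np.asarray(v, dtype=float) for k, v in matrices.items()})


def get_backend(name: str, **kwargs) -> EncoderBackend:
    """Backend factory used by the CLI and checkpoint loader."""
    if name in ("one-hot", "onehot"):
        return OneHotEncoder()
    if name == "embedding":
        return EmbeddingEncoder(**kwargs)
    if name == "precomputed":
        return PrecomputedEncoder(**kwargs)
    raise EncoderError(f"unknown encoder backend {name!r}")
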