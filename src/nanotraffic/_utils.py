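"""Shared helpers: validation, seeded substreams, small numerics."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["ValidationError", "require", "substream", "data_substream"]


class ValidationError(ValueError):
    """Raised when an input value or table violates a documented contract."""


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one integer seed.

    Every source of randomness in the package flows through one of these so a
    whole run is reconstructable from a single reported seed; distinct stage
    names give statistically independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def data_substream(seed: int, values: np.ndarray) -> np.random.Generator:
    """Substream keyed on the *content* of an array rather than a label.

    Used for per-group bootstraps: two groups holding identical data receive
    identical resampling streams, so comparing a group with itself is exactly
    a null comparison (t = 0).
    """
    digest = zlib.crc32(np.ascontiguousarray(values, dtype=np.float64).tobytes())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest]))
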