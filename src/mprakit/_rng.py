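"""Seed derivation: one root seed, independent child streams per stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(root_seed: int, *labels: object) -> int:
    """Derive a stable 31-bit child seed from a root seed and string labels.

    The label hash is CRC32-based, so the mapping is fixed across runs and
    platforms; distinct labels give independent streams for each pipeline stage.
    """
    tag = "/".join(str(x) for x in labels)
    h = zlib.crc32(tag.encode()) & 0x7FFFFFFF
    return (int(root_seed) ^ h) & 0x7FFFFFFF


def child_rng(root_seed: int, *labels: object) -> np.random.Generator:
    """A numpy Generator seeded from ``child_seed(root_seed, *labels)``."""
    return np.random.default_rng(child_seed(root_seed, *labels))
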