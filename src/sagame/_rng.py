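"""Seed fan-out helpers.

One root seed per run; every stochastic stage derives its own child seed by
stable hashing of (root, purpose-label), so adding a stage never perturbs the
streams of existing stages.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(root: int, label: str) -> int:
    """Derive a deterministic child seed from a root seed and a label."""
    h = zlib.crc32(label.encode("utf-8"))
    return int((int(root) * 2654435761 + h) % _MOD)


def rng_for(root: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(root, label))
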