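"""Named deterministic random substreams.

A single top-level seed is expanded into independent per-purpose streams via
``numpy.random.SeedSequence`` spawn keys derived from stable string labels,
so adding a consumer never shifts the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of string labels."""
    key = tuple(_label_key(lab) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
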