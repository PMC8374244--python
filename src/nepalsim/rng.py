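"""Seeded randomness.

One master seed spawns named, mutually independent substreams so that a
change to one sub-model's draws cannot perturb another's.  Stream names are
fixed: a typo raises rather than silently minting a new stream.
"""

from __future__ import annotations

import numpy as np

STREAM_NAMES = (
    "synthesis",
    "demography",
    "yields",
    "labour",
    "livestock",
    "scenario",
    "finance",
)


class RngStreams:
    """Named independent generators derived from one master seed."""

    def __init__(self, seed: int) -> None:
        self.seed = int(seed)
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(STREAM_NAMES))
        self._streams = {
            name: np.random.default_rng(child)
            for name, child in zip(STREAM_NAMES, children)
        }

    def __getitem__(self, name: str) -> np.random.Generator:
        try:
            return self._streams[name]
        except KeyError:
            raise KeyError(f"unknown RNG stream {name!r}; valid: {STREAM_NAMES}") from None

    def __getattr__(self, name: str) -> np.random.Generator:
        if name in STREAM_NAMES:
            return self._streams[name]
        raise AttributeError(name)
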