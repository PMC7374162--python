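"""Named random substreams.

All randomness in the package flows from one master seed.  Each consumer
(simulation stage, split plan, internal CV, ...) derives its own independent
generator from the master seed plus a short label, so stages are reproducible
in isolation and insensitive to each other's draw counts.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, label: str) -> int:
    """Derive a deterministic 31-bit child seed from (seed, label)."""
    mix = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(mix.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, label: str) -> np.random.Generator:
    """A Generator seeded from the master seed and a stream label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )
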