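"""Counter-based random substreams.

Every stochastic stage derives its generator from one integer root seed plus a
stage label, so stages are statistically independent, reproducible, and
insensitive to the order in which other stages consume randomness.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _label_code(label: object) -> int:
    """Stable 31-bit code for a stream label (not salted like ``hash``)."""
    digest = hashlib.blake2s(str(label).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little") & 0x7FFFFFFF


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Philox generator for the (seed, labels...) substream."""
    key = tuple(_label_code(lab) for lab in labels)
    ss = np.random.SeedSequence(int(seed), spawn_key=key)
    return np.random.Generator(np.random.Philox(ss))
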