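"""Deterministic child-seed derivation from one master seed.

Every stochastic stage of the pipeline draws its seed from the master seed
plus a stable textual scope (stage name, subject id, condition, run index),
so reruns with the same configuration reproduce every artifact while
distinct stages never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *scope) -> int:
    """A 31-bit seed unique to (master, scope...)."""
    entropy = [int(master) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(item).encode()) for item in scope)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
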