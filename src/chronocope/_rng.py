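"""Deterministic counter-based random substreams.

Every stochastic draw in the synthetic cohort is made from a Generator seeded
by ``(cohort_seed, *labels)`` where the labels are stable strings such as the
individual id, the channel name and the session label.  Adding a fish or a
channel therefore never perturbs the draws made for any other fish, and the
same configuration always reproduces the same cohort byte for byte.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_entropy(label: str | int) -> int:
    if isinstance(label, int):
        return label & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``.

    Parameters
    ----------
    seed
        The cohort-level seed.
    labels
        Stable identifiers (individual id, channel, session, ...) hashed with
        CRC32 into the seed sequence entropy.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_label_entropy(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
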