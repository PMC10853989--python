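"""Deterministic seed derivation.

Every source of randomness in the pipeline (cohort simulation, fold
assignment, autoencoder initialisation and shuffling, classifier
initialisation, upsampling) draws its seed from one master seed through a
splitmix64-style hash keyed by a path of string/int tags.  This makes each
stage independently reproducible: re-running any stage with the same master
seed and tags yields the same stream without consuming state from other
stages.
"""
from __future__ import annotations

_MASK64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


def _mix(z: int) -> int:
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def derive_seed(master: int, *tags: str | int) -> int:
    """Hash ``master`` and a path of tags into a seed below 2**31.

    Parameters
    ----------
    master
        The run's master seed.
    tags
        Strings and/or integers naming the consumer, e.g.
        ``derive_seed(s, "repeat", 2, "fold", 0, "mask", "whole")``.
    """
    state = _mix((int(master) + _GOLDEN) & _MASK64)
    for tag in tags:
        if isinstance(tag, str):
            for byte in tag.encode("utf-8"):
                state = _mix((state + byte + _GOLDEN) & _MASK64)
        else:
            state = _mix((state + (int(tag) & _MASK64) + _GOLDEN) & _MASK64)
    return state % (1 << 31)
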