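"""Deterministic seed substreams.

Every stochastic stage derives its randomness from a single master seed
through named substreams, so that a full pipeline run (simulation,
selection repetitions, cross-validation splits, forest ensembles) is
reproducible end to end and individual stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

# integer seeds handed to third-party learners stay below 2**31
_SEED_MOD = 2**31 - 1


def _spawn_key(labels: tuple) -> tuple[int, ...]:
    key = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            key.append(int(lab))
        else:
            key.append(zlib.crc32(str(lab).encode("utf-8")))
    return tuple(key)


def substream(seed: int, *labels) -> np.random.Generator:
    """A ``numpy`` Generator for the substream named by ``labels``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_spawn_key(labels))
    return np.random.default_rng(ss)


def substream_seed(seed: int, *labels) -> int:
    """A plain integer seed (< 2**31) for the named substream.

    Used where a library takes ``random_state`` as an int.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=_spawn_key(labels))
    return int(ss.generate_state(1)[0] % _SEED_MOD)
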