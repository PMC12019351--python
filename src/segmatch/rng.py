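"""Deterministic random-stream derivation.

Every source of randomness in the package derives from one integer seed via
named substreams, so that scene ``i`` is reproducible independently of
generation order and two runs with equal seeds produce identical histories.
"""

from __future__ import annotations

import numpy as np

# Fixed stream identifiers. Never renumber: doing so silently changes every
# seeded artefact (datasets, batch orders, initial weights).
STREAM_SCENE = 1
STREAM_SPLIT = 2
STREAM_MODEL = 3
STREAM_BATCH = 4
STREAM_AUGMENT = 5
STREAM_NOISE = 6


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Return a generator for the substream identified by ``keys``.

    ``substream(seed, STREAM_SCENE, index)`` is independent of any other
    (seed, keys) combination and stable across processes.
    """
    return np.random.default_rng([int(seed), *map(int, keys)])
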