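"""Named, independent random substreams derived from one master seed.

Every stochastic component of the pipeline (landscape layers, movement
tracks, available-point/step sampling, experiment cells) draws from its own
substream keyed by a human-readable label path, so any single component is
reproducible in isolation without replaying everything upstream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key(labels: tuple) -> tuple[int, ...]:
    # crc32 gives a stable 32-bit integer per label across platforms/sessions
    return tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)


def substream(master_seed: int, *labels) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``.

    Distinct label paths yield statistically independent streams
    (numpy SeedSequence spawn-key mechanism).
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key(labels))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *labels) -> int:
    """A single integer seed (< 2**31) for components that need a plain seed,
    e.g. the compiled movement kernel."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key(labels))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
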