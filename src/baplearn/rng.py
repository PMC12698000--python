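"""Seeded random-number stream management.

A single experiment seed fans out deterministically into named sub-streams
(input generation, weight initialization, transmission failure, jitter,
network wiring, ...) so that toggling one stochastic feature never shifts
the draws consumed by another.
"""

from __future__ import annotations

import numpy as np

#: Registry of named sub-streams. Each name maps to a fixed spawn key so the
#: mapping seed -> stream is stable across releases.
STREAMS = {
    "input": 0,
    "weights": 1,
    "failure": 2,
    "jitter": 3,
    "network": 4,
    "noise": 5,
    "protocol": 6,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named PCG64 sub-stream derived from ``seed``.

    Parameters
    ----------
    seed
        Global experiment seed (non-negative integer).
    name
        One of :data:`STREAMS`.
    """
    if name not in STREAMS:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(seed, spawn_key=(STREAMS[name],))
    return np.random.Generator(np.random.PCG64(ss))


def substream(seed: int, name: str, index: int) -> np.random.Generator:
    """A per-trial child of the named stream (e.g. one per presentation)."""
    if name not in STREAMS:
        raise KeyError(f"unknown RNG stream {name!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(seed, spawn_key=(STREAMS[name], index))
    return np.random.Generator(np.random.PCG64(ss))
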