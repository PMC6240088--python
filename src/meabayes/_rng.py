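"""Seed handling: one global seed expanded into independent per-purpose streams.

Each stage of the pipeline (source sampling, stimulus sampling, site
assignment, agent initialisation, recording noise, surrogate permutation)
draws from its own substream so that changing the amount of randomness one
stage consumes never shifts the draws of another.
"""

from __future__ import annotations

import numpy as np

_PURPOSES = {
    "sources": 11,
    "stimuli": 23,
    "sites": 37,
    "agent": 41,
    "recording": 53,
    "surrogate": 67,
    "generic": 71,
}


def substream(seed: int, purpose: str = "generic") -> np.random.Generator:
    """Return an independent generator for *purpose* derived from *seed*."""
    if purpose not in _PURPOSES:
        raise ValueError(f"unknown RNG purpose {purpose!r}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _PURPOSES[purpose]])
    )
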