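"""Shared numerical helpers: RNG plumbing and the Fisher transform."""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "spawn_seeds", "fisher_z"]

#: |r| is clipped below 1 by this margin before arctanh so perfect
#: correlations stay finite.
R_CLIP = 1.0 - 1e-12


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, SeedSequence, Generator or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed.

    Used by the pipeline so that every stochastic stage gets its own
    reproducible stream while the user supplies a single integer.
    """
    state = np.random.SeedSequence(seed).generate_state(n, np.uint64)
    return [int(s % (2**31)) for s in state]


def fisher_z(r):
    """Fisher z-transform with perfect correlations clipped at |r| = 1 - 1e-12."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
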