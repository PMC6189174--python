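"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def nearest_rank_quantile(values, q: float) -> float:
    """Nearest-rank (inverse empirical CDF) quantile.

    Returns the ``ceil(q * n)``-th smallest value (1-based), the classic
    nearest-rank definition. Deterministic and integer-friendly; used for every
    centile/decile/quartile in the package so that rank conventions agree
    across stages.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("quantile of empty collection")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    rank = int(np.ceil(q * n))
    rank = min(max(rank, 1), n)
    return float(arr[rank - 1])


def spawn_seeds(master_seed: int, n: int, stream: str = "") -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed.

    A named stream decouples the substreams used by different operations so
    that e.g. adding control wells does not shift the counts drawn for cells.
    """
    entropy = [int(master_seed)] + [ord(c) for c in stream]
    ss = np.random.SeedSequence(entropy)
    state = ss.generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]


def rng_for(master_seed: int, stream: str) -> np.random.Generator:
    """Generator for a named substream of a master seed."""
    return np.random.default_rng(spawn_seeds(master_seed, 1, stream)[0])
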