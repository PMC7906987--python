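"""Seed plumbing.

One root integer seed governs every stochastic step.  Each stage draws from
its own derived stream (a ``SeedSequence`` keyed by a fixed stage code plus
optional sub-keys such as a dataset id), so adding or reordering stages never
perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

# Fixed registry: appending new stages gets a new code; existing codes never change.
_STAGE_CODES = {
    "simulate_meta": 101,
    "simulate_paired": 102,
    "simulate_baseline": 103,
    "sam_permutations": 201,
    "evaluation": 301,
}


def _as_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF
    return int(key) & 0x7FFFFFFF


def stage_rng(seed: int, stage: str, *subkeys) -> np.random.Generator:
    """Return the dedicated random generator for one pipeline stage.

    Parameters
    ----------
    seed : root seed from the analysis or generator config.
    stage : registered stage name.
    subkeys : extra identifiers (dataset ids, replicate indices); strings are
        hashed with CRC-32 so the derivation is stable across runs.
    """
    if stage not in _STAGE_CODES:
        raise KeyError(f"unregistered rng stage: {stage!r}")
    entropy = [int(seed) & 0x7FFFFFFF, _STAGE_CODES[stage]] + [_as_int(k) for k in subkeys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
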