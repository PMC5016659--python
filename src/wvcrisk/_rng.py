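"""Named random substreams.

All stochastic operations in the package draw from independent,
reproducible substreams derived from a single user seed plus a short
string key.  This keeps the draws of one stage (e.g. road-network
generation) stable when another stage's sample size changes.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: str) -> int:
    digest = hashlib.blake2s(key.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def substream(seed: int, key: str) -> np.random.Generator:
    """Return a Generator for the substream named *key* under *seed*.

    The same (seed, key) pair always yields an identical stream;
    distinct keys yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), _key_to_int(key)]))
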