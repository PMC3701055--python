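"""Shared helpers: deterministic seed derivation and logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("grninfer")


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a child seed from a base seed and arbitrary string tokens.

    Hash-based so the result depends only on (seed, tokens), never on the
    order in which work items are scheduled — this is what makes per-target
    parallel decomposition reproducible for any worker count.  The result
    fits in a signed 32-bit integer, as required by scikit-learn's
    ``random_state``.
    """
    key = "|".join([str(int(seed)), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
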