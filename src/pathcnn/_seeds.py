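"""Deterministic seed derivation.

One user-facing seed fans out to named per-stage seeds (embedding
initialization, weight initialization, epoch shuffling, fold assignment,
corpus synthesis) so that each source of randomness can be reproduced and
debugged in isolation.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31


def derive_seed(seed: int, name: str) -> int:
    """Derive a stage-specific seed from a base seed and a stage name.

    The derivation is a SHA-256 hash of ``"{seed}:{name}"`` reduced
    modulo 2**31, so it is stable across processes and platforms.
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
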