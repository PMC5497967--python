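"""Deterministic per-stage seed derivation.

Every random stage of the pipeline derives its own seed from the global
seed plus a tuple of string/int tokens (stage name, subject id, window
index ...), so any stage can be regenerated in isolation and two runs
with the same global seed are bit-identical.
"""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int, *tokens: object) -> int:
    """Stable 31-bit seed from a global seed and context tokens.

    Uses SHA-256 of the repr of the token tuple, so the mapping is
    identical across platforms and Python processes (no reliance on
    ``hash()``).
    """
    payload = repr((int(global_seed),) + tuple(tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
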