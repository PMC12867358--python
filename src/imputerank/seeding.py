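"""Stable seed derivation.

Child seeds are derived by hashing the master seed together with string
tags (method name, iteration index, repeat index ...) through SHA-256, so
randomness is reproducible and independent of work partitioning: serial and
parallel executions consume identical random streams.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(master: int, *parts) -> int:
    """Deterministic 31-bit child seed from a master seed and context tags."""
    key = "|".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)
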