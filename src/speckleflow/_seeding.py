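"""Stable seed derivation so every video/stage gets an independent stream."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *parts) -> int:
    """Derive a sub-seed below 2**31 from a master seed and string-able parts.

    Uses SHA-256 so the mapping is stable across Python processes and
    platforms (unlike the builtin ``hash``), making generation order
    irrelevant for reproducibility.
    """
    key = ":".join([str(int(master_seed)), *map(str, parts)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
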