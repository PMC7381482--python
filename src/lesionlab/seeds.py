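"""Deterministic, collision-resistant seed derivation.

All randomness in the package flows from a master seed through
:func:`derive_seed`; no stage reads global RNG state.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, stage: str, counter: int = 0) -> int:
    """Derive a per-stage seed below 2**31 from a master seed.

    Hash-based, so distinct (stage, counter) pairs give independent seeds
    and changing the master seed changes every derived seed.
    """
    key = f"{master_seed}:{stage}:{counter}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
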