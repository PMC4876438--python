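"""Deterministic seed derivation.

Every stochastic stage (null ensembles, permutation tests, cohort
simulation) draws its seed from the run's master seed plus a stable
string key, so results do not depend on subject ordering and reruns are
bit-identical.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *parts) -> int:
    """Map (master seed, key parts) to a seed in [0, 2**31).

    Uses SHA-256 of the textual key so the mapping is stable across
    platforms and Python hash randomization.
    """
    key = "|".join([str(int(master))] + [repr(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
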