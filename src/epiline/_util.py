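"""Small shared helpers: sequence alphabet utilities and seed derivation."""

from __future__ import annotations

import hashlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a stage seed (< 2**31) from a global seed.

    Every stochastic stage of the pipeline seeds its own generator from
    (global seed, stage name) so that stages can be re-run in isolation and
    the whole run is reproducible from one integer.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
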