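"""Shared helper: random stop-free coding sequences for tests."""

from __future__ import annotations

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_sense_cds(rng, n_codons: int) -> str:
    return "".join(SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons))
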