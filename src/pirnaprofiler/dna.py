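"""Tiny nucleotide-string helpers shared across modules."""

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_nucleotides(seq: str, allow_n: bool = False, what: str = "sequence") -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)!r}")
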