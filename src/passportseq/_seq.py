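"""Small sequence helpers used throughout the package."""

from .errors import InvalidBase

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, what: str = "sequence") -> str:
    """Uppercase *seq* and verify it is plain ACGT DNA.

    Soft-masked (lowercase) bases are accepted and uppercased; ambiguity
    codes (N, R, ...) raise :class:`InvalidBase` because a synthesized
    oligo needs a concrete sequence.
    """
    up = seq.upper()
    bad = set(up) - DNA_BASES
    if bad:
        raise InvalidBase(
            f"{what} contains non-ACGT character(s) {sorted(bad)}: {seq!r}"
        )
    return up


def rna_to_dna(seq: str) -> str:
    """Uppercase an RNA (or DNA) string and rewrite U as T."""
    return seq.upper().replace("U", "T")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in *seq*."""
    best = run = 0
    prev = None
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best
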