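"""IUPAC degenerate nucleotide codes shared by the scanner, discovery, and simulator.

A degenerate code denotes a set of bases; ``N`` in a *pattern* means "any base",
but an ``N`` in a *sequence* is an unknown base and never satisfies any pattern
position (conservative matching).
"""

from __future__ import annotations

# code -> frozenset of concrete bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# frozenset of bases -> the unique code covering exactly that set
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

ALPHABET = frozenset(IUPAC_SETS)
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def validate_iupac(pattern: str) -> None:
    """Raise ``ValueError`` naming the first illegal position."""
    for i, c in enumerate(pattern):
        if c not in ALPHABET:
            raise ValueError(
                f"illegal IUPAC character {c!r} at position {i + 1} of {pattern!r}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain or degenerate nucleotide string.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from None


def code_for_bases(bases: frozenset[str]) -> str:
    """The single IUPAC code whose base set is exactly ``bases``."""
    return SETS_TO_CODE[frozenset(bases)]
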