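"""Degenerate-pattern scanning of promoter/gene-flank region sets.

Implements exact IUPAC set matching (every occurrence, overlapping occurrences
included) on both strands, records occurrence position, orientation, and per-gene
copy number, and stratifies carrier genes by upstream position bin, orientation,
or copy number for position/orientation/copy-number significance analyses.

Conventions
-----------
* Region sequences are written 5'->3' in the gene's reading orientation.
* For upstream kinds (``up1k``/``up3k``) occurrence position is reported as the
  *upstream distance*: the 1-based distance from the TSS to the occurrence base
  nearest the TSS (so a motif ending at the last base of ``up1k`` has distance 1).
  For other kinds the 1-based in-region start offset is reported.
* Palindromic patterns (equal to their own reverse complement as degenerate
  sets) are scanned on the forward strand only — a palindrome's reverse-strand
  occurrences are the same sites, and double counting would inflate copy number.
* An ``N`` in the sequence never matches any pattern position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from ._iupac import IUPAC_SETS, reverse_complement, validate_iupac

UPSTREAM_KINDS = frozenset({"up1k", "up3k"})

MIN_PATTERN_LEN = 4
MAX_PATTERN_LEN = 25

POSITION_BIN_WIDTH = 200
COPY_NUMBER_CAP = 4  # counts >= 4 pooled into one stratum


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC degenerate pattern, 4-25 nt."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac", self.iupac.upper())
        validate_iupac(self.iupac)
        if not MIN_PATTERN_LEN <= len(self.iupac) <= MAX_PATTERN_LEN:
            raise ValueError(
                f"pattern {self.name!r} length {len(self.iupac)} outside "
                f"[{MIN_PATTERN_LEN}, {MAX_PATTERN_LEN}]"
            )

    @property
    def width(self) -> int:
        return len(self.iupac)

    @property
    def is_palindromic(self) -> bool:
        """True when the pattern equals its reverse complement as a degenerate set."""
        return self.iupac == reverse_complement(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(self.name, reverse_complement(self.iupac))


def compile_pattern(iupac: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern to a regex reporting all (overlapping) matches.

    The regex recognises exactly the set product of each position's base set;
    a lookahead makes ``finditer`` enumerate overlapping occurrences.
    """
    validate_iupac(iupac.upper())
    body = "".join(
        c if len(IUPAC_SETS[c]) == 1 else "[" + "".join(sorted(IUPAC_SETS[c])) + "]"
        for c in iupac.upper()
    )
    return re.compile(f"(?=({body}))")


def find_occurrences(sequence: str, iupac: str) -> list[int]:
    """0-based start offsets of every (overlapping) occurrence on the given strand."""
    rx = compile_pattern(iupac)
    return [m.start() for m in rx.finditer(sequence.upper())]


@dataclass(frozen=True)
class MotifHit:
    """One occurrence: position (upstream distance or 1-based offset) + orientation."""

    position: int
    orientation: str  # "forward" | "reverse"


@dataclass
class MotifHitTable:
    """All occurrences of one pattern across one region set."""

    pattern: MotifPattern
    region_kind: str
    hits: dict[str, list[MotifHit]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.hits)

    def copy_number(self, gene_id: str) -> int:
        return len(self.hits[gene_id])

    def carrier_genes(self) -> set[str]:
        """Genes with at least one occurrence."""
        return {g for g, h in self.hits.items() if h}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tregion\tpattern\tdistance\torientation\n")
            for gene in sorted(self.hits):
                for hit in sorted(self.hits[gene], key=lambda h: (h.position, h.orientation)):
                    fh.write(
                        f"{gene}\t{self.region_kind}\t{self.pattern.name}\t"
                        f"{hit.position}\t{hit.orientation}\n"
                    )


def _positions_to_hits(
    starts: list[int], seq_len: int, width: int, region_kind: str, orientation: str
) -> list[MotifHit]:
    hits = []
    for s in starts:
        if region_kind in UPSTREAM_KINDS:
            # base nearest the TSS is the occurrence's last base (region ends at TSS-1)
            position = seq_len - (s + width - 1)
        else:
            position = s + 1
        hits.append(MotifHit(position, orientation))
    return hits


def scan_region_set(regions, pattern: MotifPattern, strands: str = "both") -> MotifHitTable:
    """Scan every sequence of a region set for a degenerate pattern.

    Parameters
    ----------
    regions : RegionSet
        Sequences written 5'->3' in reading orientation (see ``cresig.regions``).
    pattern : MotifPattern
    strands : {"both", "forward_only"}
        ``both`` scans the forward strand with the pattern and the reverse
        strand via the reverse-complemented pattern; palindromic patterns are
        scanned forward only regardless.
    """
    if strands not in ("both", "forward_only"):
        raise ValueError(f"strands must be 'both' or 'forward_only', got {strands!r}")
    if not regions.sequences:
        raise ValueError("region set is empty")
    table = MotifHitTable(pattern=pattern, region_kind=regions.kind)
    w = pattern.width
    scan_reverse = strands == "both" and not pattern.is_palindromic
    rc_iupac = reverse_complement(pattern.iupac)
    any_long_enough = False
    for gene_id, seq in regions.sequences.items():
        if len(seq) >= w:
            any_long_enough = True
        fwd = find_occurrences(seq, pattern.iupac)
        hits = _positions_to_hits(fwd, len(seq), w, regions.kind, "forward")
        if scan_reverse:
            rev = find_occurrences(seq, rc_iupac)
            hits += _positions_to_hits(rev, len(seq), w, regions.kind, "reverse")
        if hits:
            table.hits[gene_id] = sorted(hits, key=lambda h: (h.position, h.orientation))
    if not any_long_enough:
        warnings.warn(
            f"pattern {pattern.name!r} ({w} nt) is longer than every sequence "
            f"in region set {regions.kind!r}; hit table is empty",
            stacklevel=2,
        )
    return table


def position_bin_label(distance: int, bin_width: int = POSITION_BIN_WIDTH) -> str:
    lo = ((distance - 1) // bin_width) * bin_width + 1
    return f"{lo}-{lo + bin_width - 1}"


def stratify_hits(table: MotifHitTable, mode: str) -> dict[str, set[str]]:
    """Split carrier genes into analysis strata.

    ``position``: 200-bp upstream-distance bins (1-200, 201-400, ...); a gene
    joins every bin in which it has an occurrence.  Upstream region kinds only.
    ``orientation``: genes with >=1 forward hit vs genes with >=1 reverse hit
    (a gene can appear in both strata).
    ``copy_number``: exact counts "1", "2", "3", and ">=4".
    """
    if mode == "position":
        if table.region_kind not in UPSTREAM_KINDS:
            raise ValueError(
                f"position stratification applies only to upstream regions, "
                f"not {table.region_kind!r}"
            )
        strata: dict[str, set[str]] = {}
        for gene, hits in table.hits.items():
            for hit in hits:
                strata.setdefault(position_bin_label(hit.position), set()).add(gene)
        return strata
    if mode == "orientation":
        strata = {"forward": set(), "reverse": set()}
        for gene, hits in table.hits.items():
            for hit in hits:
                strata[hit.orientation].add(gene)
        return {k: v for k, v in strata.items() if v}
    if mode == "copy_number":
        strata = {}
        for gene, hits in table.hits.items():
            n = len(hits)
            label = str(n) if n < COPY_NUMBER_CAP else f">={COPY_NUMBER_CAP}"
            strata.setdefault(label, set()).add(gene)
        return strata
    raise ValueError(f"unknown stratification mode {mode!r}")


def load_catalog(path: str | Path) -> list[MotifPattern]:
    """Read a pattern catalog TSV: ``name<TAB>iupac[<TAB>source]``."""
    patterns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name" and lineno == 1:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>iupac")
            patterns.append(MotifPattern(parts[0], parts[1]))
    if not patterns:
        raise ValueError(f"pattern catalog {path} is empty")
    return patterns
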