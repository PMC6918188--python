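"""Strand-aware extraction of the five analysis regions around each gene.

For every gene the analysis considers 1-kb and 3-kb upstream sequence from the
transcription start site (TSS), the 5'-UTR, the introns, and 1-kb downstream
of the translational stop codon (TSC, 3'-UTR included).  All extracted
sequences are written 5'->3' in the gene's reading orientation, so downstream
scanning code never needs to know the strand.

Coordinates are 0-based half-open internally; GFF3 input/output is 1-based
inclusive per the standard.  Introns are concatenated with a run of 30 ``N``s
— longer than the 25-nt maximum pattern width — so no pattern can bridge two
introns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

REGION_KINDS = ("up1k", "up3k", "utr5", "intron", "down1k")
DEFAULT_LENGTHS = {"up1k": 1000, "up3k": 3000, "down1k": 1000}

# region kind -> two-letter code used in CRE names (OS_<AA>_<NNN>)
REGION_CODES = {"up1k": "1K", "up3k": "3K", "utr5": "5U", "intron": "UT", "down1k": "1D"}

INTRON_SEPARATOR = "N" * 30


@dataclass
class GeneModel:
    """One gene reduced to a single (longest-span) transcript.

    ``tss``/``tsc`` are 0-based positions of the transcription start base and
    the last base of the stop codon; ``exons``/``utr5`` are 0-based half-open
    intervals sorted by genomic coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tsc: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic-order complement of the exons within the transcript span."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


def load_genome(path: str | Path) -> dict[str, str]:
    """Multi-contig FASTA -> {contig: uppercase sequence}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences found in FASTA {path}")
    return genome


def _intervals(features) -> list[tuple[int, int]]:
    # gffutils keeps 1-based inclusive coords; convert to 0-based half-open
    return sorted((f.start - 1, f.end) for f in features)


def parse_annotation(gff3: str | Path) -> dict[str, GeneModel]:
    """Parse a GFF3 file into one ``GeneModel`` per gene.

    When a gene has several mRNAs the one with the longest genomic span is
    kept.  The TSC is the CDS boundary nearest the transcript 3' end when CDS
    features are present, else the transcript end.  Genes without exons are
    skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            candidates = [gene]
        else:
            candidates = sorted(mrnas, key=lambda m: (m.end - m.start, m.id), reverse=True)
        mrna = candidates[0]
        exons = _intervals(db.children(mrna, featuretype="exon"))
        if not exons:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        utr5 = _intervals(db.children(mrna, featuretype="five_prime_UTR"))
        cds = _intervals(db.children(mrna, featuretype="CDS"))
        strand = gene.strand
        if strand not in "+-":
            logger.warning("gene %s has no strand; skipped", gene.id)
            continue
        start0, end0 = mrna.start - 1, mrna.end
        if strand == "+":
            tss = start0
            tsc = (cds[-1][1] - 1) if cds else end0 - 1
        else:
            tss = end0 - 1
            tsc = cds[0][0] if cds else start0
        models[gene.id] = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=strand,
            tss=tss, tsc=tsc, exons=exons, utr5=utr5,
        )
    return models


@dataclass
class RegionSet:
    """Extracted sequences of one region kind, 5'->3' in reading orientation."""

    kind: str
    sequences: dict[str, str] = field(default_factory=dict)
    # per gene: list of genomic intervals (chrom, start0, end0, strand)
    intervals: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, seq in self.sequences.items():
                spans = ",".join(
                    f"{c}:{s + 1}-{e}({st})" for c, s, e, st in self.intervals.get(gene, [])
                )
                fh.write(f">{gene}|{self.kind}|{spans}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def subset(self, gene_ids) -> "RegionSet":
        keep = set(gene_ids)
        return RegionSet(
            self.kind,
            {g: s for g, s in self.sequences.items() if g in keep},
            {g: v for g, v in self.intervals.items() if g in keep},
        )


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else str(Seq(seq).reverse_complement())


def _flank_interval(model: GeneModel, kind: str, length: int, contig_len: int):
    """Genomic 0-based half-open interval of an upstream/downstream flank."""
    if kind in ("up1k", "up3k"):
        anchor = model.tss
        before = model.strand == "+"  # flank lies 5' of the anchor base
    else:  # down1k: starts at the base after the stop codon
        anchor = model.tsc
        before = model.strand == "-"
    if before:
        start, end = anchor - length, anchor
    else:
        start, end = anchor + 1, anchor + 1 + length
    return max(0, start), min(contig_len, end)


def extract_region(
    genome: dict[str, str],
    model: GeneModel,
    kind: str,
    length: int | None = None,
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Extract one region of one gene: (sequence 5'->3', genomic intervals).

    Flank regions are truncated at contig edges (a zero-length result is kept
    with a warning); UTR and intron regions come from the gene model's
    intervals, introns joined with the 30-N separator.
    """
    if kind not in REGION_KINDS:
        raise ValueError(f"unknown region kind {kind!r}")
    if model.chrom not in genome:
        raise KeyError(f"gene {model.gene_id}: unknown contig {model.chrom!r}")
    contig = genome[model.chrom]
    if model.span[1] > len(contig):
        raise ValueError(
            f"gene {model.gene_id} extends past the end of contig {model.chrom}"
        )

    if kind in ("up1k", "up3k", "down1k"):
        length = length if length is not None else DEFAULT_LENGTHS[kind]
        start, end = _flank_interval(model, kind, length, len(contig))
        if end <= start:
            warnings.warn(
                f"gene {model.gene_id}: {kind} region is empty at the contig edge",
                stacklevel=2,
            )
            return "", []
        return _oriented(contig[start:end], model.strand), [(model.chrom, start, end, model.strand)]

    if kind == "utr5":
        ivs = model.utr5
        sep = ""
    else:  # intron
        ivs = model.introns
        sep = INTRON_SEPARATOR
    pieces = [_oriented(contig[s:e], model.strand) for s, e in ivs]
    if model.strand == "-":
        pieces = pieces[::-1]
        ivs = ivs[::-1]
    seq = sep.join(pieces)
    return seq, [(model.chrom, s, e, model.strand) for s, e in ivs]


def extract_region_set(
    genome: dict[str, str],
    models: dict[str, GeneModel],
    kind: str,
    length: int | None = None,
) -> RegionSet:
    """Extract one region kind for every gene model."""
    rs = RegionSet(kind=kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-gene edge warnings handled in bulk
        for gene_id, model in models.items():
            seq, ivs = extract_region(genome, model, kind, length)
            rs.sequences[gene_id] = seq
            rs.intervals[gene_id] = ivs
    return rs
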