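"""Synthetic genomes, planted motifs, and expression matrices with known truth.

Everything the pipeline consumes can be generated at desk scale: a multi-gene
contig from an order-1 Markov background (rice-like GC 0.43 by default) with
annotated gene models (promoter, 5'-UTR, two exons, one intron, downstream
flank) on alternating strands; motif words planted into chosen regions at
controlled carrier fraction, copy number, position bin, and orientation; an
M-value matrix in which motif-bearing responder genes are shifted up or down
in designated arrays on top of Gaussian noise; and TF expression rows
constructed to correlate with a gene set's z-score profile at an exact
population correlation.  A truth table records every placement and responder
so each pipeline stage can be checked against ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._iupac import IUPAC_SETS, reverse_complement, validate_iupac
from .expression import ExpressionMatrix
from .patterns import MotifPattern, find_occurrences
from .regions import GeneModel
from .tfassoc import ZProfile

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

# gene architecture (bp), transcription orientation
PROMOTER_LEN = 1200
UTR5_LEN = 150
EXON1_LEN = 300  # includes the 5'-UTR
INTRON_LEN = 200
EXON2_LEN = 250
DOWNSTREAM_LEN = 1100
SPACER_LEN = 100

GENE_LEN = EXON1_LEN + INTRON_LEN + EXON2_LEN
BLOCK_LEN = PROMOTER_LEN + GENE_LEN + DOWNSTREAM_LEN


@dataclass
class PlantingSpec:
    """What to plant: pattern, carrier fraction, copies, positions, orientation."""

    pattern: str
    fraction: float
    name: str = ""
    copies: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    # upstream-distance bins "lo-hi" -> probability; None = uniform over the region
    position_bins: Mapping[str, float] | None = None
    orientation: str = "forward"  # forward | reverse | both
    region_kind: str = "up1k"

    def __post_init__(self) -> None:
        validate_iupac(self.pattern.upper())
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if abs(sum(self.copies.values()) - 1.0) > 1e-9:
            raise ValueError("copies distribution must sum to 1")
        if self.position_bins is not None and abs(sum(self.position_bins.values()) - 1.0) > 1e-9:
            raise ValueError("position distribution must sum to 1")
        if self.orientation not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown orientation policy {self.orientation!r}")
        if not self.name:
            object.__setattr__(self, "name", self.pattern)


@dataclass
class EffectSpec:
    """How planted genes respond: arrays, direction, effect size, noise."""

    arrays: Sequence[str]
    direction: str = "induce"  # induce | suppress
    delta: float = 1.5
    responder_fraction: float = 0.5
    noise_sd: float = 0.5
    baseline_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.direction not in ("induce", "suppress"):
            raise ValueError(f"direction must be induce|suppress, got {self.direction!r}")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise/baseline sd must be > 0")


@dataclass
class Placement:
    """One planted occurrence (truth record)."""

    gene_id: str
    pattern_name: str
    region_kind: str
    position: int  # upstream distance for up1k/up3k, 1-based offset otherwise
    orientation: str
    word: str  # the concrete instantiated word


@dataclass
class TruthTable:
    """Ground truth: placements, responder sets, and TF target correlations."""

    placements: list[Placement] = field(default_factory=list)
    responders: dict[str, set[str]] = field(default_factory=dict)  # effect label -> genes
    effects: dict[str, EffectSpec] = field(default_factory=dict)
    tf_targets: dict[str, float] = field(default_factory=dict)  # tf id -> population r

    def carriers(self, pattern_name: str) -> set[str]:
        return {p.gene_id for p in self.placements if p.pattern_name == pattern_name}

    def copy_numbers(self, pattern_name: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.placements:
            if p.pattern_name == pattern_name:
                out[p.gene_id] = out.get(p.gene_id, 0) + 1
        return out

    def placements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": p.gene_id, "pattern": p.pattern_name,
                    "region": p.region_kind, "position": p.position,
                    "orientation": p.orientation, "word": p.word,
                }
                for p in self.placements
            ]
        )


@dataclass
class GeneLayout:
    """Where a gene's block sits on the contig (block coords are transcription
    orientation; for '-' genes local x maps to genomic offset + L - 1 - x)."""

    gene_id: str
    offset: int  # contig offset of the block
    strand: str
    block_len: int  # including the trailing spacer


@dataclass
class GenomeBundle:
    """A synthetic genome: contig(s), gene models, layouts, and truth."""

    contigs: dict[str, str]
    models: dict[str, GeneModel]
    layouts: dict[str, GeneLayout]
    truth: TruthTable = field(default_factory=TruthTable)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.contigs.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for gene_id, m in self.models.items():
                s, e = m.span
                feats = [("gene", s, e, gene_id, None), ("mRNA", s, e, f"{gene_id}.1", gene_id)]
                for i, (xs, xe) in enumerate(m.exons, 1):
                    feats.append(("exon", xs, xe, f"{gene_id}.1.exon{i}", f"{gene_id}.1"))
                for i, (xs, xe) in enumerate(m.utr5, 1):
                    feats.append(
                        ("five_prime_UTR", xs, xe, f"{gene_id}.1.utr5.{i}", f"{gene_id}.1")
                    )
                for i, (xs, xe) in enumerate(self._cds_intervals(m), 1):
                    feats.append(("CDS", xs, xe, f"{gene_id}.1.cds{i}", f"{gene_id}.1"))
                for ftype, xs, xe, fid, parent in feats:
                    attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
                    fh.write(
                        f"{m.chrom}\tcresig_sim\t{ftype}\t{xs + 1}\t{xe}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )

    @staticmethod
    def _cds_intervals(m: GeneModel) -> list[tuple[int, int]]:
        """CDS = exons minus the 5'-UTR (no 3'-UTR in the synthetic models)."""
        utr = set()
        for s, e in m.utr5:
            utr.update(range(s, e))
        out = []
        for s, e in m.exons:
            pos = [p for p in range(s, e) if p not in utr]
            if pos:
                out.append((pos[0], pos[-1] + 1))
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "truth": outdir / "truth_placements.tsv",
        }
        self.write_fasta(paths["fasta"])
        self.write_gff3(paths["gff3"])
        self.truth.placements_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _markov_matrix(gc: float, homopolymer_bias: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Order-1 transition matrix with a mild homopolymer bias at given GC."""
    marginal = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = np.tile(marginal, (4, 1))
    trans[np.arange(4), np.arange(4)] *= 1.0 + homopolymer_bias
    trans /= trans.sum(axis=1, keepdims=True)
    return marginal, trans


def _sample_markov_block(
    rng: np.random.Generator, n_rows: int, n_cols: int, marginal: np.ndarray,
    trans: np.ndarray, order: int,
) -> np.ndarray:
    """(n_rows, n_cols) base codes; each row an independent chain."""
    u = rng.random((n_rows, n_cols))
    out = np.empty((n_rows, n_cols), dtype=np.int8)
    cum0 = np.cumsum(marginal)
    out[:, 0] = np.searchsorted(cum0, u[:, 0])
    if order == 0:
        for j in range(1, n_cols):
            out[:, j] = np.searchsorted(cum0, u[:, j])
        return out
    cum = np.cumsum(trans, axis=1)
    for j in range(1, n_cols):
        prev = out[:, j - 1]
        rows = cum[prev]
        out[:, j] = (u[:, j][:, None] > rows).sum(axis=1)
    return np.clip(out, 0, 3)


def make_genome(
    n_genes: int = 2000,
    contig_len: int | None = None,
    promoter_len: int = PROMOTER_LEN,
    gc: float = 0.43,
    order: int = 1,
    seed: int = 0,
    contig_name: str = "chr1",
) -> GenomeBundle:
    """Generate a single-contig synthetic genome with ``n_genes`` gene models.

    Genes alternate strands; each has a 5'-UTR, two exons, and one intron, with
    ``promoter_len`` of upstream background and a 1.1-kb downstream flank.
    Background is an order-``order`` Markov chain at the given GC content.
    """
    if promoter_len < 1100:
        raise ValueError("promoter_len must be >= 1100 to host a full 1-kb upstream region")
    block = promoter_len + GENE_LEN + DOWNSTREAM_LEN
    total_block = block + SPACER_LEN
    required = n_genes * total_block
    if contig_len is None:
        contig_len = required
    elif contig_len < required:
        raise ValueError(
            f"contig_len {contig_len} too short for {n_genes} genes "
            f"({required} bp needed) — overcrowded layout"
        )
    rng = np.random.default_rng(seed)
    marginal, trans = _markov_matrix(gc)
    codes = _sample_markov_block(rng, n_genes, total_block, marginal, trans, order)

    models: dict[str, GeneModel] = {}
    layouts: dict[str, GeneLayout] = {}
    p = promoter_len
    for i in range(n_genes):
        gene_id = f"gene_{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        offset = i * total_block
        if strand == "-":
            codes[i, :] = 3 - codes[i, ::-1]  # reverse complement the block
        layouts[gene_id] = GeneLayout(gene_id, offset, strand, total_block)
        # local transcription-orientation intervals
        utr5_l = (p, p + UTR5_LEN)
        exon1_l = (p, p + EXON1_LEN)
        exon2_l = (p + EXON1_LEN + INTRON_LEN, p + GENE_LEN)
        if strand == "+":
            tss = offset + p
            tsc = offset + p + GENE_LEN - 1
            to_g = lambda a, b: (offset + a, offset + b)  # noqa: E731
        else:
            L = total_block
            tss = offset + L - 1 - p
            tsc = offset + L - (p + GENE_LEN)
            to_g = lambda a, b: (offset + L - b, offset + L - a)  # noqa: E731
        exons = sorted([to_g(*exon1_l), to_g(*exon2_l)])
        utr5 = [to_g(*utr5_l)]
        models[gene_id] = GeneModel(
            gene_id=gene_id, chrom=contig_name, strand=strand,
            tss=tss, tsc=tsc, exons=exons, utr5=utr5,
        )
    extra = contig_len - required
    if extra > 0:
        tail = _sample_markov_block(rng, 1, extra, marginal, trans, order)[0]
        flat = np.concatenate([codes.reshape(-1), tail])
    else:
        flat = codes.reshape(-1)
    contig = _BASE_ARR[flat.astype(np.intp)].tobytes().decode("ascii")
    return GenomeBundle(contigs={contig_name: contig}, models=models, layouts=layouts)


def _region_local_interval(layout: GeneLayout, promoter_len: int, kind: str) -> tuple[int, int]:
    """Local (transcription-orientation) half-open interval of a region kind."""
    p = promoter_len
    if kind == "up1k":
        return p - 1000, p
    if kind == "up3k":
        return max(0, p - 3000), p
    if kind == "utr5":
        return p, p + UTR5_LEN
    if kind == "intron":
        return p + EXON1_LEN, p + EXON1_LEN + INTRON_LEN
    if kind == "down1k":
        # plant only within the 1-kb window the pipeline extracts
        return p + GENE_LEN, p + GENE_LEN + min(DOWNSTREAM_LEN, 1000)
    raise ValueError(f"unknown region kind {kind!r}")


def _local_to_genomic(layout: GeneLayout, a: int, b: int) -> tuple[int, int]:
    if layout.strand == "+":
        return layout.offset + a, layout.offset + b
    L = layout.block_len
    return layout.offset + L - b, layout.offset + L - a


def _instantiate(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in pattern
    )


def _sample_distance(rng, spec: PlantingSpec, max_distance: int) -> int:
    """Upstream distance of the TSS-nearest base (1-based)."""
    if spec.position_bins is None:
        return int(rng.integers(1, max_distance + 1))
    labels = list(spec.position_bins)
    probs = np.array([spec.position_bins[b] for b in labels])
    label = labels[rng.choice(len(labels), p=probs / probs.sum())]
    lo, hi = (int(x) for x in label.split("-"))
    hi = min(hi, max_distance)
    if lo > hi:
        raise ValueError(f"position bin {label} does not fit in the region")
    return int(rng.integers(lo, hi + 1))


def plant_motifs(
    bundle: GenomeBundle,
    spec: PlantingSpec,
    seed: int = 0,
    promoter_len: int = PROMOTER_LEN,
    exclusive: bool = True,
    max_retries: int = 100,
) -> GenomeBundle:
    """Plant a motif into a fraction of genes; mutates and returns the bundle.

    Each selected gene receives its sampled number of non-overlapping copies,
    one concrete word per site drawn uniformly from the degenerate expansion.
    With ``exclusive=True`` (default) chance occurrences of the pattern in the
    same region of *any* gene, beyond the planted sites, are resampled away so
    the truth table is exact.
    """
    rng = np.random.default_rng(seed)
    contig_name = next(iter(bundle.contigs))
    arr = bytearray(bundle.contigs[contig_name], "ascii")
    w = len(spec.pattern)
    genes = sorted(bundle.layouts)
    n_sel = round(spec.fraction * len(genes))
    selected = [genes[i] for i in sorted(rng.choice(len(genes), size=n_sel, replace=False))]

    copy_labels = sorted(spec.copies)
    copy_probs = np.array([spec.copies[c] for c in copy_labels], dtype=float)
    copy_probs /= copy_probs.sum()

    planted_local: dict[str, list[tuple[int, int, str, str]]] = {}
    for gene_id in selected:
        layout = bundle.layouts[gene_id]
        lo, hi = _region_local_interval(layout, promoter_len, spec.region_kind)
        region_len = hi - lo
        n_copies = int(copy_labels[rng.choice(len(copy_labels), p=copy_probs)])
        used: list[tuple[int, int]] = []
        for _ in range(n_copies):
            for attempt in range(max_retries):
                if spec.region_kind in ("up1k", "up3k"):
                    max_d = region_len - w + 1
                    d = _sample_distance(rng, spec, max_d)
                    a = hi - d - w + 1  # local start so nearest-TSS base is at distance d
                    position = d
                else:
                    off = int(rng.integers(0, region_len - w + 1))
                    a = lo + off
                    position = off + 1
                if all(a + w <= s or a >= e for s, e in used):
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_copies} non-overlapping copies in "
                    f"{gene_id} {spec.region_kind}"
                )
            used.append((a, a + w))
            orientation = (
                spec.orientation
                if spec.orientation != "both"
                else ("forward" if rng.random() < 0.5 else "reverse")
            )
            word = _instantiate(rng, spec.pattern)
            oriented = word if orientation == "forward" else reverse_complement(word)
            gs, ge = _local_to_genomic(layout, a, a + w)
            insert = oriented if layout.strand == "+" else reverse_complement(oriented)
            arr[gs:ge] = insert.encode("ascii")
            planted_local.setdefault(gene_id, []).append((a, a + w, orientation, word))
            bundle.truth.placements.append(
                Placement(gene_id, spec.name, spec.region_kind, position, orientation, word)
            )

    if exclusive:
        _scrub_spurious(arr, bundle, spec, planted_local, promoter_len, rng)
    bundle.contigs[contig_name] = arr.decode("ascii")
    return bundle


def _scrub_spurious(arr, bundle, spec: PlantingSpec, planted_local, promoter_len, rng):
    """Resample chance occurrences of the pattern outside the truth table."""
    w = len(spec.pattern)
    rc = reverse_complement(spec.pattern)
    patterns = [spec.pattern] if spec.pattern == rc else [spec.pattern, rc]
    for gene_id, layout in bundle.layouts.items():
        lo, hi = _region_local_interval(layout, promoter_len, spec.region_kind)
        gs, ge = _local_to_genomic(layout, lo, hi)
        keep = planted_local.get(gene_id, [])
        # planted genomic intervals (bases never to resample)
        protected: set[int] = set()
        for a, b, _, _ in keep:
            pa, pb = _local_to_genomic(layout, a, b)
            protected.update(range(pa, pb))
        for _ in range(50):
            seg = arr[gs:ge].decode("ascii")
            dirty = False
            for pat in patterns:
                for off in find_occurrences(seg, pat):
                    span = range(gs + off, gs + off + w)
                    if all(p in protected for p in span):
                        continue
                    free = [p for p in span if p not in protected]
                    if not free:
                        continue
                    dirty = True
                    for p in free:
                        arr[p] = ord("ACGT"[rng.integers(4)])
            if not dirty:
                break


def simulate_expression(
    gene_ids: Sequence[str],
    effects: Mapping[str, tuple[Iterable[str], EffectSpec]],
    n_arrays: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    baseline_sd: float = 0.5,
    truth: TruthTable | None = None,
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Simulate the M-value meta-matrix with planted expression effects.

    ``effects`` maps an effect label to (carrier gene ids, EffectSpec); in the
    spec's responsive arrays a ``responder_fraction`` subset of carriers gets
    M ~ Normal(+/-delta, noise_sd) while every other cell is
    Normal(0, baseline_sd).  Returns the matrix and the responder sets (also
    recorded in ``truth`` when given).
    """
    rng = np.random.default_rng(seed)
    arrays = [f"array_{i + 1:02d}" for i in range(n_arrays)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    m = rng.normal(0.0, baseline_sd, size=(len(gene_ids), n_arrays))
    responders: dict[str, set[str]] = {}
    for label, (carriers, eff) in effects.items():
        # sort so responder sampling is independent of set iteration order
        carriers = sorted(g for g in carriers if g in gene_index)
        unknown_arrays = set(eff.arrays) - set(arrays)
        if unknown_arrays:
            raise ValueError(f"effect {label!r} targets unknown arrays {sorted(unknown_arrays)}")
        n_resp = round(eff.responder_fraction * len(carriers))
        chosen = rng.choice(len(carriers), size=n_resp, replace=False)
        resp = {carriers[i] for i in chosen}
        responders[label] = resp
        mu = eff.delta if eff.direction == "induce" else -eff.delta
        rows = [gene_index[g] for g in sorted(resp)]
        cols = [arrays.index(a) for a in eff.arrays]
        for c in cols:
            m[rows, c] = rng.normal(mu, eff.noise_sd, size=len(rows))
    if missing_rate > 0:
        mask = rng.random(m.shape) < missing_rate
        m[mask] = np.nan
    frame = pd.DataFrame(m, index=list(gene_ids), columns=arrays)
    matrix = ExpressionMatrix(frame)
    if truth is not None:
        truth.responders.update(responders)
        truth.effects.update({k: v for k, (_, v) in effects.items()})
    return matrix, responders


def simulate_tf_profiles(
    zprofile: ZProfile,
    target_r: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """TF expression rows with exact population correlation to a Z profile.

    Each TF row is ``r * z_standardized + sqrt(1 - r^2) * eps`` with iid
    standard-normal noise, so the population Pearson correlation with the Z
    profile equals the target exactly.  Arrays where Z is missing get plain
    noise.  Returns a TF x array DataFrame to append to the meta-matrix.
    """
    rng = np.random.default_rng(seed)
    z = zprofile.z.to_numpy(dtype=float)
    obs = ~np.isnan(z)
    if obs.sum() < 3 or np.nanstd(z) == 0:
        raise ValueError("degenerate Z profile: too few arrays or zero variance")
    zs = np.where(obs, (z - np.nanmean(z)) / np.nanstd(z), 0.0)
    rows = {}
    for tf, r in target_r.items():
        if not -1 < r < 1:
            raise ValueError(f"target r for {tf!r} must be in (-1, 1)")
        eps = rng.normal(size=len(z))
        rows[tf] = r * zs + math.sqrt(1.0 - r * r) * eps
    return pd.DataFrame(rows, index=zprofile.z.index).T


def append_tf_profiles(
    matrix: ExpressionMatrix,
    tf_rows: pd.DataFrame,
) -> ExpressionMatrix:
    """Meta-matrix with TF rows appended (TF ids must be new)."""
    clash = set(tf_rows.index) & set(matrix.data.index)
    if clash:
        raise ValueError(f"TF ids already present in the matrix: {sorted(clash)[:5]}")
    return ExpressionMatrix(pd.concat([matrix.data, tf_rows]))


TF_FAMILIES = ["bZIP", "WRKY", "ERF", "MYB", "NAC", "bHLH", "C2H2", "HD-ZIP"]


@dataclass
class DemoScenario:
    """The default end-to-end demo: genome, planted CREs, matrix, TFs, truth."""

    bundle: GenomeBundle
    matrix: ExpressionMatrix  # includes TF rows
    planting: dict[str, PlantingSpec]
    effects: dict[str, tuple[set[str], EffectSpec]]
    tf_table: dict[str, str]  # tf id -> family
    tf_targets: dict[str, tuple[str, float]]  # tf id -> (cre label, population r)

    @property
    def truth(self) -> TruthTable:
        return self.bundle.truth


def demo_scenario(
    seed: int = 0,
    n_genes: int = 2000,
    n_arrays: int = 24,
    n_strong_tfs: int = 20,
    n_decoy_tfs: int = 30,
    strong_r: float = 0.8,
) -> DemoScenario:
    """Build the default synthetic study: 2,000 genes, 24 arrays, two planted
    CREs (an ABRE-like CACGTGTC inducing arrays 1-2 and a GCC-box-like
    CGCCGCCG suppressing arrays 3-4), and 20 strongly correlated TFs plus
    decoys.

    The strong-TF target correlation is +/-0.8: at 24 arrays the sampling
    noise of r is large, and 0.8 keeps a truly strong TF reliably inside the
    strong band.
    """
    bundle = make_genome(n_genes=n_genes, seed=seed)
    cre1 = PlantingSpec(
        pattern="CACGTGTC", name="CRE1", fraction=0.15,
        copies={1: 0.7, 2: 0.3}, orientation="both",
    )
    cre2 = PlantingSpec(
        pattern="CGCCGCCG", name="CRE2", fraction=0.15,
        copies={1: 0.7, 2: 0.3}, orientation="both",
    )
    plant_motifs(bundle, cre1, seed=seed + 1)
    plant_motifs(bundle, cre2, seed=seed + 2)

    arrays = [f"array_{i + 1:02d}" for i in range(n_arrays)]
    effects = {
        "CRE1": (
            bundle.truth.carriers("CRE1"),
            EffectSpec(arrays=arrays[0:2], direction="induce"),
        ),
        "CRE2": (
            bundle.truth.carriers("CRE2"),
            EffectSpec(arrays=arrays[2:4], direction="suppress"),
        ),
    }
    matrix, _ = simulate_expression(
        sorted(bundle.models), effects, n_arrays, seed=seed + 3, truth=bundle.truth
    )

    # TF rows correlate with the carrier sets' Z profiles
    from .tfassoc import zscore_profile  # local import to avoid a cycle

    tf_table: dict[str, str] = {}
    tf_targets: dict[str, tuple[str, float]] = {}
    tf_rows = []
    half = n_strong_tfs // 2
    for j, cre_label in enumerate(["CRE1", "CRE2"]):
        zp = zscore_profile(sorted(bundle.truth.carriers(cre_label)), matrix, cre=cre_label)
        targets = {}
        for i in range(half):
            tf_id = f"TF_{j * half + i + 1:03d}"
            r = strong_r if i % 2 == 0 else -strong_r
            targets[tf_id] = r
            tf_targets[tf_id] = (cre_label, r)
            tf_table[tf_id] = TF_FAMILIES[(j * half + i) % len(TF_FAMILIES)]
        tf_rows.append(simulate_tf_profiles(zp, targets, seed=seed + 10 + j))
    decoy_rng = np.random.default_rng(seed + 20)
    decoys = pd.DataFrame(
        decoy_rng.normal(size=(n_decoy_tfs, n_arrays)),
        index=[f"TF_{n_strong_tfs + i + 1:03d}" for i in range(n_decoy_tfs)],
        columns=arrays,
    )
    for i, tf_id in enumerate(decoys.index):
        tf_table[tf_id] = TF_FAMILIES[i % len(TF_FAMILIES)]
        tf_targets[tf_id] = ("none", 0.0)
    full = append_tf_profiles(matrix, pd.concat(tf_rows + [decoys]))
    bundle.truth.tf_targets.update({tf: r for tf, (_, r) in tf_targets.items()})
    return DemoScenario(
        bundle=bundle, matrix=full, planting={"CRE1": cre1, "CRE2": cre2},
        effects=effects, tf_table=tf_table, tf_targets=tf_targets,
    )
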