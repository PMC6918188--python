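"""The expression meta-matrix: M-values, regulation calls, and co-expression seeds.

The meta-matrix is a genes x arrays grid of M-values (log2 expression ratios)
pooled from many microarray comparisons.  Each array's genes are called
*induced* (M >= log2(cutoff)), *suppressed* (M <= -log2(cutoff)) or *neutral*,
with a default two-fold cutoff and optional per-array overrides (e.g. 1.5-fold
for low-dynamic-range arrays).  Genome-wide call proportions per array are the
background expectation for every enrichment test, and a seeded k-means on
M-value rows provides co-expressed gene sets to seed forward motif searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NA_TOKENS = {"", "NA", "nan", "NaN", "NAN"}

INDUCED, SUPPRESSED, NEUTRAL = "I", "S", "N"


class ExpressionMatrix:
    """Genes x arrays matrix of M-values; missing cells are NaN.

    Thin validated wrapper around a float ``pandas.DataFrame`` (index: gene
    ids, columns: array ids).
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 gene and 1 array")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate array ids: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            raise ValueError("expression matrix contains non-finite (inf) values")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return load_expression_matrix(path)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])


def load_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV meta-matrix: header ``gene_id<TAB>array1...``; NA tokens
    accepted: empty, ``NA``, ``nan``.  Malformed numeric cells and duplicate
    ids raise with the offending row/column named."""
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"expression matrix file {path} is empty") from None
    if raw.shape[1] < 1:
        raise ValueError(f"expression matrix file {path} has no array columns")
    data = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_na = cells.isin(NA_TOKENS)
        parsed = pd.to_numeric(cells.where(~is_na), errors="coerce")
        bad = (~is_na) & parsed.isna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"malformed numeric cell at gene {row!r}, array {col!r} "
                f"(value {raw.loc[row, col]!r})"
            )
        data[col] = parsed
    return ExpressionMatrix(data)


class RegulationCalls:
    """Per-gene, per-array regulation state: I / S / N, NaN when M missing."""

    def __init__(self, calls: pd.DataFrame, fold_cutoffs: pd.Series):
        self.calls = calls
        self.fold_cutoffs = fold_cutoffs

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.calls.columns)

    def state_counts(self, array_id: str) -> dict[str, int]:
        col = self.calls[array_id]
        return {s: int((col == s).sum()) for s in (INDUCED, SUPPRESSED, NEUTRAL)}

    def to_tsv(self, path: str | Path) -> None:
        self.calls.fillna("NA").to_csv(path, sep="\t", index_label="gene_id")


def call_regulation(
    matrix: ExpressionMatrix,
    default_cutoff: float = 2.0,
    per_array_cutoffs: Mapping[str, float] | None = None,
) -> RegulationCalls:
    """Call two-fold (or per-array override) induced/suppressed/neutral states.

    Thresholds are boundary-inclusive: induced iff M >= log2(cutoff),
    suppressed iff M <= -log2(cutoff).
    """
    cutoffs = pd.Series(default_cutoff, index=matrix.data.columns, dtype=float)
    if per_array_cutoffs:
        for arr, fold in per_array_cutoffs.items():
            if arr not in cutoffs.index:
                raise KeyError(f"cutoff override for unknown array {arr!r}")
            cutoffs[arr] = fold
    if (cutoffs <= 1).any():
        bad = cutoffs[cutoffs <= 1].index.tolist()
        raise ValueError(f"fold cutoffs must be > 1; offending arrays: {bad}")

    thresh = np.log2(cutoffs.to_numpy())
    m = matrix.data.to_numpy()
    calls = np.full(m.shape, NEUTRAL, dtype=object)
    calls[m >= thresh] = INDUCED
    calls[m <= -thresh] = SUPPRESSED
    calls[np.isnan(m)] = np.nan
    frame = pd.DataFrame(calls, index=matrix.data.index, columns=matrix.data.columns)
    return RegulationCalls(frame, cutoffs)


@dataclass(frozen=True)
class BackgroundRates:
    """Genome-wide regulation proportions for one array (missing calls excluded)."""

    array_id: str
    n_called: int
    p_induced: float
    p_suppressed: float
    p_neutral: float

    def p_target(self, mode: str) -> float:
        if mode == "induced":
            return self.p_induced
        if mode == "suppressed":
            return self.p_suppressed
        if mode == "combined":
            return self.p_induced + self.p_suppressed
        raise ValueError(f"unknown mode {mode!r}")


def array_background(calls: RegulationCalls, array_id: str) -> BackgroundRates:
    """Proportions of I/S/N over the array's non-missing calls."""
    if array_id not in calls.calls.columns:
        raise KeyError(f"unknown array {array_id!r}")
    counts = calls.state_counts(array_id)
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"array {array_id!r} has zero non-missing calls")
    return BackgroundRates(
        array_id=array_id,
        n_called=n,
        p_induced=counts[INDUCED] / n,
        p_suppressed=counts[SUPPRESSED] / n,
        p_neutral=counts[NEUTRAL] / n,
    )


def load_cutoff_overrides(path: str | Path) -> dict[str, float]:
    """Two-column TSV ``array_id<TAB>fold`` -> override map."""
    overrides: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected array_id<TAB>fold")
            overrides[parts[0]] = float(parts[1])
    return overrides


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One seeded k-means run: k distinct rows as initial centers, 100-iter
    cap, relative inertia tolerance 1e-8."""
    centers = x[rng.choice(x.shape[0], size=k, replace=False)].copy()
    prev_inertia = np.inf
    labels = np.zeros(x.shape[0], dtype=int)
    inertia = np.inf
    for _ in range(100):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(x.shape[0]), labels].sum())
        for j in range(k):
            members = x[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster from the farthest point
                centers[j] = x[d2.min(axis=1).argmax()]
        if prev_inertia - inertia <= 1e-8 * max(prev_inertia, 1e-300):
            break
        prev_inertia = inertia
    return labels, inertia


def cluster_coexpressed(
    matrix: ExpressionMatrix,
    k: int,
    seed: int,
    max_missing_frac: float = 0.5,
    n_init: int = 10,
) -> list[set[str]]:
    """Seeded k-means on M-value rows; returns gene-id sets partitioning the
    retained genes.

    Genes with more than ``max_missing_frac`` missing cells are dropped; the
    rest are mean-imputed per array for distance computation only.  Each of
    ``n_init`` restarts starts Lloyd iteration from k distinct rows drawn by
    the seeded generator (100-iteration cap, relative-change tolerance 1e-8);
    the lowest-inertia restart wins.  Fully deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    data = matrix.data
    keep = data.isna().mean(axis=1) <= max_missing_frac
    retained = data.loc[keep]
    if k > retained.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {retained.shape[0]} genes retained after the "
            f"missingness filter"
        )
    x = retained.to_numpy(dtype=float).copy()
    col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])

    best_labels, best_inertia = None, np.inf
    for restart in range(n_init):
        rng = np.random.default_rng([seed, restart])
        labels, inertia = _lloyd(x, k, rng)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    genes = retained.index.to_numpy()
    return [set(genes[best_labels == j]) for j in range(k) if (best_labels == j).any()]
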