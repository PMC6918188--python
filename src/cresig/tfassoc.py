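"""Transcription-factor association by z-score profile correlation.

For a CRE's carrier-gene set, each array of the meta-matrix yields a
standardized mean expression Z = (X - mu) * sqrt(n) / delta, where X is the
set's mean M-value, mu and delta the array's mean and (population) standard
deviation over all measured genes, and n the set's effective size on that
array.  The Z profile across arrays is then correlated (Pearson r, pairwise
complete) with every TF's own M-value profile; significance comes from
T = r * sqrt[(n_pairs - 2) / (1 - r^2)] on a t distribution with n_pairs - 2
degrees of freedom (two-sided).  Associations require coverage of at least 80%
of the arrays (generalising the fixed "n > 184 of 231" rule).  Strength bands:
strong |r| >= 0.5, moderate 0.3 < |r| < 0.5, weak |r| <= 0.3.  A TF whose own
1-kb upstream region carries the CRE is flagged as potentially autoregulated.

Exposed statsmodels-style: :class:`TFAssociationModel` built from a Z profile,
the meta-matrix, and a TF table; ``fit()`` returns
:class:`TFAssociationResults` with ``summary()``, ``to_frame()``, and
``export_network()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .patterns import MotifHitTable

T_SENTINEL = float("inf")
MIN_P = 1e-300

STRONG_R = 0.5
MODERATE_R = 0.3
NETWORK_R = 0.45  # default |r| threshold for the exported edge list (inclusive)


@dataclass
class ZProfile:
    """Per-array standardized mean expression of a CRE gene set."""

    cre: str
    z: pd.Series  # index: array ids; NaN where undefined
    n_per_array: pd.Series  # effective gene-set size per array

    @property
    def array_ids(self) -> list[str]:
        return list(self.z.index)


def zscore_profile(
    gene_set: Iterable[str],
    matrix: ExpressionMatrix,
    cre: str = "CRE",
    population_sd: bool = True,
) -> ZProfile:
    """Z = (X - mu) * sqrt(n) / delta per array for a CRE gene set.

    mu and delta are computed over ALL genes with non-missing values on the
    array (delta is the population standard deviation by default); X and n use
    only the set's non-missing genes.  Z is missing where the set has no
    called gene on the array or the array has zero variance; a singleton set
    is legal (Z = (X - mu)/delta).
    """
    genes = list(dict.fromkeys(gene_set))
    missing = set(genes) - set(matrix.data.index)
    if missing:
        raise KeyError(f"gene set contains unknown ids: {sorted(missing)[:5]}")
    all_values = matrix.data.to_numpy()
    mu = np.nanmean(all_values, axis=0)
    ddof = 0 if population_sd else 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanstd(all_values, axis=0, ddof=ddof)
    sub = matrix.data.loc[genes].to_numpy()
    n_eff = (~np.isnan(sub)).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x = np.nanmean(sub, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) * np.sqrt(n_eff) / delta
    bad = (n_eff < 1) | (delta == 0) | np.isnan(delta)
    # the full-genome set is a legal degenerate case: X == mu exactly, Z == 0
    z[bad] = np.nan
    if len(genes) == matrix.n_genes and set(genes) == set(matrix.data.index):
        z = np.where(delta > 0, 0.0, np.nan)
    arrays = matrix.data.columns
    return ZProfile(
        cre=cre,
        z=pd.Series(z, index=arrays),
        n_per_array=pd.Series(n_eff, index=arrays),
    )


@dataclass
class TFAssociation:
    """One (CRE, TF) edge: correlation, T score, p-value, strength class."""

    cre: str
    tf: str
    tf_family: str
    r: float
    n_pairs: int
    T: float
    p: float
    strength: str
    autoregulated: bool | None = None
    below_coverage: bool = False


def t_score(r: float, n_pairs: int) -> float:
    """T = r * sqrt[(n - 2) / (1 - r^2)]; +/-inf sentinel at |r| = 1."""
    if abs(r) >= 1.0:
        return math.copysign(T_SENTINEL, r)
    return r * math.sqrt((n_pairs - 2) / (1.0 - r * r))


def classify_strength(r: float) -> str:
    """strong+/- at |r| >= 0.5; moderate+/- at 0.3 < |r| < 0.5; weak otherwise."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if r >= STRONG_R:
        return "strong+"
    if r <= -STRONG_R:
        return "strong-"
    if MODERATE_R < r < STRONG_R:
        return "moderate+"
    if -STRONG_R < r < -MODERATE_R:
        return "moderate-"
    return "weak"


def correlate_tf(
    zprofile: ZProfile,
    tf_gene_id: str,
    matrix: ExpressionMatrix,
    n_min: int | None = None,
    tf_family: str = "",
) -> TFAssociation:
    """Pearson correlation of a TF's M-value profile with a CRE Z profile.

    Arrays where either value is missing are dropped (pairwise complete);
    ``n_min`` defaults to ceil(0.8 * total arrays).  Below-coverage results
    are returned flagged (and excluded from ranking by the model)."""
    if tf_gene_id not in matrix.data.index:
        raise KeyError(f"TF {tf_gene_id!r} absent from the expression matrix")
    if n_min is None:
        n_min = math.ceil(0.8 * matrix.n_arrays)
    tf_vals = matrix.data.loc[tf_gene_id].reindex(zprofile.z.index)
    mask = tf_vals.notna() & zprofile.z.notna()
    n_pairs = int(mask.sum())
    if n_pairs < max(n_min, 3):
        return TFAssociation(
            cre=zprofile.cre, tf=tf_gene_id, tf_family=tf_family,
            r=float("nan"), n_pairs=n_pairs, T=float("nan"), p=float("nan"),
            strength="", below_coverage=True,
        )
    x = zprofile.z[mask].to_numpy()
    y = tf_vals[mask].to_numpy()
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    if math.isnan(r):  # zero variance on either side
        return TFAssociation(
            cre=zprofile.cre, tf=tf_gene_id, tf_family=tf_family,
            r=float("nan"), n_pairs=n_pairs, T=float("nan"), p=float("nan"),
            strength="", below_coverage=True,
        )
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # numerically perfect correlation
        r = math.copysign(1.0, r)
    T = t_score(r, n_pairs)
    if math.isinf(T):
        p = MIN_P
    else:
        p = max(float(2.0 * stats.t.sf(abs(T), df=n_pairs - 2)), MIN_P)
    return TFAssociation(
        cre=zprofile.cre, tf=tf_gene_id, tf_family=tf_family,
        r=r, n_pairs=n_pairs, T=T, p=p, strength=classify_strength(r),
    )


def autoregulation_flags(
    tf_ids: Iterable[str], hits: MotifHitTable
) -> dict[str, bool | None]:
    """True iff the TF's own gene carries >= 1 occurrence in the scanned
    (1-kb upstream) hit table; None when the TF is absent from the annotation
    behind the table's region set."""
    carriers = hits.carrier_genes()
    flags: dict[str, bool | None] = {}
    for tf in tf_ids:
        flags[tf] = tf in carriers
    return flags


def load_tf_table(path: str | Path) -> dict[str, str]:
    """TF list TSV ``tf_gene_id<TAB>family`` -> {id: family}."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("tf_gene_id", "tf") and lineno == 1:
                continue
            table[parts[0]] = parts[1] if len(parts) > 1 else ""
    return table


class TFAssociationModel:
    """CRE-TF association model: a Z profile against a panel of TF profiles."""

    def __init__(
        self,
        zprofile: ZProfile,
        matrix: ExpressionMatrix,
        tf_table: Mapping[str, str],
        upstream_hits: MotifHitTable | None = None,
    ):
        self.zprofile = zprofile
        self.matrix = matrix
        self.tf_table = dict(tf_table)
        self.upstream_hits = upstream_hits

    def fit(self, n_min: int | None = None) -> "TFAssociationResults":
        auto = (
            autoregulation_flags(self.tf_table, self.upstream_hits)
            if self.upstream_hits is not None
            else {}
        )
        associations = []
        skipped = []
        for tf, family in self.tf_table.items():
            if tf not in self.matrix.data.index:
                warnings.warn(f"TF {tf!r} absent from the matrix; skipped", stacklevel=2)
                skipped.append(tf)
                continue
            assoc = correlate_tf(self.zprofile, tf, self.matrix, n_min, family)
            assoc.autoregulated = auto.get(tf)
            associations.append(assoc)
        return TFAssociationResults(self, associations, skipped)


class TFAssociationResults:
    """Fitted CRE-TF associations, ranked by |r| (below-coverage excluded)."""

    def __init__(self, model, associations: list[TFAssociation], skipped: list[str]):
        self.model = model
        self.associations = associations
        self.skipped = skipped

    def ranked(self) -> list[TFAssociation]:
        usable = [a for a in self.associations if not a.below_coverage]
        return sorted(usable, key=lambda a: (-abs(a.r), a.p, a.tf))

    def to_frame(self, include_below_coverage: bool = False) -> pd.DataFrame:
        rows = self.ranked()
        if include_below_coverage:
            rows = rows + [a for a in self.associations if a.below_coverage]
        return pd.DataFrame(
            {
                "cre": [a.cre for a in rows],
                "tf": [a.tf for a in rows],
                "tf_family": [a.tf_family for a in rows],
                "r": [a.r for a in rows],
                "n_pairs": [a.n_pairs for a in rows],
                "T": [a.T for a in rows],
                "p": [a.p for a in rows],
                "strength": [a.strength for a in rows],
                "autoregulated": [a.autoregulated for a in rows],
                "below_coverage": [a.below_coverage for a in rows],
            }
        )

    def summary(self, top: int = 20) -> str:
        frame = self.to_frame().head(top)
        n_bc = sum(a.below_coverage for a in self.associations)
        lines = [
            f"TF associations for {self.model.zprofile.cre}: "
            f"{len(self.associations)} TFs tested, {n_bc} below coverage, "
            f"{len(self.skipped)} absent from the matrix",
            "",
        ]
        with pd.option_context("display.float_format", lambda v: f"{v:.3g}"):
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def export_network(
        self, path: str | Path, r_threshold: float = NETWORK_R
    ) -> pd.DataFrame:
        """TSV edge list filtered to |r| >= threshold (inclusive), sorted by
        |r| descending then p ascending."""
        edges = [a for a in self.ranked() if abs(a.r) >= r_threshold]
        frame = pd.DataFrame(
            {
                "cre": [a.cre for a in edges],
                "tf": [a.tf for a in edges],
                "r": [a.r for a in edges],
                "T": [a.T for a in edges],
                "p": [a.p for a in edges],
                "sign": ["+" if a.r >= 0 else "-" for a in edges],
                "autoregulated": [a.autoregulated for a in edges],
                "tf_family": [a.tf_family for a in edges],
            }
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return frame
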