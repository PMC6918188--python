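"""Regulatory fingerprints: chi-squared enrichment of regulation states.

The reverse-search core.  For a set of genes carrying a candidate cis-regulatory
element, each array of the expression meta-matrix is asked: are these genes more
often induced (or suppressed, or differentially expressed at all) than the
genome-wide background proportions predict?  Each question is a 1-df
goodness-of-fit chi-squared on the binary split (target state vs rest) with
expected counts ``n * p_background``; the vector of per-array significances is
the CRE's *regulatory fingerprint*.  No continuity correction is applied;
expected cells below 5 are flagged rather than switched to an exact test.
Raw p-values are reported by default (the analysis convention is p < 0.05 per
array); Benjamini-Hochberg across arrays is available as an option.

The core is exposed statsmodels-style: build a :class:`FingerprintModel` from a
gene set and regulation calls, ``fit()`` it, and read the per-array estimates
off the returned :class:`FingerprintResults` (``summary()``, ``to_frame()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import INDUCED, NEUTRAL, SUPPRESSED, RegulationCalls, array_background
from .patterns import MotifHitTable, MotifPattern, scan_region_set, stratify_hits
from .regions import REGION_CODES, RegionSet

MODES = ("induced", "suppressed", "combined")
MIN_P = 1e-300  # reported when the background makes the observation "impossible"

_STATE_OF_MODE = {"induced": INDUCED, "suppressed": SUPPRESSED}


def cre_name(region_kind: str, index: int) -> str:
    """Auto-assigned CRE name, OS_<AA>_<NNN> (NNN = discovery order)."""
    return f"OS_{REGION_CODES[region_kind]}_{index:03d}"


@dataclass
class EnrichmentResult:
    """One array's observed/expected regulation counts and chi-squared tests."""

    array_id: str
    n: int
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def is_significant(self, mode: str, alpha: float = 0.05) -> bool:
        return mode in self.p and self.p[mode] < alpha

    def is_enriched(self, mode: str, alpha: float = 0.05) -> bool:
        """Significant AND in the enriched direction ("significantly more
        induced/suppressed") — the chi-squared statistic alone is sign-blind."""
        return self.is_significant(mode, alpha) and self.direction.get(mode) == "enriched"


def _gof_binary(observed_target: int, n: int, p_target: float) -> tuple[float, float, set[str]]:
    """1-df goodness-of-fit chi-squared of target-vs-rest against p_target."""
    flags: set[str] = set()
    e_t = p_target * n
    e_r = (1.0 - p_target) * n
    if e_t == 0.0 or e_r == 0.0:
        if (e_t == 0.0 and observed_target > 0) or (e_r == 0.0 and observed_target < n):
            flags.add("impossible_under_background")
            return float("inf"), MIN_P, flags
        return 0.0, 1.0, flags
    if min(e_t, e_r) < 5:
        flags.add("low_expected")
    o_t = observed_target
    o_r = n - observed_target
    chi2 = (o_t - e_t) ** 2 / e_t + (o_r - e_r) ** 2 / e_r
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, MIN_P), flags


def enrichment_test(
    gene_set: Iterable[str],
    calls: RegulationCalls,
    array_id: str,
    mode: str = "induced",
    combined_3cat: bool = False,
) -> EnrichmentResult:
    """Chi-squared enrichment of one regulation state in a gene set on one array.

    ``mode='combined'`` tests (induced + suppressed) vs neutral as a binary
    split by default; with ``combined_3cat=True`` it is instead a 2-df
    three-category goodness-of-fit against (p_induced, p_suppressed, p_neutral).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    genes = list(dict.fromkeys(gene_set))
    missing = set(genes) - set(calls.calls.index)
    if missing:
        raise KeyError(f"gene set contains ids absent from the calls: {sorted(missing)[:5]}")
    bg = array_background(calls, array_id)
    col = calls.calls.loc[genes, array_id]
    col = col[col.notna()]
    n = len(col)
    if n == 0:
        raise ValueError(f"gene set has no non-missing calls on array {array_id!r}")
    obs = {
        "induced": int((col == INDUCED).sum()),
        "suppressed": int((col == SUPPRESSED).sum()),
        "neutral": int((col == NEUTRAL).sum()),
    }
    exp = {
        "induced": bg.p_induced * n,
        "suppressed": bg.p_suppressed * n,
        "neutral": bg.p_neutral * n,
    }
    result = EnrichmentResult(array_id=array_id, n=n, observed=obs, expected=exp)

    if mode == "combined" and combined_3cat:
        cells = [
            (obs["induced"], exp["induced"]),
            (obs["suppressed"], exp["suppressed"]),
            (obs["neutral"], exp["neutral"]),
        ]
        if any(e == 0.0 and o > 0 for o, e in cells):
            chi2, p, flags = float("inf"), MIN_P, {"impossible_under_background"}
        else:
            live = [(o, e) for o, e in cells if e > 0.0]
            chi2 = float(sum((o - e) ** 2 / e for o, e in live))
            p = max(float(stats.chi2.sf(chi2, df=max(len(live) - 1, 1))), MIN_P)
            flags = {"low_expected"} if min(e for _, e in live) < 5 else set()
        o_t = obs["induced"] + obs["suppressed"]
        e_t = exp["induced"] + exp["suppressed"]
    else:
        if mode == "combined":
            o_t = obs["induced"] + obs["suppressed"]
            p_t = bg.p_induced + bg.p_suppressed
        else:
            o_t = obs[mode]
            p_t = bg.p_target(mode)
        e_t = p_t * n
        chi2, p, flags = _gof_binary(o_t, n, p_t)

    result.chi2[mode] = chi2
    result.p[mode] = p
    result.direction[mode] = "enriched" if o_t > e_t else ("depleted" if o_t < e_t else "none")
    result.flags |= flags
    return result


def _all_mode_result(
    genes: Sequence[str],
    calls: RegulationCalls,
    array_id: str,
    combined_3cat: bool,
) -> EnrichmentResult:
    """EnrichmentResult carrying all three modes; degenerate arrays flagged."""
    try:
        res = enrichment_test(genes, calls, array_id, "induced", combined_3cat)
    except ValueError:
        res = EnrichmentResult(
            array_id=array_id, n=0, observed={}, expected={}, flags={"degenerate_array"}
        )
        return res
    for mode in ("suppressed", "combined"):
        extra = enrichment_test(genes, calls, array_id, mode, combined_3cat)
        res.chi2[mode] = extra.chi2[mode]
        res.p[mode] = extra.p[mode]
        res.direction[mode] = extra.direction[mode]
        res.flags |= extra.flags
    return res


class FingerprintModel:
    """Regulatory-fingerprint model for one CRE gene set.

    Parameters
    ----------
    gene_set : iterable of gene ids
        Genes carrying the candidate element ("at least one copy").
    calls : RegulationCalls
        Per-array regulation states of the whole measured genome; genome-wide
        proportions per array form the null expectation.
    name, pattern, region_kind : metadata carried into results and reports.
    """

    def __init__(
        self,
        gene_set: Iterable[str],
        calls: RegulationCalls,
        name: str = "CRE",
        pattern: str = "",
        region_kind: str = "",
    ):
        self.gene_set = list(dict.fromkeys(gene_set))
        if not self.gene_set:
            raise ValueError("gene set is empty: the pattern occurs in no gene")
        self.calls = calls
        self.name = name
        self.pattern = pattern
        self.region_kind = region_kind

    def fit(
        self,
        alpha: float = 0.05,
        arrays: Sequence[str] | None = None,
        correction: str | None = None,
        combined_3cat: bool = False,
    ) -> "FingerprintResults":
        """Run the three enrichment tests on every array.

        ``correction=None`` reports raw p-values (default convention);
        ``correction='bh'`` applies Benjamini-Hochberg across arrays per mode.
        """
        if correction not in (None, "none", "bh"):
            raise ValueError(f"correction must be None or 'bh', got {correction!r}")
        arrays = list(arrays) if arrays is not None else self.calls.array_ids
        results = [
            _all_mode_result(self.gene_set, self.calls, a, combined_3cat) for a in arrays
        ]
        if correction == "bh":
            for mode in MODES:
                idx = [i for i, r in enumerate(results) if mode in r.p]
                if idx:
                    adj = stats.false_discovery_control([results[i].p[mode] for i in idx])
                    for i, q in zip(idx, adj):
                        results[i].p[mode] = float(q)
        return FingerprintResults(self, results, alpha=alpha)


class FingerprintResults:
    """Fitted regulatory fingerprint: one :class:`EnrichmentResult` per array."""

    def __init__(self, model: FingerprintModel, results: list[EnrichmentResult], alpha: float):
        self.model = model
        self.results = results
        self.alpha = alpha

    @property
    def name(self) -> str:
        return self.model.name

    def result_for(self, array_id: str) -> EnrichmentResult:
        for r in self.results:
            if r.array_id == array_id:
                return r
        raise KeyError(array_id)

    def significant_arrays(self, mode: str = "induced", alpha: float | None = None) -> list[str]:
        a = self.alpha if alpha is None else alpha
        return [r.array_id for r in self.results if r.is_significant(mode, a)]

    def enriched_arrays(self, mode: str = "induced", alpha: float | None = None) -> list[str]:
        """Arrays where the gene set is significantly MORE in the target state."""
        a = self.alpha if alpha is None else alpha
        return [r.array_id for r in self.results if r.is_enriched(mode, a)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "cre": self.model.name,
                "pattern": self.model.pattern,
                "array": r.array_id,
                "n": r.n,
            }
            for mode in MODES:
                row[f"p_{mode[:3] if mode != 'combined' else 'combined'}"] = r.p.get(
                    mode, np.nan
                )
            row["direction"] = r.direction.get("combined", "")
            row["flags"] = ",".join(sorted(r.flags))
            rows.append(row)
        frame = pd.DataFrame(rows)
        return frame.rename(columns={"p_ind": "p_induced", "p_sup": "p_suppressed"})

    def summary(self) -> str:
        """Human-readable per-array table, mirroring the report layout."""
        frame = self.to_frame()
        lines = [
            f"Regulatory fingerprint: {self.model.name}"
            + (f" ({self.model.pattern}, {self.model.region_kind})" if self.model.pattern else ""),
            f"gene-set size: {len(self.model.gene_set)}; alpha = {self.alpha}",
            "",
        ]
        with pd.option_context("display.float_format", lambda v: f"{v:.3g}"):
            lines.append(frame.to_string(index=False))
        sig = self.significant_arrays("combined")
        lines.append("")
        lines.append(
            f"arrays significant (combined, p < {self.alpha}): "
            + (", ".join(sig) if sig else "none")
        )
        return "\n".join(lines)


def regulatory_fingerprint(
    pattern: MotifPattern,
    regions: RegionSet,
    calls: RegulationCalls,
    name: str | None = None,
    alpha: float = 0.05,
    strands: str = "both",
    **fit_kwargs,
) -> FingerprintResults:
    """Scan a region set for a pattern and fingerprint its carrier genes."""
    hits = scan_region_set(regions, pattern, strands=strands)
    carriers = hits.carrier_genes() & set(calls.calls.index)
    if not carriers:
        raise ValueError(f"pattern {pattern.name!r} occurs in no measured gene")
    model = FingerprintModel(
        sorted(carriers),
        calls,
        name=name or pattern.name,
        pattern=pattern.iupac,
        region_kind=regions.kind,
    )
    return model.fit(alpha=alpha, **fit_kwargs)


def stratified_fingerprint(
    hits: MotifHitTable,
    calls: RegulationCalls,
    mode: str,
    arrays: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_stratum_n: int = 20,
    **fit_kwargs,
) -> dict[str, FingerprintResults]:
    """Fingerprint each position/orientation/copy-number stratum independently.

    Every stratum's gene set is tested against the same genome background;
    strata smaller than ``min_stratum_n`` are still reported but carry an
    ``underpowered`` flag on every array.
    """
    strata = stratify_hits(hits, mode)
    strata = {k: v & set(calls.calls.index) for k, v in strata.items()}
    strata = {k: v for k, v in strata.items() if v}
    if not strata:
        raise ValueError("all strata are empty")
    out: dict[str, FingerprintResults] = {}
    for label in sorted(strata):
        genes = strata[label]
        model = FingerprintModel(
            sorted(genes),
            calls,
            name=f"{hits.pattern.name}[{mode}={label}]",
            pattern=hits.pattern.iupac,
            region_kind=hits.region_kind,
        )
        fitted = model.fit(alpha=alpha, arrays=arrays, **fit_kwargs)
        if len(genes) < min_stratum_n:
            for r in fitted.results:
                r.flags.add("underpowered")
        out[label] = fitted
    return out


def fingerprint_report(
    fingerprints: Sequence[FingerprintResults],
    path: str | Path,
    matrix_path: str | Path | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Write the long-format report TSV and (optionally) a significance matrix.

    The matrix has one row per CRE and one column per array; each cell holds
    ``p_ind:<p>`` / ``p_sup:<p>`` for directions significant at ``alpha`` and
    ``N`` otherwise, mirroring the table convention of the analysis.
    """
    frames = [fp.to_frame() for fp in fingerprints]
    long = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cre", "pattern", "array", "n", "p_induced", "p_suppressed",
                 "p_combined", "direction", "flags"]
    )
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if matrix_path is not None:
        rows = {}
        for fp in fingerprints:
            cells = {}
            for r in fp.results:
                parts = []
                if r.is_significant("induced", alpha) and r.direction.get("induced") == "enriched":
                    parts.append(f"p_ind:{r.p['induced']:.3g}")
                if r.is_significant("suppressed", alpha) and r.direction.get("suppressed") == "enriched":
                    parts.append(f"p_sup:{r.p['suppressed']:.3g}")
                cells[r.array_id] = "/".join(parts) if parts else "N"
            rows[fp.name] = cells
        pd.DataFrame(rows).T.to_csv(matrix_path, sep="\t", index_label="cre")
    return long
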