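"""Chi-squared enrichment and regulatory fingerprints."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cresig.expression import ExpressionMatrix, RegulationCalls, call_regulation
from cresig.fingerprint import (
    FingerprintModel,
    cre_name,
    enrichment_test,
    fingerprint_report,
    regulatory_fingerprint,
    stratified_fingerprint,
)
from cresig.patterns import MotifPattern, scan_region_set
from cresig.regions import extract_region_set
from cresig.simulate import EffectSpec, PlantingSpec, make_genome, plant_motifs, simulate_expression


def calls_with_counts(n_induced, n_suppressed, n_neutral, array="a1"):
    states = ["I"] * n_induced + ["S"] * n_suppressed + ["N"] * n_neutral
    frame = pd.DataFrame({array: states}, index=[f"g{i}" for i in range(len(states))])
    return RegulationCalls(frame, pd.Series({array: 2.0}))


class TestEnrichment:
    def test_worked_cell(self):
        """n=100 genes with background 5% induced and 15 observed induced:
        chi2 = (15-5)^2/5 + (85-95)^2/95."""
        # genome: 2000 genes, exactly 100 induced (p = 0.05); the gene set is
        # 100 genes of which 15 are induced
        calls = calls_with_counts(100, 0, 1900)
        gene_set = [f"g{i}" for i in range(15)] + [f"g{i}" for i in range(115, 200)]
        res = enrichment_test(gene_set, calls, "a1", "induced")
        expected = (15 - 5) ** 2 / 5 + (85 - 95) ** 2 / 95
        assert res.chi2["induced"] == pytest.approx(expected, abs=1e-9)
        assert round(res.chi2["induced"], 2) == 21.05
        assert res.direction["induced"] == "enriched"

    def test_observed_equals_expected(self):
        calls = calls_with_counts(100, 100, 1800)
        gene_set = (
            [f"g{i}" for i in range(5)]  # 5 of 100 induced
            + [f"g{i}" for i in range(100, 105)]  # 5 of 100 suppressed
            + [f"g{i}" for i in range(200, 290)]  # 90 neutral
        )
        res = enrichment_test(gene_set, calls, "a1", "induced")
        assert res.chi2["induced"] == pytest.approx(0.0, abs=1e-12)
        assert res.p["induced"] == 1.0

    def test_full_genome_self_consistency(self):
        calls = calls_with_counts(50, 30, 920)
        res = enrichment_test(list(calls.calls.index), calls, "a1", "combined")
        assert res.chi2["combined"] == pytest.approx(0.0, abs=1e-9)
        assert res.p["combined"] == pytest.approx(1.0)

    def test_empty_effective_set_rejected(self):
        frame = pd.DataFrame({"a1": ["I", np.nan]}, index=["g0", "g1"])
        calls = RegulationCalls(frame, pd.Series({"a1": 2.0}))
        with pytest.raises(ValueError, match="non-missing"):
            enrichment_test(["g1"], calls, "a1", "induced")

    def test_impossible_under_background_flagged(self):
        calls = calls_with_counts(0, 10, 990)
        res = enrichment_test([f"g{i}" for i in range(5)], calls, "a1", "induced")
        # 0 observed induced and p_induced = 0: consistent, chi2 = 0
        assert res.chi2["induced"] == 0.0

    def test_low_expected_flag(self):
        calls = calls_with_counts(10, 10, 1980)
        res = enrichment_test([f"g{i}" for i in range(2, 30)], calls, "a1", "induced")
        assert "low_expected" in res.flags

    def test_oracle_equivalence_random_configurations(self):
        """500 random gene-set/array configurations agree with scipy's
        textbook chi-squared to 1e-9."""
        rng = np.random.default_rng(2024)
        n_genes = 1500
        for _ in range(500):
            p_i, p_s = rng.uniform(0.02, 0.3, size=2) / 2
            states = rng.choice(
                ["I", "S", "N"], size=n_genes, p=[p_i, p_s, 1 - p_i - p_s]
            )
            frame = pd.DataFrame({"a": states}, index=[f"g{i}" for i in range(n_genes)])
            calls = RegulationCalls(frame, pd.Series({"a": 2.0}))
            size = int(rng.integers(20, 400))
            gene_set = [f"g{i}" for i in rng.choice(n_genes, size=size, replace=False)]
            mode = ["induced", "suppressed", "combined"][int(rng.integers(3))]
            res = enrichment_test(gene_set, calls, "a", mode)
            # independent oracle: textbook goodness-of-fit via scipy.stats.chisquare
            col = frame.loc[gene_set, "a"]
            if mode == "combined":
                obs_t = int((col != "N").sum())
                p_t = float((states != "N").mean())
            else:
                s = "I" if mode == "induced" else "S"
                obs_t = int((col == s).sum())
                p_t = float((states == s).mean())
            n = len(col)
            expected = [p_t * n, (1 - p_t) * n]
            chi2_ref, p_ref = stats.chisquare([obs_t, n - obs_t], f_exp=expected)
            assert res.chi2[mode] == pytest.approx(float(chi2_ref), abs=1e-9)
            assert res.p[mode] == pytest.approx(float(p_ref), abs=1e-9)

    def test_monotonicity_adding_induced_gene(self):
        """Adding an induced gene never decreases chi2 when enrichment holds."""
        calls = calls_with_counts(100, 0, 1900)
        base = [f"g{i}" for i in range(15)] + [f"g{i}" for i in range(115, 200)]
        res0 = enrichment_test(base, calls, "a1", "induced")
        res1 = enrichment_test(base + ["g20"], calls, "a1", "induced")
        assert res0.direction["induced"] == "enriched"
        assert res1.chi2["induced"] >= res0.chi2["induced"]

    def test_combined_3cat_variant(self):
        calls = calls_with_counts(100, 100, 1800)
        gene_set = [f"g{i}" for i in range(40)] + [f"g{i}" for i in range(200, 260)]
        res = enrichment_test(gene_set, calls, "a1", "combined", combined_3cat=True)
        obs = [res.observed["induced"], res.observed["suppressed"], res.observed["neutral"]]
        exp = [res.expected["induced"], res.expected["suppressed"], res.expected["neutral"]]
        chi2_ref = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert res.chi2["combined"] == pytest.approx(chi2_ref, abs=1e-9)
        assert res.p["combined"] == pytest.approx(float(stats.chi2.sf(chi2_ref, 2)), abs=1e-12)


class TestFingerprintModel:
    def test_planted_arrays_significant_only(self, planted_study):
        bundle, matrix, calls, carriers, responders = planted_study
        fp = FingerprintModel(sorted(carriers), calls, name="ABRE").fit()
        assert fp.significant_arrays("induced") == ["array_01"]

    def test_empty_gene_set_rejected(self, planted_study):
        _, _, calls, _, _ = planted_study
        with pytest.raises(ValueError, match="empty"):
            FingerprintModel([], calls)

    def test_summary_mentions_significant_array(self, planted_study):
        bundle, matrix, calls, carriers, _ = planted_study
        fp = FingerprintModel(sorted(carriers), calls, name="ABRE").fit()
        text = fp.summary()
        assert "ABRE" in text and "array_01" in text

    def test_bh_correction_weakens_p(self, planted_study):
        _, _, calls, carriers, _ = planted_study
        raw = FingerprintModel(sorted(carriers), calls).fit()
        adj = FingerprintModel(sorted(carriers), calls).fit(correction="bh")
        for r_raw, r_adj in zip(raw.results, adj.results):
            assert r_adj.p["induced"] >= r_raw.p["induced"] - 1e-12

    def test_regulatory_fingerprint_end_to_end(self, planted_study, abre):
        bundle, matrix, calls, carriers, _ = planted_study
        regions = extract_region_set(bundle.contigs, bundle.models, "up1k")
        fp = regulatory_fingerprint(abre, regions, calls)
        assert set(fp.model.gene_set) == carriers
        assert fp.significant_arrays("induced") == ["array_01"]

    def test_absent_pattern_rejected(self, planted_study):
        bundle, matrix, calls, _, _ = planted_study
        regions = extract_region_set(bundle.contigs, bundle.models, "up1k")
        # 25-mer that cannot occur in the synthetic promoters
        pattern = MotifPattern("none", "ACGTACGTACGTACGTACGTACGTA")
        with pytest.raises(ValueError, match="no measured gene"):
            regulatory_fingerprint(pattern, regions, calls)


class TestStratified:
    def test_identical_gene_sets_identical_results(self, planted_study, abre):
        bundle, matrix, calls, carriers, _ = planted_study
        fp1 = FingerprintModel(sorted(carriers), calls).fit()
        fp2 = FingerprintModel(sorted(carriers), calls).fit()
        assert fp1.to_frame().equals(fp2.to_frame())

    def test_underpowered_strata_flagged_but_reported(self, planted_study, abre):
        bundle, matrix, calls, carriers, _ = planted_study
        regions = extract_region_set(bundle.contigs, bundle.models, "up1k")
        hits = scan_region_set(regions, abre)
        strat = stratified_fingerprint(hits, calls, "copy_number", min_stratum_n=1000)
        for fp in strat.values():
            assert all("underpowered" in r.flags for r in fp.results)

    def test_position_effect_detected_in_matching_bin(self):
        """Effect planted only at distances 1-200 is significant only there."""
        bundle = make_genome(n_genes=1000, seed=21)
        spec = PlantingSpec(pattern="CACGTGTC", fraction=0.5, name="X")
        plant_motifs(bundle, spec, seed=22)
        regions = extract_region_set(bundle.contigs, bundle.models, "up1k")
        hits = scan_region_set(regions, MotifPattern("X", "CACGTGTC"))
        near = {
            p.gene_id for p in bundle.truth.placements if p.position <= 200
        }
        eff = EffectSpec(arrays=["array_01"], direction="induce",
                         responder_fraction=0.8)
        matrix, _ = simulate_expression(
            sorted(bundle.models), {"X": (near, eff)}, n_arrays=2, seed=23
        )
        calls = call_regulation(matrix)
        strat = stratified_fingerprint(hits, calls, "position", arrays=["array_01"])
        assert strat["1-200"].results[0].is_enriched("induced")
        off_target = [
            lab for lab, fp in strat.items()
            if lab != "1-200" and fp.results[0].is_enriched("induced")
        ]
        assert len(off_target) <= 1  # chance allows an occasional false positive


class TestReport:
    def test_report_round_trip_and_determinism(self, planted_study, tmp_path):
        _, _, calls, carriers, _ = planted_study
        fp = FingerprintModel(sorted(carriers), calls, name="ABRE").fit()
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        m1, m2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        fingerprint_report([fp], p1, m1)
        fingerprint_report([fp], p2, m2)
        assert p1.read_bytes() == p2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()
        matrix = pd.read_csv(m1, sep="\t", index_col=0)
        # induced only in array_01, "N" elsewhere
        assert matrix.loc["ABRE", "array_01"].startswith("p_ind:")
        assert (matrix.loc["ABRE"].drop("array_01") == "N").all()

    def test_cre_naming(self):
        assert cre_name("up1k", 1) == "OS_1K_001"
        assert cre_name("intron", 12) == "OS_UT_012"
        assert cre_name("down1k", 3) == "OS_1D_003"
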