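"""Allele-score construction: the four QC screens, alignment, scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibromr import (
    SimConfig,
    VariantInstrument,
    align_effect_alleles,
    compute_allele_score,
    filter_chd_ld,
    filter_cross_cohort_missingness,
    filter_imputation_quality,
    filter_risk_factor_correlation,
    panel_to_variants,
    prune_ld_pairs,
    rescale_score,
    retained,
    score_risk_factor_check,
    simulate_cohort,
    simulate_risk_factor_correlated_variant,
    variant_panel,
)
from fibromr.instruments import AlleleScore

from conftest import make_minimal_cohort


def mk_variant(vid="v1", beta=0.05, rank=1, **kw):
    defaults = dict(
        variant_id=vid,
        effect_allele="A",
        other_allele="G",
        published_beta=beta,
        published_se=0.01,
        source_rank=rank,
    )
    defaults.update(kw)
    return VariantInstrument(**defaults)


class TestImputationQualityFilter:
    @pytest.mark.parametrize(
        "method,quality,flagged",
        [
            ("MACH", 0.29, True),
            ("MACH", 0.30, False),  # strict inequality
            ("IMPUTE", 0.35, True),
            ("IMPUTE", 0.40, False),
            ("IMPUTE", 0.39999, True),
        ],
    )
    def test_method_specific_thresholds(self, method, quality, flagged):
        v = mk_variant()
        filter_imputation_quality([v], {"v1": (method, quality)})
        assert ("low_imputation" in v.qc_flags) is flagged

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            filter_imputation_quality([mk_variant()], {"v1": ("minimac", 0.9)})

    def test_variant_absent_from_table_untouched(self):
        v = mk_variant()
        filter_imputation_quality([v], {"other": ("MACH", 0.1)})
        assert v.passes_qc


class TestRiskFactorCorrelationFilter:
    def _cohort_with_ranks(self, dosage_ranks, trait_vals):
        """5-person cohort: one variant with chosen dosage ordering, BMI as
        given; every other trait constant (skipped with a warning)."""
        dosages = pd.DataFrame({"v1": np.array(dosage_ranks) * 0.5 - 0.5})
        c = make_minimal_cohort(dosages)
        c.phenotypes["bmi"] = trait_vals
        for t in ("ldl", "hdl", "hypertension", "diabetes", "smoking"):
            c.phenotypes[t] = 1.0
        return c

    def test_exact_rho_point_one_retained(self):
        # ranks (2,5,1,4,3) vs (1,2,3,4,5): sum d^2 = 18 -> Spearman exactly 0.10
        c = self._cohort_with_ranks([2, 5, 1, 4, 3], [1.0, 2.0, 3.0, 4.0, 5.0])
        v = mk_variant()
        filter_risk_factor_correlation([v], [c])
        assert v.passes_qc

    def test_perfect_correlation_flagged(self):
        c = self._cohort_with_ranks([1, 2, 3, 4, 5], [1.0, 2.0, 3.0, 4.0, 5.0])
        v = mk_variant()
        filter_risk_factor_correlation([v], [c])
        assert "rf_correlated" in v.qc_flags

    def test_single_offending_cohort_suffices(self, config):
        clean = simulate_cohort(config, 1)
        dirty = simulate_risk_factor_correlated_variant(
            SimConfig(n_individuals=10_000, seed=13), 0.3
        )
        v = [mk_variant(vid) for vid in clean.dosages.columns[:3]]
        filter_risk_factor_correlation(v, [clean, dirty])
        assert "rf_correlated" in v[0].qc_flags  # the copula-coupled variant
        assert v[1].passes_qc and v[2].passes_qc

    def test_matches_scipy_spearman_oracle(self):
        rng = np.random.default_rng(4)
        dosages = pd.DataFrame(
            rng.integers(0, 3, size=(300, 4)).astype(float),
            columns=[f"v{j}" for j in range(4)],
        )
        c = make_minimal_cohort(dosages)
        variants = [mk_variant(f"v{j}") for j in range(4)]
        filter_risk_factor_correlation(variants, [c])
        traits = ["bmi", "ldl", "hdl", "hypertension", "diabetes", "smoking"]
        for v in variants:
            worst = max(
                abs(stats.spearmanr(dosages[v.variant_id], c.phenotypes[t]).statistic)
                for t in traits
            )
            assert ("rf_correlated" in v.qc_flags) == bool(worst > 0.10)


class TestChdLdFilter:
    def test_threshold_cases(self):
        table = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "locus_id": ["chd1", "chd1"],
                "r2": [0.25, 0.20],
            }
        )
        v1, v2 = mk_variant("v1"), mk_variant("v2")
        filter_chd_ld([v1, v2], table)
        assert "chd_ld" in v1.qc_flags
        assert v2.passes_qc  # exactly 0.20 retained

    def test_empty_locus_table_flags_nothing(self):
        v = mk_variant()
        filter_chd_ld([v], pd.DataFrame(columns=["variant_id", "locus_id", "r2"]))
        assert v.passes_qc

    def test_out_of_range_r2_rejected(self):
        table = pd.DataFrame({"variant_id": ["v1"], "locus_id": ["x"], "r2": [1.2]})
        with pytest.raises(ValueError):
            filter_chd_ld([mk_variant()], table)


def _ld(pairs):
    return pd.DataFrame(pairs, columns=["id1", "id2", "r2"])


class TestLdPruning:
    def test_larger_scan_preferred(self):
        a, b = mk_variant("a", rank=3), mk_variant("b", rank=1)
        prune_ld_pairs([a, b], _ld([("a", "b", 0.71)]))
        assert a.passes_qc and "ld_pruned" in b.qc_flags

    def test_exact_point_seven_keeps_both(self):
        a, b = mk_variant("a", rank=3), mk_variant("b", rank=1)
        prune_ld_pairs([a, b], _ld([("a", "b", 0.70)]))
        assert a.passes_qc and b.passes_qc

    def test_triangle_same_source_single_survivor(self):
        vs = [mk_variant(x, beta=0.05, rank=2) for x in ("a", "b", "c")]
        prune_ld_pairs(
            vs, _ld([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)])
        )
        kept = retained(vs)
        assert [v.variant_id for v in kept] == ["a"]  # id tie-break

    def test_beta_tie_break_before_id(self):
        a = mk_variant("zzz", beta=0.09, rank=2)
        b = mk_variant("aaa", beta=0.02, rank=2)
        prune_ld_pairs([a, b], _ld([("zzz", "aaa", 0.8)]))
        assert a.passes_qc and not b.passes_qc

    def test_matches_brute_force_component_oracle(self):
        """On random graphs of <= 12 variants the pruned set equals an
        independent BFS component search applying the retention rule."""
        rng = np.random.default_rng(9)
        for trial in range(20):
            n = int(rng.integers(2, 13))
            ids = [f"v{i:02d}" for i in range(n)]
            variants = [
                mk_variant(vid, beta=float(rng.normal(0, 0.05)) or 0.01,
                           rank=int(rng.integers(1, 4)))
                for vid in ids
            ]
            pairs = [
                (ids[i], ids[j], float(rng.uniform(0, 1)))
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.3
            ]
            expected_kept = _brute_force_prune(variants, pairs)
            prune_ld_pairs(variants, _ld(pairs))
            got = {v.variant_id for v in variants if "ld_pruned" not in v.qc_flags}
            assert got == expected_kept


def _brute_force_prune(variants, pairs):
    adj = {v.variant_id: set() for v in variants}
    for i, j, r2 in pairs:
        if r2 > 0.70:
            adj[i].add(j)
            adj[j].add(i)
    by_id = {v.variant_id: v for v in variants}
    seen, kept = set(), set()
    for start in adj:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            x = queue.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    queue.append(y)
        seen |= comp
        best = min(
            comp,
            key=lambda vid: (
                -by_id[vid].source_rank,
                -abs(by_id[vid].published_beta),
                vid,
            ),
        )
        kept.add(best)
        # singletons keep themselves
        if len(comp) == 1:
            kept.add(start)
    return kept


class TestMissingnessFilter:
    def test_absent_in_one_cohort_flags(self):
        full = make_minimal_cohort(pd.DataFrame({"a": [0.0, 1], "b": [1.0, 2]}))
        partial = make_minimal_cohort(pd.DataFrame({"a": [0.0, 1]}))
        va, vb = mk_variant("a"), mk_variant("b")
        filter_cross_cohort_missingness([va, vb], [full, partial])
        assert va.passes_qc
        assert "missing_in_cohort" in vb.qc_flags

    def test_nested_replication_score_counts(self):
        """38 variants minus 6 unavailable in replication gives a 32-variant
        replication score (membership synthetic, count is the check)."""
        ids = [f"v{i:02d}" for i in range(38)]
        disc = make_minimal_cohort(
            pd.DataFrame(np.zeros((3, 38)), columns=ids)
        )
        repl = make_minimal_cohort(
            pd.DataFrame(np.zeros((3, 32)), columns=ids[:32])
        )
        variants = [mk_variant(vid) for vid in ids]
        filter_cross_cohort_missingness(variants, [disc])
        assert len(retained(variants)) == 38
        filter_cross_cohort_missingness(variants, [repl])
        assert len(retained(variants)) == 32


class TestFilterAlgebra:
    def test_idempotence_and_order_invariance(self, config):
        cohorts = [simulate_cohort(config, i) for i in range(2)]
        chd = pd.DataFrame(
            {"variant_id": ["snp001"], "locus_id": ["x"], "r2": [0.5]}
        )
        ld = _ld([("snp002", "snp003", 0.9)])

        def apply_all(order_reversed=False, twice=False):
            vs = panel_to_variants(variant_panel(config))
            ops = [
                lambda v: filter_chd_ld(v, chd),
                lambda v: prune_ld_pairs(v, ld),
                lambda v: filter_cross_cohort_missingness(v, cohorts),
                lambda v: filter_risk_factor_correlation(v, cohorts),
            ]
            if order_reversed:
                ops = ops[::-1]
            for op in ops:
                op(vs)
                if twice:
                    op(vs)
            return {v.variant_id: frozenset(v.qc_flags) for v in vs}

        base = apply_all()
        assert apply_all(order_reversed=True) == base
        assert apply_all(twice=True) == base


class TestAlignment:
    def test_negative_beta_reflected(self):
        v = mk_variant(beta=-0.03)
        dosages = pd.DataFrame({"v1": [2.0, 1.0, 0.0]})
        aligned_v, aligned_d = align_effect_alleles([v], dosages)
        assert list(aligned_d["v1"]) == [0.0, 1.0, 2.0]
        assert aligned_v[0].published_beta == 0.03
        assert aligned_v[0].effect_allele == "G"  # labels swapped

    def test_positive_beta_untouched_and_mixed_panel(self):
        vs = [mk_variant("a", 0.03), mk_variant("b", -0.02), mk_variant("c", 0.01)]
        dosages = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [0.5]})
        _, aligned = align_effect_alleles(vs, dosages)
        assert list(aligned.iloc[0]) == [1.0, 0.0, 0.5]

    def test_double_alignment_restores_dosages(self, cohort, variants):
        for v in variants[::2]:
            v.published_beta *= -1
        once_v, once_d = align_effect_alleles(variants, cohort.dosages)
        _, twice_d = align_effect_alleles(
            [v for v in variants], once_d
        )
        pd.testing.assert_frame_equal(twice_d, cohort.dosages)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            align_effect_alleles([mk_variant(beta=0.0)], pd.DataFrame({"v1": [1.0]}))


class TestScore:
    def test_hand_sums(self):
        vs = [mk_variant(x) for x in ("a", "b", "c")]
        dosages = pd.DataFrame({"a": [2.0, 0.0], "b": [1.0, 0.0], "c": [0.5, 0.0]})
        s = compute_allele_score(dosages, vs)
        assert list(s.values) == [3.5, 0.0]

    def test_single_variant(self):
        s = compute_allele_score(pd.DataFrame({"a": [2.0]}), [mk_variant("a")])
        assert s.values[0] == 2.0

    def test_flagged_variants_excluded(self):
        vs = [mk_variant("a"), mk_variant("b")]
        vs[1].qc_flags.add("chd_ld")
        s = compute_allele_score(pd.DataFrame({"a": [1.0], "b": [2.0]}), vs)
        assert s.variant_ids == ["a"] and s.values[0] == 1.0

    def test_empty_retained_set_rejected(self):
        v = mk_variant("a")
        v.qc_flags.add("chd_ld")
        with pytest.raises(ValueError):
            compute_allele_score(pd.DataFrame({"a": [1.0]}), [v])

    def test_missing_dosages_mean_imputed(self):
        dosages = pd.DataFrame({"a": [0.0, 2.0, np.nan]})
        s = compute_allele_score(dosages, [mk_variant("a")])
        assert s.values[2] == pytest.approx(1.0)  # 2 x within-cohort EAF

    def test_score_bounds_on_simulated_cohort(self, score):
        assert np.all(score.values >= 0)
        assert np.all(score.values <= 2 * len(score.variant_ids))

    def test_weighted_option(self):
        vs = [mk_variant("a", beta=0.1), mk_variant("b", beta=0.2)]
        s = compute_allele_score(
            pd.DataFrame({"a": [1.0], "b": [2.0]}), vs, weighted=True
        )
        assert s.values[0] == pytest.approx(0.1 + 0.4)


class TestRescale:
    def test_definition(self):
        s = AlleleScore(values=np.array([10.0, 20.0, 30.0]), variant_ids=list("abcdefghijklmnop"))
        r = rescale_score(s)
        assert r.divisor == 10.0
        assert r.values[-1] == pytest.approx(3.0)
        assert np.ptp(r.values) == pytest.approx(2.0)

    def test_single_variant_span_unchanged(self):
        s = AlleleScore(values=np.array([0.0, 1.0, 2.0]), variant_ids=["a"])
        r = rescale_score(s)
        assert r.divisor == 1.0
        assert np.allclose(r.values, s.values)

    def test_constant_scores_rejected(self):
        s = AlleleScore(values=np.array([1.0, 1.0]), variant_ids=["a"])
        with pytest.raises(ValueError):
            rescale_score(s)


class TestScoreRiskFactorCheck:
    def test_threshold_and_null_panel(self, config):
        cohorts = {}
        scores = {}
        for i in range(2):
            c = simulate_cohort(config, i)
            cohorts[c.label] = c
            vs = panel_to_variants(variant_panel(config))
            scores[c.label] = compute_allele_score(c.dosages, vs)
        table = score_risk_factor_check(scores, cohorts)
        assert table.attrs["threshold"] == pytest.approx(0.05 / 6)
        assert round(table.attrs["threshold"], 3) == 0.008
        assert set(table["trait"]) == {
            "bmi", "ldl", "hdl", "hypertension", "diabetes", "smoking"
        }
        # variants are generated independent of risk factors: nothing flagged
        assert not table["significant"].any()

    def test_planted_bmi_correlation_detected(self):
        cfg = SimConfig(n_individuals=10_000, seed=17)
        c = simulate_risk_factor_correlated_variant(cfg, 0.3)
        vs = panel_to_variants(variant_panel(cfg))
        score = compute_allele_score(c.dosages, [vs[0]])  # the coupled variant
        table = score_risk_factor_check({"c": score}, {"c": c})
        bmi_p = float(table.loc[table["trait"] == "bmi", "p"].iloc[0])
        assert bmi_p < 0.008
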