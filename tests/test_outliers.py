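import numpy as np
import pandas as pd
import pytest

from carekit import (
    CareValidationError,
    CareConfig,
    CareModel,
    SimulationConfig,
    compute_similarity,
    simulate_compendium,
    tukey_threshold,
)
from carekit.outliers import (
    CohortSpec,
    build_cohorts,
    call_outliers,
    neighbor_label_concordance,
    pan_disease_aggregate,
    usable_pan_disease_cohorts,
)
from carekit.similarity import pairwise_rho_matrix
from conftest import make_compendium, make_focus


def quantile_oracle(values, q):
    s = sorted(values)
    pos = q * (len(s) - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    return s[lo] + frac * (s[lo + 1] - s[lo]) if lo + 1 < len(s) else s[lo]


class TestTukeyThreshold:
    def test_hand_oracle_one_to_eight(self):
        q25, q75, iqr, thr = tukey_threshold([1, 2, 3, 4, 5, 6, 7, 8])
        assert q25 == pytest.approx(2.75)
        assert q75 == pytest.approx(6.25)
        assert iqr == pytest.approx(3.5)
        assert thr == pytest.approx(11.5)

    def test_constant_vector_threshold_is_the_constant(self):
        _, _, iqr, thr = tukey_threshold([4.2] * 25)
        assert iqr == 0.0 and thr == 4.2

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.random(31) * 10
        ref = tukey_threshold(v)
        assert tukey_threshold(rng.permutation(v)) == pytest.approx(ref)

    def test_random_vectors_match_sort_interpolate_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            v = rng.random(rng.integers(4, 60)) * rng.uniform(1, 20)
            q25, q75, iqr, thr = tukey_threshold(v)
            oq25 = quantile_oracle(v, 0.25)
            oq75 = quantile_oracle(v, 0.75)
            assert q25 == pytest.approx(oq25, abs=1e-12)
            assert q75 == pytest.approx(oq75, abs=1e-12)
            assert thr == pytest.approx(oq75 + 1.5 * (oq75 - oq25), abs=1e-12)


class TestCallOutliers:
    def make_single_gene_setup(self, cohort_vals, focus_val):
        n = len(cohort_vals)
        vals = np.vstack([cohort_vals, np.linspace(1, 2, n)])
        comp = make_compendium(vals, ["d"] * n)
        focus = make_focus([focus_val, 1.5], comp, "d")
        cohort = CohortSpec("same_diagnosis", list(comp.samples), True)
        return comp, focus, cohort

    def test_focus_above_threshold_is_outlier(self):
        comp, focus, cohort = self.make_single_gene_setup(
            [1, 2, 3, 4, 5, 6, 7, 8], 12.0
        )
        calls = call_outliers(focus, cohort, comp, comp.genes)
        row = calls.set_index("gene").loc["G0000"]
        assert row["threshold"] == pytest.approx(11.5)
        assert bool(row["is_outlier"])

    def test_focus_equal_to_threshold_is_not_outlier(self):
        comp, focus, cohort = self.make_single_gene_setup(
            [1, 2, 3, 4, 5, 6, 7, 8], 11.5
        )
        calls = call_outliers(focus, cohort, comp, comp.genes)
        assert not bool(calls.set_index("gene").loc["G0000", "is_outlier"])

    def test_expression_floor_suppresses_low_expression_calls(self):
        comp, focus, cohort = self.make_single_gene_setup([0.0] * 10, 0.5)
        calls = call_outliers(focus, cohort, comp, comp.genes,
                              expression_floor=1.0)
        assert not bool(calls.set_index("gene").loc["G0000", "is_outlier"])
        calls = call_outliers(focus, cohort, comp, comp.genes,
                              expression_floor=0.0)
        assert bool(calls.set_index("gene").loc["G0000", "is_outlier"])

    def test_unusable_cohort_rejected(self):
        comp, focus, _ = self.make_single_gene_setup([1.0] * 5, 2.0)
        bad = CohortSpec("first_degree", list(comp.samples), False, "too small")
        with pytest.raises(CareValidationError, match="not usable"):
            call_outliers(focus, bad, comp, comp.genes)

    def test_monotonicity_raising_focus_never_unflags(self):
        rng = np.random.default_rng(2)
        comp = make_compendium(rng.random((50, 30)) * 8, ["d"] * 30)
        focus_lo = make_focus(rng.random(50) * 8, comp, "d")
        cohort = CohortSpec("same_diagnosis", list(comp.samples), True)
        lo = call_outliers(focus_lo, cohort, comp, comp.genes)
        focus_hi = make_focus(focus_lo.expression.to_numpy() + 1.0, comp, "d")
        hi = call_outliers(focus_hi, cohort, comp, comp.genes)
        assert (hi["is_outlier"] | ~lo["is_outlier"]).all()

    def test_pan_cancer_calls_equal_brute_force_scan(self):
        """Full-pipeline pan-cancer outlier set vs an independent from-scratch
        scan (sort, interpolate, compare) over the same universe."""
        comp, focus, _ = simulate_compendium(
            SimulationConfig(n_diseases=4, samples_per_disease=[20] * 4,
                             n_genes=400, outlier_genes=15, seed=6)
        )
        res = CareModel(comp, focus, config=CareConfig(seed=6)).fit()
        floor = res.config.expression_floor
        expected = []
        for g in res.filtered.retained:
            vals = comp.values.loc[g].tolist()
            q25, q75 = quantile_oracle(vals, 0.25), quantile_oracle(vals, 0.75)
            thr = q75 + 1.5 * (q75 - q25)
            fx = focus.expression.loc[g]
            if fx > thr and fx >= floor:
                expected.append(g)
        assert res.pan_cancer_outliers == expected


class TestCohortAssembly:
    def test_clean_clusters_give_four_usable_cohorts(self):
        """A tight focus cluster plus a looser sibling disease yields four
        usable, mutually distinct personalized cohorts and no fallback."""
        rng = np.random.default_rng(31)
        n_genes = 150
        prof_a = rng.normal(5, 2, n_genes).clip(min=0)
        cols, dis, names = [], [], []
        for i in range(25):  # tight focus disease
            cols.append(np.clip(prof_a + rng.normal(0, 0.05, n_genes), 0, None))
            dis.append("disease_a")
            names.append(f"a{i:02d}")
        for i in range(25):  # sibling disease straddling the threshold
            cols.append(np.clip(prof_a + rng.normal(0, 0.4, n_genes), 0, None))
            dis.append("disease_b")
            names.append(f"b{i:02d}")
        for d in range(3):  # unrelated background diseases
            prof = rng.normal(5, 2, n_genes).clip(min=0)
            for i in range(25):
                cols.append(np.clip(prof + rng.normal(0, 0.6, n_genes), 0, None))
                dis.append(f"disease_{chr(99 + d)}")
                names.append(f"{chr(99 + d)}{i:02d}")
        comp = make_compendium(np.column_stack(cols), dis, samples=names)
        focus = make_focus(
            np.clip(prof_a + rng.normal(0, 0.05, n_genes), 0, None),
            comp, "disease_a",
        )
        sim = compute_similarity(focus, comp)
        cohorts = build_cohorts(focus, comp, sim, min_cohort_size=20)
        by_kind = {c.kind: c for c in cohorts}
        assert "merged_pan_disease" not in by_kind
        assert all(c.usable for c in cohorts)
        assert set(by_kind["first_degree"].members) <= set(
            by_kind["first_and_second_degree"].members
        )
        assert focus.sample_id not in set().union(
            *(set(c.members) for c in cohorts)
        )

    def test_case_study_topology_emits_single_merged_cohort(self):
        """Focus diagnosis carried by only 3 compendium samples which are also
        the only first-degree neighbors: the four personalized cohorts
        collapse and one merged cohort (their deduplicated union) results."""
        comp, focus, truth = simulate_compendium(
            SimulationConfig(
                n_diseases=5,
                samples_per_disease=[3, 40, 40, 40, 40],
                n_genes=600,
                disease_effect_sd=2.0,
                seed=10,
            )
        )
        sim = compute_similarity(focus, comp)
        cohorts = build_cohorts(focus, comp, sim, min_cohort_size=20)
        merged = [c for c in cohorts if c.kind == "merged_pan_disease"]
        assert len(merged) == 1
        union = set().union(*(set(c.members) for c in cohorts[:4]))
        assert set(merged[0].members) == union
        assert len(merged[0]) == len(union)
        usable = usable_pan_disease_cohorts(cohorts)
        assert [c.kind for c in usable] == ["merged_pan_disease"]

    def test_everything_unusable_degrades_gracefully(self):
        comp, focus, _ = simulate_compendium(
            SimulationConfig(n_diseases=2, samples_per_disease=[5, 5],
                             n_genes=100, seed=1)
        )
        sim = compute_similarity(focus, comp)
        cohorts = build_cohorts(focus, comp, sim, min_cohort_size=1000)
        assert all(not c.usable for c in cohorts)
        assert usable_pan_disease_cohorts(cohorts) == []
        with pytest.warns(UserWarning):
            agg = pan_disease_aggregate({})
        assert agg.empty


class TestPanDiseaseAggregation:
    def make_calls(self, flags_by_cohort):
        out = {}
        for kind, flags in flags_by_cohort.items():
            out[kind] = pd.DataFrame(
                {"gene": [f"G{i}" for i in range(len(flags))],
                 "is_outlier": flags}
            )
        return out

    def test_two_of_four_flags(self):
        calls = self.make_calls(
            {k: [v] for k, v in zip("abcd", [True, True, False, False])}
        )
        agg = pan_disease_aggregate(calls)
        assert bool(agg.loc[0, "is_pan_disease_outlier"])
        assert agg.loc[0, "n_cohorts_outlier"] == 2

    def test_one_of_four_does_not_flag(self):
        calls = self.make_calls(
            {k: [v] for k, v in zip("abcd", [True, False, False, False])}
        )
        agg = pan_disease_aggregate(calls)
        assert not bool(agg.loc[0, "is_pan_disease_outlier"])

    def test_single_merged_cohort_uses_one_of_one_rule(self):
        calls = self.make_calls({"merged_pan_disease": [True, False]})
        agg = pan_disease_aggregate(calls).set_index("gene")
        assert bool(agg.loc["G0", "is_pan_disease_outlier"])
        assert not bool(agg.loc["G1", "is_pan_disease_outlier"])
        assert (agg["n_cohorts_usable"] == 1).all()


class TestNullBehavior:
    def test_null_flag_rate_is_stable_across_seeds(self):
        """With no planted signal the per-gene flag rate reflects only the
        Tukey rule on the simulated null and should not inflate across
        seeds: planted-gene 'recall' stays within 3 binomial SDs of the
        genome-wide flag rate."""
        rates, planted_rates = [], []
        for seed in range(5):
            comp, focus, truth = simulate_compendium(
                SimulationConfig(n_diseases=3, samples_per_disease=[25] * 3,
                                 n_genes=600, outlier_genes=30,
                                 outlier_delta=0.0, seed=seed)
            )
            res = CareModel(comp, focus, config=CareConfig(seed=seed)).fit()
            flagged = set(res.outlier_genes)
            rates.append(len(flagged) / comp.n_genes)
            planted_rates.append(
                len(flagged & set(truth.planted_outlier_genes))
                / len(truth.planted_outlier_genes)
            )
        overall = np.mean(rates)
        n_planted_total = 30 * 5
        sd = np.sqrt(max(overall * (1 - overall), 1e-9) / n_planted_total)
        assert abs(np.mean(planted_rates) - overall) <= 3 * sd + 1e-9


class TestConcordanceFlagger:
    def test_separated_clusters_produce_no_flags(self, clustered_compendium):
        comp, _ = clustered_compendium
        pw = pairwise_rho_matrix(comp)
        flags = neighbor_label_concordance(comp, pw, k=5)
        assert not flags["flagged"].any()

    def test_mislabelled_sample_is_flagged(self, clustered_compendium):
        comp, _ = clustered_compendium
        meta = comp.metadata.copy()
        victim = comp.samples[0]  # truly in disease_a's cluster
        meta.loc[victim, "disease"] = "disease_b"
        relabelled = type(comp)(comp.values, meta).validate()
        pw = pairwise_rho_matrix(relabelled)
        flags = neighbor_label_concordance(relabelled, pw, k=5).set_index(
            "sample_id"
        )
        assert bool(flags.loc[victim, "flagged"])

    def test_rare_disease_samples_are_exempt(self, clustered_compendium):
        comp, _ = clustered_compendium
        meta = comp.metadata.copy()
        rare = comp.samples[-1]
        meta.loc[rare, "disease"] = "ultra_rare"
        relabelled = type(comp)(comp.values, meta).validate()
        pw = pairwise_rho_matrix(relabelled)
        flags = neighbor_label_concordance(relabelled, pw, k=5).set_index(
            "sample_id"
        )
        assert bool(flags.loc[rare, "exempt"])
        assert not bool(flags.loc[rare, "flagged"])
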