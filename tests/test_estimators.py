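"""Pedigree-based and rarefaction population estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedpop import (
    CreInputs,
    CreelRosenblattModel,
    RarefactionModel,
    accumulation_counts,
    cre_estimate,
    estimate_unsampled,
    fit_saturation,
    infer_by_ratio,
    mortality_correct,
    pedigree_from_assignments,
    percentage_increase,
    rarefaction_estimate,
    screen_fullsib_dyads,
)
from pedpop.relatedness import RelatednessMatrix


def rel_matrix(ids, pairs):
    """Build a RelatednessMatrix with given r for listed pairs, 0 elsewhere."""
    n = len(ids)
    r = np.zeros((n, n))
    np.fill_diagonal(r, np.nan)
    idx = {i: k for k, i in enumerate(ids)}
    for a, b, v in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return RelatednessMatrix(ids=ids, r=r, n_informative=np.full((n, n), 85))


class TestFullSibScreen:
    def test_full_sibs_collapse_to_one_parent(self):
        dyads = [("o1", "dam1", "F"), ("o2", "dam1", "F")]
        rel = rel_matrix(["o1", "o2"], [("o1", "o2", 0.5)])
        comps, sires, dams, remaining = screen_fullsib_dyads(dyads, rel, 0.375)
        assert sires == 1 and dams == 0
        assert comps == [["o1", "o2"]]
        assert remaining == []

    def test_half_sibs_left_alone(self):
        dyads = [("o1", "dam1", "F"), ("o2", "dam1", "F")]
        rel = rel_matrix(["o1", "o2"], [("o1", "o2", 0.25)])
        comps, sires, dams, remaining = screen_fullsib_dyads(dyads, rel, 0.375)
        assert (sires, dams) == (0, 0)
        assert remaining == dyads

    def test_known_sire_group_infers_dam(self):
        dyads = [("o1", "sire1", "M"), ("o2", "sire1", "M"), ("o3", "dam1", "F")]
        rel = rel_matrix(["o1", "o2", "o3"], [("o1", "o2", 0.55)])
        comps, sires, dams, remaining = screen_fullsib_dyads(dyads, rel, 0.375)
        assert (sires, dams) == (0, 1)
        assert remaining == [("o3", "dam1", "F")]

    def test_no_relatedness_skips_screen(self):
        dyads = [("o1", "dam1", "F"), ("o2", "dam1", "F")]
        comps, sires, dams, remaining = screen_fullsib_dyads(dyads, None, 0.375)
        assert (sires, dams) == (0, 0) and remaining == dyads


class TestRatioInference:
    def test_unit_ratio_identity(self):
        dyads = [(f"o{i}", f"d{i}", "F") for i in range(10)] + [
            (f"p{i}", f"s{i}", "M") for i in range(10)
        ]
        assert infer_by_ratio(dyads, 1.0) == (10, 10)

    def test_ratio_scales_counterparts(self):
        dyads = [(f"o{i}", f"d{i}", "F") for i in range(6)] + [
            (f"p{i}", f"s{i}", "M") for i in range(4)
        ]
        # x = round(6 / 1.5) = 4 sires, y = round(4 * 1.5) = 6 dams
        assert infer_by_ratio(dyads, 1.5) == (4, 6)

    def test_distinct_parents_counted_once(self):
        dyads = [("o1", "d1", "F"), ("o2", "d1", "F"), ("o3", "d2", "F")]
        assert infer_by_ratio(dyads, 1.0) == (2, 0)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            infer_by_ratio([], 0.0)


class TestMortalityCorrection:
    def test_printed_worked_examples(self):
        assert mortality_correct(58, 69) == 115
        assert mortality_correct(45, 48) == 85

    def test_zero_counts(self):
        assert mortality_correct(0, 0) == 0

    def test_zero_mortality_identity(self):
        assert mortality_correct(37, 52, m_m=0.0, m_f=0.0) == 89

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mortality_correct(-1, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s1=st.integers(0, 300), d1=st.integers(0, 300),
        ds=st.integers(0, 50), dd=st.integers(0, 50),
    )
    def test_monotone_in_both_counts(self, s1, d1, ds, dd):
        assert mortality_correct(s1 + ds, d1 + dd) >= mortality_correct(s1, d1)


class TestUnsampledEstimate:
    def test_nonbreeder_fraction_worked_example(self):
        assert estimate_unsampled(115, 433, 159, "nonbreeder_fraction") == 73

    def test_all_breeders_gives_zero(self):
        assert estimate_unsampled(50, 100, 100, "nonbreeder_fraction") == 0
        assert estimate_unsampled(50, 100, 100, "breeder_ratio") == 0

    def test_zero_inferred_gives_zero(self):
        assert estimate_unsampled(0, 100, 10, "breeder_ratio") == 0

    def test_none_strategy(self):
        assert estimate_unsampled(115, 433, 159, "none") == 0

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            estimate_unsampled(1, 10, 5, "bogus")


class TestCreEstimate:
    def make_inputs(self):
        # 4 dyads: 2 dams with missing sires (one shared by full sibs),
        # 2 sires with missing dams
        dyads = [
            ("o1", "dam1", "F"),
            ("o2", "dam1", "F"),
            ("o3", "sire1", "M"),
            ("o4", "sire2", "M"),
        ]
        rel = rel_matrix(["o1", "o2", "o3", "o4"], [("o1", "o2", 0.5)])
        return CreInputs(
            n_s=40, b_s=10, dyads=dyads, rho=1.0, relatedness=rel,
            m_f=0.0, m_m=0.0,
        )

    def test_pipeline_composition(self):
        res = cre_estimate(self.make_inputs())
        # FS screen: one inferred sire consumes o1/o2; ratio: 0 dams left
        # with missing sires, 2 sires missing dams -> 0 sires + 2 dams
        assert res.fs_inferred_sires == 1 and res.fs_inferred_dams == 0
        assert res.ratio_inferred_sires == 0 and res.ratio_inferred_dams == 2
        assert res.n_in == 3
        assert res.n_un == estimate_unsampled(3, 40, 10)
        assert res.n_hat == 40 + res.n_in + res.n_un
        assert res.lower_bound == 40
        assert res.upper_bound == 40 + 4 + estimate_unsampled(4, 40, 10)
        assert res.lower_bound <= res.n_hat <= res.upper_bound

    def test_trivial_no_inference(self):
        inputs = CreInputs(n_s=25, b_s=5, dyads=[], rho=1.0)
        res = cre_estimate(inputs)
        assert res.n_in == 0 and res.n_un == 0 and res.n_hat == 25

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            CreInputs(n_s=10, b_s=11, dyads=[], rho=1.0)
        with pytest.raises(ValueError):
            CreInputs(n_s=10, b_s=5, dyads=[], rho=0.0)

    def test_model_front_end(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "offspring_id": ["a", "b", "c"],
                "dam_id": ["m1", "m2", None],
                "sire_id": [None, None, "f1"],
            }
        )
        ped = pedigree_from_assignments(df)
        res = CreelRosenblattModel(ped).fit()
        assert res.n_s == 3
        assert res.rho == pytest.approx(2.0)
        assert "Population estimate" in res.summary()

    def test_percentage_increase(self):
        assert percentage_increase(630, 433) == 45
        assert percentage_increase(408, 265) == 54


class TestAccumulation:
    def test_repeats_flat(self):
        assert accumulation_counts(list("AAA")).tolist() == [1, 1, 1]

    def test_mixed_sequence(self):
        assert accumulation_counts(list("ABAC")).tolist() == [1, 2, 2, 3]

    def test_all_distinct_identity_line(self):
        assert accumulation_counts(range(7)).tolist() == list(range(1, 8))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accumulation_counts([])


class TestSaturationFit:
    def test_exact_recovery(self):
        xs = np.arange(1.0, 40.0)
        ys = 100.0 * xs / (50.0 + xs)
        fit = fit_saturation(xs, ys)
        assert fit.converged and not fit.degenerate
        assert fit.a == pytest.approx(100.0, abs=1e-6)
        assert fit.b == pytest.approx(50.0, abs=1e-6)

    def test_grid_search_oracle_five_points(self):
        xs = np.array([2.0, 5.0, 9.0, 14.0, 20.0])
        rng = np.random.default_rng(8)
        ys = 30.0 * xs / (12.0 + xs) + rng.normal(0, 0.15, 5)

        def sse(a, b):
            return float(np.sum((a * xs / (b + xs) - ys) ** 2))

        a_lo, a_hi = ys.max(), 3 * ys.max()
        b_lo, b_hi = 1e-3, 2 * xs.max()
        best = None
        for _ in range(6):  # successive grid refinement well below 1e-3
            a_grid = np.linspace(a_lo, a_hi, 61)
            b_grid = np.linspace(b_lo, b_hi, 61)
            vals = [(sse(a, b), a, b) for a in a_grid for b in b_grid]
            best = min(vals)
            da, db = a_grid[1] - a_grid[0], b_grid[1] - b_grid[0]
            a_lo, a_hi = best[1] - 3 * da, best[1] + 3 * da
            b_lo, b_hi = max(1e-6, best[2] - 3 * db), best[2] + 3 * db
        fit = fit_saturation(xs, ys)
        assert fit.converged
        assert fit.a == pytest.approx(best[1], abs=1e-3)
        assert fit.b == pytest.approx(best[2], abs=1e-3)

    def test_constant_counts_degenerate(self):
        fit = fit_saturation([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.degenerate and not fit.converged

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_saturation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_saturation([1, 1, 2], [1, 2, 3])


class TestRarefaction:
    def test_high_coverage_overestimates(self, rng):
        seq = rng.integers(0, 100, size=1000)  # 100 equally catchable animals
        fit = rarefaction_estimate(seq, n_iter=40, seed=1)
        assert fit.n_unique == 100
        assert fit.mean_a >= 100.0

    def test_estimate_at_least_observed_across_seeds(self, rng):
        failures = 0
        for seed in range(8):
            seq = rng.integers(0, 60, size=250)
            fit = rarefaction_estimate(seq, n_iter=20, seed=seed)
            if fit.mean_a < fit.n_unique:
                failures += 1
        assert failures <= 1  # holds in >= 95% of runs

    def test_every_individual_once_degenerate(self):
        with pytest.raises(RuntimeError):
            rarefaction_estimate(list(range(40)), n_iter=10, seed=0)

    def test_seed_determinism(self, rng):
        seq = rng.integers(0, 50, size=300).tolist()
        a = RarefactionModel(seq).fit(n_iter=15, seed=9)
        b = RarefactionModel(seq).fit(n_iter=15, seed=9)
        assert a.mean_a == b.mean_a
        assert np.array_equal(a.asymptotes, b.asymptotes)

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_estimate(["A", "A", "A"], n_iter=5, seed=0)
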