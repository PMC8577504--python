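"""MAF computation, log2-ratio concordance filter, threshold optimization."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarearray.concordance import (
    DEFAULT_T_LOWER,
    DEFAULT_T_UPPER,
    compute_array_maf,
    filter_by_concordance,
    optimize_thresholds,
)
from rarearray.types import AA, AB, BB, NOCALL

from test_consolidate import matrix_from_codes


class TestComputeArrayMaf:
    def test_single_het_allele_counting(self):
        n = 43_433
        codes = np.full((1, n), AA, dtype=np.int8)
        codes[0, 0] = AB
        maf = compute_array_maf(matrix_from_codes(codes))
        assert maf["array_maf"].iloc[0] == pytest.approx(1 / (2 * n))

    def test_all_nocall_flagged_undefined(self):
        maf = compute_array_maf(matrix_from_codes([[NOCALL, NOCALL]]))
        assert not maf["defined"].iloc[0]
        assert np.isnan(maf["array_maf"].iloc[0])

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([AA, AB, BB, NOCALL], size=(20, 60), p=[0.8, 0.1, 0.05, 0.05])
        maf = compute_array_maf(matrix_from_codes(codes))
        for i in range(codes.shape[0]):
            b_alleles = called = 0
            for c in codes[i]:
                if c == NOCALL:
                    continue
                called += 1
                b_alleles += {AA: 0, AB: 1, BB: 2}[c]
            if called == 0:
                assert not maf["defined"].iloc[i]
            else:
                assert maf["array_maf"].iloc[i] == pytest.approx(b_alleles / (2 * called))


def maf_tables(pairs: dict[str, tuple[float, float]]):
    array = pd.Series({k: v[0] for k, v in pairs.items()}, name="array_maf")
    ref = pd.Series({k: v[1] for k, v in pairs.items()}, name="ref_maf")
    return array, ref


class TestFilterByConcordance:
    def test_validated_variant_examples_retained(self):
        """The two experimentally validated variants' array/sequencing MAF
        pairs fall inside the default thresholds."""
        array, ref = maf_tables(
            {
                "rs749038326": (0.000842, 0.000461),
                "rs730882109": (0.00192, 0.000691),
            }
        )
        results, _ = filter_by_concordance(array, ref)
        r1 = results.loc["rs749038326", "log2_ratio"]
        r2 = results.loc["rs730882109", "log2_ratio"]
        assert r1 == pytest.approx(math.log2(0.0842 / 0.0461), abs=1e-9)
        assert r1 == pytest.approx(0.87, abs=0.01)
        assert r2 == pytest.approx(1.47, abs=0.01)
        assert (results["verdict"] == "retained").all()

    def test_identical_mafs_retained_at_zero(self):
        array, ref = maf_tables({"v": (0.004, 0.004)})
        results, _ = filter_by_concordance(array, ref)
        assert results["log2_ratio"].iloc[0] == 0.0
        assert results["verdict"].iloc[0] == "retained"

    def test_eightfold_excess_excluded(self):
        array, ref = maf_tables({"v": (0.008, 0.001)})
        results, _ = filter_by_concordance(array, ref)
        assert results["log2_ratio"].iloc[0] == pytest.approx(3.0)
        assert results["verdict"].iloc[0] == "excluded"

    def test_zero_maf_is_indeterminate(self):
        array, ref = maf_tables({"a": (0.0, 0.001), "b": (0.001, 0.0), "c": (0.001, 0.001)})
        results, diag = filter_by_concordance(array, ref)
        assert results.loc["a", "verdict"] == "indeterminate"
        assert results.loc["b", "verdict"] == "indeterminate"
        assert results.loc["c", "verdict"] == "retained"
        assert diag.n_indeterminate == 2

    def test_empty_intersection_rejected(self):
        array = pd.Series({"a": 0.001})
        ref = pd.Series({"b": 0.001})
        with pytest.raises(ValueError, match="no variants"):
            filter_by_concordance(array, ref)

    def test_filter_monotone_in_interval(self):
        rng = np.random.default_rng(5)
        ref = pd.Series(rng.uniform(1e-4, 1e-2, 40), index=[f"v{i}" for i in range(40)])
        array = ref * np.exp2(rng.normal(0, 1.2, 40))
        narrow, _ = filter_by_concordance(array, ref, 1.0, -1.0)
        wide, _ = filter_by_concordance(array, ref, 2.0, -2.5)
        retained_narrow = set(narrow.index[narrow["verdict"] == "retained"])
        retained_wide = set(wide.index[wide["verdict"] == "retained"])
        assert retained_narrow <= retained_wide

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(1e-5, 0.01, allow_nan=False),
        f=st.floats(1e-5, 0.01, allow_nan=False),
    )
    def test_log_ratio_antisymmetric(self, a, f):
        array, ref = maf_tables({"v": (a, f)})
        fwd, _ = filter_by_concordance(array, ref, 10, -10)
        rev, _ = filter_by_concordance(ref, array, 10, -10)
        assert fwd["log2_ratio"].iloc[0] == pytest.approx(
            -rev["log2_ratio"].iloc[0], abs=1e-9
        )

    def test_r_squared_matches_closed_form(self):
        rng = np.random.default_rng(11)
        ref = pd.Series(rng.uniform(1e-4, 1e-2, 50), index=[f"v{i}" for i in range(50)])
        array = ref * np.exp2(rng.normal(0, 0.3, 50))
        _, diag = filter_by_concordance(array, ref)
        x = np.log2(ref.to_numpy())
        y = np.log2(array.to_numpy())
        # closed-form least squares on the retained set (all retained here)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        ss_res = ((y - slope * x - intercept) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert diag.slope == pytest.approx(slope, abs=1e-10)
        assert diag.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert 0.0 <= diag.r_squared <= 1.0


class TestCrossHybScenario:
    def test_cross_hyb_probesets_excluded(self):
        """Planted cross-hybridizing probesets (8x contaminated MAF) are
        excluded; clean probesets with sampling noise only are retained."""
        from rarearray.concordance import compute_array_maf
        from rarearray.synthdata import simulate_reference_maf
        from conftest import make_config, run_calling

        cfg = make_config(
            n_samples=2000,
            n_probesets=12,
            seed=71,
            n_cross_hyb=3,
            contamination_factor=10,
            maf_range=(0.004, 0.009),
        )
        exp = run_calling(cfg)
        ref = simulate_reference_maf(exp.truth, 5000, seed=72).set_index("variant_id")[
            "ref_maf"
        ]
        results, _ = filter_by_concordance(compute_array_maf(exp.base), ref)
        cross = set(exp.truth.cross_hyb_probesets)
        for variant, row in results.iterrows():
            if variant in cross:
                assert row["verdict"] == "excluded", variant
            else:
                assert row["verdict"] == "retained", variant

    def test_exclusion_rate_decreases_with_maf(self):
        """Sampling noise alone excludes more probesets at low MAF than at
        high MAF (directional analogue of the published bin rates)."""
        rng = np.random.default_rng(9)
        n_per_bin = 300
        rates = []
        for maf in (2e-4, 5e-3):
            ids = [f"m{maf}_{i}" for i in range(n_per_bin)]
            true = pd.Series(maf, index=ids)
            n_array, n_ref = 4000, 3370
            array = pd.Series(
                rng.binomial(2 * n_array, true) / (2 * n_array), index=ids
            )
            ref = pd.Series(rng.binomial(2 * n_ref, true) / (2 * n_ref), index=ids)
            results, _ = filter_by_concordance(array, ref)
            determinate = results["verdict"] != "indeterminate"
            rates.append(
                (results["verdict"] == "excluded").sum() / max(determinate.sum(), 1)
            )
        assert rates[0] > rates[1]


class TestOptimizeThresholds:
    def test_no_outliers_picks_widest_pair(self):
        rng = np.random.default_rng(13)
        ref = pd.Series(rng.uniform(1e-3, 1e-2, 30), index=[f"v{i}" for i in range(30)])
        array = ref * np.exp2(rng.normal(0, 0.2, 30))
        t_up, t_lo, surface = optimize_thresholds(
            array, ref, upper_grid=[1.0, 2.0, 3.0], lower_grid=[-3.0, -2.0, -1.0]
        )
        assert (t_up, t_lo) == (3.0, -3.0)

    def test_planted_outliers_excluded_by_optimum(self):
        rng = np.random.default_rng(17)
        ids = [f"v{i}" for i in range(40)]
        ref = pd.Series(rng.uniform(1e-3, 1e-2, 40), index=ids)
        array = ref * np.exp2(rng.normal(0, 0.15, 40))
        # plant discordant probesets at log2 ratios +-5
        array.iloc[0] = ref.iloc[0] * 2**5
        array.iloc[1] = ref.iloc[1] * 2**-5
        t_up, t_lo, _ = optimize_thresholds(
            array, ref, upper_grid=[2.0, 6.0], lower_grid=[-6.0, -2.0]
        )
        assert t_up < 5 and t_lo > -5
        results, _ = filter_by_concordance(array, ref, t_up, t_lo)
        assert results.loc["v0", "verdict"] == "excluded"
        assert results.loc["v1", "verdict"] == "excluded"

    def test_surface_r2_matches_direct_filter_call(self):
        rng = np.random.default_rng(19)
        ref = pd.Series(rng.uniform(1e-3, 1e-2, 25), index=[f"v{i}" for i in range(25)])
        array = ref * np.exp2(rng.normal(0, 0.4, 25))
        _, _, surface = optimize_thresholds(
            array, ref, upper_grid=[1.0, 2.0], lower_grid=[-2.0]
        )
        for row in surface.itertuples(index=False):
            _, diag = filter_by_concordance(array, ref, row.t_upper, row.t_lower)
            assert diag.r_squared == pytest.approx(row.r_squared, nan_ok=True)


def test_default_thresholds_are_published_values():
    assert DEFAULT_T_UPPER == 1.72
    assert DEFAULT_T_LOWER == -2.0
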