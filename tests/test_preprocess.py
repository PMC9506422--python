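import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sclc_subtyper import preprocess as pp, synthetic_data as sd
from sclc_subtyper.core import IntensityMatrix


def linear_matrix(values, **kw):
    return IntensityMatrix(values=pd.DataFrame(values, **kw), scale="linear")


class TestLog2MedianNormalize:
    def test_toy_2x2_medians_equal(self):
        m = linear_matrix([[4.0, 16.0], [16.0, 64.0]], index=["P1", "P2"], columns=["S1", "S2"])
        out = pp.log2_median_normalize(m)
        med = out.values.median(axis=0)
        assert med["S1"] == pytest.approx(med["S2"])
        assert out.scale == "log2"

    def test_scale_invariance(self):
        # column S1 sits entirely above the global median, so scaling it by 8
        # leaves the global median untouched and the log2 shift of 3 is
        # removed exactly
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            np.column_stack(
                [rng.lognormal(20, 0.5, 50)] + [rng.lognormal(12, 1, 50) for _ in range(4)]
            ),
            index=[f"P{i}" for i in range(50)],
            columns=["S1", "S2", "S3", "S4", "S5"],
        )
        m = IntensityMatrix(vals, scale="linear")
        scaled = vals.copy()
        scaled["S1"] *= 8.0
        out_ref = pp.log2_median_normalize(m)
        out_scaled = pp.log2_median_normalize(IntensityMatrix(scaled, scale="linear"))
        pd.testing.assert_frame_equal(out_ref.values, out_scaled.values)

    def test_column_at_global_median_unchanged(self):
        vals = pd.DataFrame(
            {"S1": [4.0, 8.0, 16.0], "S2": [4.0, 8.0, 16.0]}, index=["P1", "P2", "P3"]
        )
        out = pp.log2_median_normalize(IntensityMatrix(vals, scale="linear"))
        np.testing.assert_allclose(out.values["S1"], np.log2(vals["S1"]))

    def test_idempotence(self, small_dataset):
        m, _, _ = small_dataset
        once = pp.log2_median_normalize(m)
        again = once.with_values(np.exp2(once.values), scale="linear")
        twice = pp.log2_median_normalize(again)
        pd.testing.assert_frame_equal(once.values, twice.values, atol=1e-12, rtol=0)

    def test_nonpositive_rejected(self):
        m = linear_matrix([[1.0, -2.0]], index=["P1"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="P1.*S2"):
            pp.log2_median_normalize(m)

    def test_mask_unchanged(self, small_dataset):
        m, _, _ = small_dataset
        holed = sd.inject_missingness(m, 18.0, 1.0, seed=0)
        out = pp.log2_median_normalize(holed)
        pd.testing.assert_frame_equal(out.values.isna(), holed.values.isna())


class TestAggregateReplicates:
    @staticmethod
    def _ann(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "measurement_id", "cell_line", "subtype", "batch",
                "culture_type", "bio_rep", "tech_rep",
            ],
        )

    def test_median_then_mean(self):
        # tech repeats (1,3) -> 2; vials (2,4) -> mean 3
        ann = self._ann([
            ["m1", "CL1", "A", "B1", "adherent", "1", "1"],
            ["m2", "CL1", "A", "B1", "adherent", "1", "2"],
            ["m3", "CL1", "A", "B1", "adherent", "2", "1"],
        ])
        vals = pd.DataFrame({"m1": [1.0], "m2": [3.0], "m3": [4.0]}, index=["P1"])
        m = IntensityMatrix(vals, scale="log2", stage="normalized")
        out = pp.aggregate_replicates(m, ann)
        assert out.values.loc["P1", "CL1"] == pytest.approx(3.0)

    def test_single_measurement_identity(self):
        ann = self._ann([["m1", "CL1", "A", "B1", "adherent", "1", "1"]])
        vals = pd.DataFrame({"m1": [5.0, 7.0]}, index=["P1", "P2"])
        m = IntensityMatrix(vals, scale="log2", stage="normalized")
        out = pp.aggregate_replicates(m, ann)
        np.testing.assert_allclose(out.values["CL1"], [5.0, 7.0])

    def test_na_aware_mean(self):
        ann = self._ann([
            ["m1", "CL1", "A", "B1", "adherent", "1", "1"],
            ["m2", "CL1", "A", "B1", "adherent", "2", "1"],
        ])
        vals = pd.DataFrame({"m1": [2.0], "m2": [np.nan]}, index=["P1"])
        m = IntensityMatrix(vals, scale="log2", stage="normalized")
        out = pp.aggregate_replicates(m, ann)
        assert out.values.loc["P1", "CL1"] == pytest.approx(2.0)

    def test_all_missing_stays_missing(self):
        ann = self._ann([
            ["m1", "CL1", "A", "B1", "adherent", "1", "1"],
            ["m2", "CL1", "A", "B1", "adherent", "2", "1"],
        ])
        vals = pd.DataFrame({"m1": [np.nan], "m2": [np.nan]}, index=["P1"])
        m = IntensityMatrix(vals, scale="log2", stage="normalized")
        out = pp.aggregate_replicates(m, ann)
        assert np.isnan(out.values.loc["P1", "CL1"])

    def test_missing_annotation_columns_rejected(self):
        ann = pd.DataFrame({"measurement_id": ["m1"], "cell_line": ["CL1"]})
        vals = pd.DataFrame({"m1": [1.0]}, index=["P1"])
        m = IntensityMatrix(vals, scale="log2")
        with pytest.raises(ValueError, match="replicate column"):
            pp.vial_median(m, ann)


class TestFilterValid:
    def test_fraction_boundary_26_samples(self):
        cols = [f"S{i}" for i in range(26)]
        row_keep = [1.0] * 21 + [np.nan] * 5  # 21/26 = 0.8077 >= 0.8
        row_drop = [1.0] * 20 + [np.nan] * 6  # 20/26 = 0.7692 < 0.8
        vals = pd.DataFrame([row_keep, row_drop], index=["keep", "drop"], columns=cols)
        out = pp.filter_valid(IntensityMatrix(vals, scale="log2"), 0.8)
        assert list(out.values.index) == ["keep"]

    def test_fully_observed_kept_fully_missing_dropped(self):
        vals = pd.DataFrame(
            {"S1": [1.0, np.nan], "S2": [2.0, np.nan]}, index=["full", "empty"]
        )
        out = pp.filter_valid(IntensityMatrix(vals, scale="log2"), 0.5)
        assert list(out.values.index) == ["full"]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_min_frac(self, bad):
        vals = pd.DataFrame({"S1": [1.0]}, index=["P1"])
        with pytest.raises(ValueError):
            pp.filter_valid(IntensityMatrix(vals, scale="log2"), bad)


class TestCorrectBatch:
    @staticmethod
    def _ann(n1, n2):
        rows = [
            {"measurement_id": f"s{i}", "batch": "B1" if i < n1 else "B2"}
            for i in range(n1 + n2)
        ]
        return pd.DataFrame(rows)

    def test_pure_shift_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(20, 1, size=(30, 4))
        vals = np.hstack([base, base + 1.5])
        df = pd.DataFrame(vals, index=[f"P{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(8)])
        m = IntensityMatrix(df, scale="log2")
        out = pp.correct_batch(m, self._ann(4, 4))
        b1 = out.values.iloc[:, :4].mean(axis=1)
        b2 = out.values.iloc[:, 4:].mean(axis=1)
        np.testing.assert_allclose(b1, b2, atol=1e-10)
        # values equal the de-shifted originals (up to the common re-centring)
        np.testing.assert_allclose(
            out.values.iloc[:, :4].to_numpy(), base + 0.75, atol=1e-10
        )

    def test_single_batch_unchanged(self):
        df = pd.DataFrame({"s0": [1.0], "s1": [2.0]}, index=["P1"])
        ann = pd.DataFrame({"measurement_id": ["s0", "s1"], "batch": ["B1", "B1"]})
        out = pp.correct_batch(IntensityMatrix(df, scale="log2"), ann)
        pd.testing.assert_frame_equal(out.values, df)

    def test_protein_absent_from_batch_flagged(self):
        df = pd.DataFrame(
            {"s0": [1.0, 1.0], "s1": [2.0, 2.0], "s2": [np.nan, 3.0], "s3": [np.nan, 4.0]},
            index=["only_b1", "both"],
        )
        out = pp.correct_batch(IntensityMatrix(df, scale="log2"), self._ann(2, 2))
        assert "only_b1" in out.uncorrected
        pd.testing.assert_series_equal(out.values.loc["only_b1"], df.loc["only_b1"])

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame(
            {"s0": [1.0], "s1": [np.nan], "s2": [3.0], "s3": [4.0]}, index=["P1"]
        )
        out = pp.correct_batch(IntensityMatrix(df, scale="log2"), self._ann(2, 2))
        assert np.isnan(out.values.loc["P1", "s1"])

    def test_closed_form_ols_equivalence(self):
        # regression on a batch indicator == per-batch de-meaning + grand mean
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.normal(20, 1, size=(10, 6)),
            index=[f"P{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        ann = self._ann(3, 3)
        out = pp.correct_batch(IntensityMatrix(df, scale="log2"), ann)
        for i in range(10):
            y = df.iloc[i].to_numpy()
            x = np.array([0.0] * 3 + [1.0] * 3)
            beta = np.polyfit(x, y, 1)
            resid = y - np.polyval(beta, x)
            np.testing.assert_allclose(out.values.iloc[i], resid + y.mean(), atol=1e-10)


class TestImputeNormal:
    def test_identity_without_missing(self, toy_matrix):
        out = pp.impute_normal(toy_matrix, seed=0)
        pd.testing.assert_frame_equal(out.values, toy_matrix.values)
        assert not out.imputed.any().any()

    def test_distribution_matches_downshifted_normal(self):
        # column mu=20, sigma=2 -> imputed ~ Normal(16.4, 0.6^2)
        rng = np.random.default_rng(0)
        n = 20000
        observed = rng.normal(20.0, 2.0, size=n)
        vals = pd.DataFrame({"S1": np.concatenate([observed, [np.nan] * 10000])})
        vals.index = [f"P{i}" for i in range(len(vals))]
        m = IntensityMatrix(vals, scale="log2", stage="filtered")
        out = pp.impute_normal(m, width=0.3, downshift=1.8, seed=1)
        drawn = out.values["S1"].iloc[n:]
        mu = observed.mean()
        sigma = observed.std(ddof=1)
        _, p = stats.kstest(drawn, "norm", args=(mu - 1.8 * sigma, 0.3 * sigma))
        assert p > 0.01

    def test_seed_reproducible(self, small_dataset):
        m, _, _ = small_dataset
        holed = sd.inject_missingness(m, 18.0, 1.0, seed=0)
        log2m = holed.with_values(np.log2(holed.values), scale="log2")
        a = pp.impute_normal(log2m, seed=5)
        b = pp.impute_normal(log2m, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_observed_untouched_and_flagged(self):
        vals = pd.DataFrame({"S1": [1.0, 2.0, 3.0, np.nan]}, index=list("abcd"))
        m = IntensityMatrix(vals, scale="log2")
        out = pp.impute_normal(m, seed=0)
        np.testing.assert_allclose(out.values["S1"].iloc[:3], [1.0, 2.0, 3.0])
        assert out.imputed.loc["d", "S1"]
        assert not out.imputed.loc["a", "S1"]

    def test_underdetermined_column_rejected(self):
        vals = pd.DataFrame({"S1": [1.0, np.nan, np.nan]}, index=list("abc"))
        with pytest.raises(ValueError, match="<2 observed"):
            pp.impute_normal(IntensityMatrix(vals, scale="log2"), seed=0)


def brute_force_on_off(present: pd.DataFrame, subtype_of: dict, hi: float, lo: float):
    """Independent exhaustive reimplementation of the on/off rule."""
    subtypes = sorted(set(subtype_of.values()))
    calls = []
    for prot in present.index:
        frac = {}
        for s in subtypes:
            cols = [c for c in present.columns if subtype_of[c] == s]
            frac[s] = sum(present.loc[prot, c] for c in cols) / len(cols)
        for s in subtypes:
            others = [t for t in subtypes if t != s]
            if frac[s] >= hi and all(frac[t] <= lo for t in others):
                calls.append((prot, s, "on"))
            if frac[s] <= lo and all(frac[t] >= hi for t in others):
                calls.append((prot, s, "off"))
    return sorted(calls)


class TestDetectOnOff:
    @staticmethod
    def _fixture(present_rows, sizes=(8, 7, 4, 7)):
        cols, subtype_of = [], {}
        for s, n in zip("ANPY", sizes):
            for i in range(n):
                c = f"{s}{i}"
                cols.append(c)
                subtype_of[c] = s
        vals = pd.DataFrame(
            [[v if p else np.nan for p in row] for row, v in zip(present_rows, range(1, len(present_rows) + 1))],
            index=[f"P{i}" for i in range(len(present_rows))],
            columns=cols,
            dtype=float,
        )
        ann = pd.DataFrame({"cell_line": cols, "subtype": [subtype_of[c] for c in cols]})
        return IntensityMatrix(vals, scale="log2"), ann, subtype_of

    def test_example_on_in_A(self):
        # present 7/8 in A, 1/7 in N, 0/4 in P, 1/7 in Y -> 'on' in A
        row = [True] * 7 + [False] + [True] + [False] * 6 + [False] * 4 + [True] + [False] * 6
        m, ann, _ = self._fixture([row])
        calls = pp.detect_on_off(m, ann)
        assert [(c.protein, c.subtype, c.direction) for c in calls] == [("P0", "A", "on")]

    def test_everywhere_present_or_absent_no_call(self):
        m, ann, _ = self._fixture([[True] * 26])
        assert pp.detect_on_off(m, ann) == []
        vals = m.values.copy() * np.nan
        m2 = m.with_values(vals)
        assert pp.detect_on_off(m2, ann) == []

    def test_matches_brute_force_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            rows = rng.random((20, 26)) < rng.uniform(0.1, 0.9)
            m, ann, subtype_of = self._fixture(list(rows))
            got = sorted(
                (c.protein, c.subtype, c.direction) for c in pp.detect_on_off(m, ann)
            )
            present = m.values.notna()
            assert got == brute_force_on_off(present, subtype_of, 0.85, 0.15)

    def test_empty_subtype_rejected(self):
        m, ann, _ = self._fixture([[True] * 26])
        bad_ann = ann[ann["subtype"] != "P"]
        m2 = m.with_values(m.values[bad_ann["cell_line"]])
        with pytest.raises(ValueError, match="empty subtype"):
            pp.detect_on_off(m2, bad_ann)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_normalization_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(
        rng.lognormal(10, 2, size=(15, 5)),
        index=[f"P{i}" for i in range(15)],
        columns=[f"S{i}" for i in range(5)],
    )
    once = pp.log2_median_normalize(IntensityMatrix(vals, scale="linear"))
    twice = pp.log2_median_normalize(once.with_values(np.exp2(once.values), scale="linear"))
    pd.testing.assert_frame_equal(once.values, twice.values, atol=1e-9, rtol=0)
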