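"""Five-way classification, crude and age-standardized prevalence, and the
composition of screen-detected diabetes, checked against brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glyconcord.classify import (
    CATEGORY_ORDER,
    ClassificationError,
    GlycemicCategory,
    StandardPopulation,
    age_standardized_prevalence,
    biomarker_correlation,
    classify_frame,
    classify_participant,
    composition_of_screen_detected,
    crude_prevalence,
    who_standard_population,
)


def random_classified_frame(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "study_id": "s",
            "sex": rng.choice(["female", "male"], n),
            "age": rng.uniform(18, 95, n),
            "bmi": rng.uniform(18, 40, n),
            "fpg": rng.lognormal(np.log(5.6), 0.25, n),
            "hba1c": rng.lognormal(np.log(5.7), 0.18, n),
            "diagnosed_previously": rng.random(n) < 0.08,
            "on_glucose_lowering_medication": rng.random(n) < 0.05,
            "pregnant": False,
            "visit_index": 1,
        }
    )


def oracle_classify(row) -> str:
    """Independent row-wise reimplementation of the category rules."""
    if row["diagnosed_previously"] or row["on_glucose_lowering_medication"]:
        return "diagnosed"
    f = row["fpg"] >= 7.0
    h = row["hba1c"] >= 6.5
    return {
        (True, True): "both_elevated",
        (True, False): "isolated_elevated_fpg",
        (False, True): "isolated_elevated_hba1c",
        (False, False): "no_diabetes",
    }[(f, h)]


class TestClassifyParticipant:
    @pytest.mark.parametrize(
        "fpg, hba1c, dx, med, expected",
        [
            (7.5, 6.0, False, False, GlycemicCategory.ISOLATED_ELEVATED_FPG),
            (6.0, 6.8, False, False, GlycemicCategory.ISOLATED_ELEVATED_HBA1C),
            (7.0, 6.5, False, False, GlycemicCategory.BOTH_ELEVATED),
            (6.99, 6.49, False, False, GlycemicCategory.NO_DIABETES),
            (5.0, 5.2, True, False, GlycemicCategory.DIAGNOSED),
            (5.0, 5.2, False, True, GlycemicCategory.DIAGNOSED),
        ],
    )
    def test_threshold_and_diagnosis_rules(self, fpg, hba1c, dx, med, expected):
        p = {
            "fpg": fpg,
            "hba1c": hba1c,
            "diagnosed_previously": dx,
            "on_glucose_lowering_medication": med,
        }
        assert classify_participant(p) is expected

    def test_missing_biomarker_raises(self):
        p = {
            "fpg": np.nan,
            "hba1c": 6.0,
            "diagnosed_previously": False,
            "on_glucose_lowering_medication": False,
        }
        with pytest.raises(ClassificationError):
            classify_participant(p)

    def test_frame_matches_rowwise_oracle(self):
        df = random_classified_frame(2000, seed=1)
        vec = classify_frame(df)
        oracle = df.apply(oracle_classify, axis=1)
        assert (vec == oracle).all()

    def test_partition_is_exhaustive_and_exclusive(self):
        df = random_classified_frame(5000, seed=2)
        cats = classify_frame(df)
        assert cats.isin(CATEGORY_ORDER).all()
        assert len(cats) == len(df)


class TestCrudePrevalence:
    def test_sixteen_of_hundred(self):
        df = random_classified_frame(100, seed=3)
        cats = pd.Series(
            ["no_diabetes"] * 84 + ["diagnosed"] * 6 + ["both_elevated"] * 10,
            index=df.index,
        )
        prev = crude_prevalence(df, cats)
        assert 1.0 - prev["no_diabetes"] == pytest.approx(0.16, abs=1e-12)

    def test_all_no_diabetes(self):
        df = random_classified_frame(50, seed=4)
        cats = pd.Series("no_diabetes", index=df.index)
        prev = crude_prevalence(df, cats)
        assert prev["no_diabetes"] == 1.0
        assert prev.drop("no_diabetes").sum() == 0.0

    def test_matches_recount_oracle_and_sums_to_one(self):
        df = random_classified_frame(3333, seed=5)
        cats = classify_frame(df)
        prev = crude_prevalence(df, cats)
        counts = {c: int((cats == c).sum()) for c in CATEGORY_ORDER}
        for c in CATEGORY_ORDER:
            assert prev[c] == pytest.approx(counts[c] / len(df), abs=1e-15)
        assert prev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            crude_prevalence(random_classified_frame(5, 6).iloc[0:0])


class TestAgeStandardized:
    def test_two_band_arithmetic(self):
        std = StandardPopulation([18, 50], [50, np.inf], [0.6, 0.4])
        df = random_classified_frame(200, seed=7)
        df["age"] = [30.0] * 100 + [70.0] * 100
        cats = pd.Series(
            ["diagnosed"] * 10 + ["no_diabetes"] * 90
            + ["diagnosed"] * 30 + ["no_diabetes"] * 70,
            index=df.index,
        )
        prev = age_standardized_prevalence(df, std, cats)
        assert prev["diagnosed"] == pytest.approx(0.6 * 0.10 + 0.4 * 0.30, abs=1e-12)

    def test_sample_weights_reduce_to_crude(self):
        df = random_classified_frame(4000, seed=8)
        cats = classify_frame(df)
        edges = [18, 30, 45, 60, 75, np.inf]
        idx = np.searchsorted(edges, df["age"], side="right") - 1
        weights = np.bincount(idx, minlength=5) / len(df)
        std = StandardPopulation(edges[:-1], edges[1:], weights)
        standardized = age_standardized_prevalence(df, std, cats)
        crude = crude_prevalence(df, cats)
        for c in CATEGORY_ORDER:
            assert standardized[c] == pytest.approx(crude[c], abs=1e-12)

    def test_matches_weighted_mean_oracle(self):
        df = random_classified_frame(2500, seed=9)
        cats = classify_frame(df)
        std = who_standard_population()
        prev = age_standardized_prevalence(df, std, cats)
        band = std.band_index(df["age"].to_numpy())
        expected = pd.Series(0.0, index=CATEGORY_ORDER)
        populated = np.unique(band)
        w = std.weights[populated] / std.weights[populated].sum()
        for weight, b in zip(w, populated):
            sub = cats[band == b]
            for c in CATEGORY_ORDER:
                expected[c] += weight * (sub == c).mean()
        for c in CATEGORY_ORDER:
            assert prev[c] == pytest.approx(expected[c], abs=1e-12)
        assert prev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_band_renormalizes_with_warning(self):
        df = random_classified_frame(300, seed=10)
        df["age"] = np.random.default_rng(0).uniform(18, 39, 300)  # older bands empty
        cats = classify_frame(df)
        with pytest.warns(UserWarning, match="empty age band"):
            prev = age_standardized_prevalence(df, categories=cats)
        assert prev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_age_outside_coverage_raises(self):
        df = random_classified_frame(10, seed=11)
        df.loc[3, "age"] = 12.0
        with pytest.raises(ValueError, match="rows"):
            age_standardized_prevalence(df)

    def test_who_weights_valid(self):
        std = who_standard_population()
        assert std.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (std.weights >= 0).all()
        assert std.lower_bounds[0] == 18.0


class TestComposition:
    def test_share_arithmetic(self):
        df = random_classified_frame(100, seed=12)
        df["age"] = 40.0
        cats = pd.Series(
            ["isolated_elevated_fpg"] * 29
            + ["isolated_elevated_hba1c"] * 37
            + ["both_elevated"] * 34,
            index=df.index,
        )
        comp = composition_of_screen_detected(df, categories=cats)
        assert comp.loc["crude", "isolated_elevated_fpg"] == pytest.approx(0.29)
        assert comp.loc["crude", "isolated_elevated_hba1c"] == pytest.approx(0.37)
        assert comp.loc["crude", "both_elevated"] == pytest.approx(0.34)
        assert comp.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])

    def test_single_category(self):
        df = random_classified_frame(40, seed=13)
        df["age"] = 50.0
        cats = pd.Series("isolated_elevated_fpg", index=df.index)
        comp = composition_of_screen_detected(df, categories=cats)
        assert comp.loc["crude", "isolated_elevated_fpg"] == 1.0

    def test_invariant_to_duplicating_dataset(self):
        df = random_classified_frame(500, seed=14)
        cats = classify_frame(df)
        doubled = pd.concat([df, df], ignore_index=True)
        c1 = composition_of_screen_detected(df, categories=cats)
        c2 = composition_of_screen_detected(
            doubled, categories=classify_frame(doubled)
        )
        pd.testing.assert_frame_equal(c1, c2)

    def test_no_screen_detected_raises(self):
        df = random_classified_frame(20, seed=15)
        cats = pd.Series("no_diabetes", index=df.index)
        with pytest.raises(ValueError, match="screen-detected"):
            composition_of_screen_detected(df, categories=cats)


class TestBiomarkerCorrelation:
    def test_collinear_is_one(self):
        df = random_classified_frame(10, seed=16)
        df["diagnosed_previously"] = False
        df["on_glucose_lowering_medication"] = False
        df["hba1c"] = 2.0 * df["fpg"] + 1.0
        assert biomarker_correlation(df) == pytest.approx(1.0)

    def test_matches_textbook_formula_on_ten_points(self):
        df = random_classified_frame(10, seed=17)
        df["diagnosed_previously"] = False
        df["on_glucose_lowering_medication"] = False
        x, y = df["fpg"].to_numpy(), df["hba1c"].to_numpy()
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert biomarker_correlation(df) == pytest.approx(expected, abs=1e-12)

    def test_restricted_to_undiagnosed(self):
        df = random_classified_frame(200, seed=18)
        with_dx = biomarker_correlation(df)
        df2 = df[
            ~(df["diagnosed_previously"] | df["on_glucose_lowering_medication"])
        ]
        assert with_dx == pytest.approx(biomarker_correlation(df2))

    def test_insufficient_data_raises(self):
        df = random_classified_frame(2, seed=19)
        df["diagnosed_previously"] = False
        df["on_glucose_lowering_medication"] = False
        with pytest.raises(ValueError):
            biomarker_correlation(df)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=20, max_value=400), st.integers(min_value=0, max_value=10**6))
def test_prevalence_partition_property(n, seed):
    """Crude proportions always sum to 1 and match per-category recounts."""
    df = random_classified_frame(n, seed)
    cats = classify_frame(df)
    prev = crude_prevalence(df, cats)
    assert prev.sum() == pytest.approx(1.0, abs=1e-12)
    assert (prev >= 0).all()
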