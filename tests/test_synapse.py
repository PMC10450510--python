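"""Length summaries, contingency tests, group comparisons and the
age/epilepsy regression over EM active-zone records."""

import numpy as np
import pandas as pd
import pytest

from epicortex import synth
from epicortex.synapse import (age_epilepsy_regression, contingency_test,
                               group_compare, length_summary,
                               per_patient_perforation, proportion_counts,
                               validate_records)


class TestLengthSummary:
    def test_two_value_arithmetic(self):
        df = pd.DataFrame({"group": ["g", "g"],
                           "active_zone_length_um": [0.2, 0.3]})
        row = length_summary(df, ["group"]).iloc[0]
        assert row["mean"] == pytest.approx(0.25)
        assert row["sem"] == pytest.approx(0.05)
        assert row["median"] == pytest.approx(0.25)

    def test_full_factorial_emits_eight_rows(self):
        cfg = synth.SimConfig()
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(0))
        out = length_summary(df, ["group", "region", "perforated"])
        assert len(out) == 8

    def test_lognormal_mean_recovered(self):
        cfg = synth.SimConfig(synapse_n={"non-epileptic": 10_000,
                                         "epileptic": 10})
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(1))
        sub = df[(df.group == "non-epileptic") & ~df.perforated]
        row = length_summary(sub.assign(g=0), ["g"]).iloc[0]
        mu, sig = np.log(cfg.length_median_um[False]), cfg.length_log_sigma
        truth = np.exp(mu + sig ** 2 / 2)
        assert abs(row["mean"] - truth) < 3 * row["sem"]


class TestProportion:
    @pytest.mark.parametrize("count,total,pct", [
        (10, 219, 4.6), (187, 281, 66.5), (128, 240, 53.3),
        (0, 50, 0.0), (18, 30, 60.0),
    ])
    def test_printed_rounding_convention(self, count, total, pct):
        assert proportion_counts(count, total).percent == pct

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_counts(1, 0)


class TestContingency:
    def test_identical_rows_null(self):
        rep = contingency_test([[50, 50], [50, 50]])
        assert rep.p == pytest.approx(1.0)

    def test_yates_and_fisher_variants(self):
        t = [[49, 191], [81, 200]]
        plain = contingency_test(t).p
        yates = contingency_test(t, "chi-square+yates").p
        fisher = contingency_test(t, "fisher").p
        assert plain < yates  # the correction is conservative
        assert 0 < fisher < 1

    def test_fisher_requires_2x2(self):
        with pytest.raises(ValueError):
            contingency_test([[1, 2, 3], [4, 5, 6]], "fisher")

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[1.5, 2], [3, 4]])

    def test_row_proportions_normalize(self):
        rep = contingency_test([[128, 93, 19], [187, 85, 9]])
        np.testing.assert_allclose(rep.row_proportions.sum(axis=1), 1.0)

    def test_matches_textbook_formula(self):
        """Pearson statistic equals a direct sum((O-E)^2/E) computation."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(5, 200, size=(2, rng.integers(2, 5))).astype(float)
            rep = contingency_test(t)
            exp = t.sum(1, keepdims=True) * t.sum(0, keepdims=True) / t.sum()
            assert rep.statistic == pytest.approx(((t - exp) ** 2 / exp).sum())


class TestGroupCompare:
    def test_equal_constant_groups_not_rejected(self):
        rep = group_compare({"a": [1.0] * 10, "b": [1.0] * 10})
        assert rep["p"] == 1.0

    def test_small_groups_excluded(self):
        rep = group_compare({"a": [1.0, 2.0], "b": [1.0] * 5})
        assert rep["status"] == "insufficient"

    def test_kruskal_null_calibration(self):
        rej, n = 0, 200
        for s in range(n):
            rng = np.random.default_rng(s)
            groups = {k: rng.lognormal(0, 0.4, 40) for k in "abcd"}
            rej += group_compare(groups)["p"] < 0.05
        assert abs(rej / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_shift_detected_at_table_sample_sizes(self):
        """A 0.05-μm shift at n=120 vs 130 is found most of the time."""
        hits, n = 0, 50
        for s in range(n):
            rng = np.random.default_rng(100 + s)
            a = rng.lognormal(np.log(0.24), 0.33, 120)
            b = rng.lognormal(np.log(0.19), 0.33, 130)
            hits += group_compare({"a": a, "b": b})["p"] < 0.05
        assert hits >= 0.8 * n

    def test_dunn_follow_up_flags_shifted_group(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.lognormal(0, 0.8, 60), "b": rng.lognormal(0, 0.8, 60),
                  "c": 3.0 * rng.lognormal(0, 0.8, 60)}
        rep = group_compare(groups)
        assert rep["test"] == "kruskal-wallis"
        pair_p = {frozenset(d["pair"]): d["p"] for d in rep["pairwise"]}
        assert pair_p[frozenset(("a", "c"))] < 0.05
        assert pair_p[frozenset(("a", "b"))] > 0.05


class TestAgeRegression:
    def _patients(self, rng, group_effect=0.2, age_effect=0.0, noise=0.03):
        rows = []
        for g, (m, sd) in (("non-epileptic", (61.5, 17.0)),
                           ("epileptic", (34.6, 13.0))):
            for i in range(7):
                age = float(np.clip(rng.normal(m, sd), 18, 85))
                frac = 0.2 + age_effect * age \
                    + (group_effect if g == "epileptic" else 0.0) \
                    + rng.normal(0, noise)
                rows.append({"patient_id": f"{g}{i}", "group": g,
                             "age": age, "perforated_fraction": frac})
        return pd.DataFrame(rows)

    def test_noise_free_group_effect_has_tiny_p(self):
        pats = self._patients(np.random.default_rng(0), noise=1e-9)
        rep = age_epilepsy_regression(pats)
        assert rep["p"]["epilepsy"] < 1e-6

    def test_group_effect_power_and_age_null(self):
        age_ps, group_hits, n = [], 0, 100
        for s in range(n):
            pats = self._patients(np.random.default_rng(s))
            rep = age_epilepsy_regression(pats)
            age_ps.append(rep["p"]["age"])
            group_hits += rep["p"]["epilepsy"] < 0.05
        assert group_hits >= 0.8 * n
        # age is a null predictor: its p-values are roughly uniform
        assert abs(np.mean(np.array(age_ps) < 0.05) - 0.05) \
            < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_permuted_group_p_uniform(self):
        rej, n = 0, 100
        for s in range(n):
            rng = np.random.default_rng(5000 + s)
            pats = self._patients(rng, group_effect=0.2)
            pats["group"] = rng.permutation(pats["group"].to_numpy())
            if pats["group"].nunique() < 2:
                continue
            rej += age_epilepsy_regression(pats)["p"]["epilepsy"] < 0.05
        assert rej / n < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_single_group_rejected(self):
        pats = self._patients(np.random.default_rng(1))
        with pytest.raises(ValueError):
            age_epilepsy_regression(pats[pats.group == "epileptic"])


class TestRecordValidation:
    def test_shared_synapse_id_must_be_perforated(self):
        df = pd.DataFrame({
            "patient_id": ["p"] * 2, "group": ["epileptic"] * 2,
            "region": ["SPA"] * 2, "synapse_id": ["s1", "s1"],
            "active_zone_length_um": [0.2, 0.25],
            "perforated": [True, False], "target": ["spine", "spine"],
            "multi_innervated": [False, False], "age": [40.0, 40.0],
        })
        with pytest.raises(ValueError):
            validate_records(df)

    def test_per_patient_aggregation(self):
        cfg = synth.SimConfig()
        df = synth.simulate_synapse_table(cfg, np.random.default_rng(2))
        pats = per_patient_perforation(df)
        assert pats["n_active_zones"].sum() == len(df)
        assert set(pats["group"]) == {"non-epileptic", "epileptic"}
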