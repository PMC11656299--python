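"""Evaluation protocol: splits, weights, filtering, tests, marks, ranks, hard subsets."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import mwu_enumeration, wilcoxon_enumeration

from ldct_benchmark.protocol import (HardSubsetSpec, MetricTable, NormalizationStats,
                                     _competition_ranks, competition_rank, evaluate_method,
                                     filter_test_slices, ldct_hard_subset, mann_whitney_u,
                                     metric_table, sampling_weights, significance_marks,
                                     split_dataset, wilcoxon_signed_rank)


def _manifest(n_per_type=50):
    return {"scans": [{"exam_type": e, "patient_id": f"{e}-{i:03d}"}
                      for e in ("abdomen", "head", "chest") for i in range(n_per_type)]}


class TestSplitDataset:
    def test_fifty_patients_split_35_10_5(self):
        s = split_dataset(_manifest(50), seed=0)
        for e in ("abdomen", "head", "chest"):
            assert (len(s.train[e]), len(s.validation[e]), len(s.test[e])) == (35, 10, 5)

    def test_disjoint_and_exhaustive(self):
        s = split_dataset(_manifest(17), seed=1)
        for e in ("abdomen", "head", "chest"):
            parts = [set(s.train[e]), set(s.validation[e]), set(s.test[e])]
            assert sum(len(p) for p in parts) == 17
            assert len(parts[0] | parts[1] | parts[2]) == 17

    def test_same_seed_same_split(self):
        a = split_dataset(_manifest(20), seed=9)
        b = split_dataset(_manifest(20), seed=9)
        assert a.train == b.train and a.test == b.test

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_manifest(2), seed=0)


class TestSamplingWeights:
    def _slices(self):
        rows = []
        per_patient = {("abdomen", "a0"): 10, ("abdomen", "a1"): 30,
                       ("head", "h0"): 20, ("chest", "c0"): 5, ("chest", "c1"): 5}
        for (e, p), n in per_patient.items():
            rows += [{"exam_type": e, "patient_id": p, "slice_index": z} for z in range(n)]
        return pd.DataFrame(rows)

    def test_weights_sum_to_one(self):
        df = sampling_weights(self._slices())
        assert df["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_marginals_uniform_over_exam_types_and_patients(self, rng):
        df = sampling_weights(self._slices())
        draws = rng.choice(len(df), size=100_000, p=df["weight"].to_numpy())
        picked = df.iloc[draws]
        # exam-type marginal: 1/3 each within 3 binomial SE
        se = np.sqrt((1 / 3) * (2 / 3) / 100_000)
        for e, frac in picked["exam_type"].value_counts(normalize=True).items():
            assert abs(frac - 1 / 3) < 3 * se
        # within abdomen, patients with 10 and 30 slices drawn equally often
        abd = picked[picked.exam_type == "abdomen"]["patient_id"].value_counts(normalize=True)
        se_p = np.sqrt(0.25 / len(picked[picked.exam_type == "abdomen"]))
        assert abs(abd["a0"] - 0.5) < 3 * se_p

    def test_patient_with_no_slices_rejected(self):
        df = self._slices()
        with pytest.raises(ValueError):
            sampling_weights(df.iloc[0:0])


class TestFilterTestSlices:
    def _masks(self, present):
        mask = np.zeros((8, 4, 4), dtype=bool)
        for z in present:
            mask[z, 1:3, 1:3] = True
        return mask

    def test_head_keeps_brain_slices(self):
        masks = {"brain": self._masks([3, 4, 5, 6, 7])}
        out = filter_test_slices(exam_type="head", organ_masks=masks, n_slices=8)
        assert out == [3, 4, 5, 6, 7]

    def test_abdomen_with_empty_lung_keeps_all(self):
        masks = {"lung": self._masks([]), "liver": self._masks([1, 2])}
        out = filter_test_slices(exam_type="abdomen", organ_masks=masks, n_slices=8)
        assert out == list(range(8))

    def test_chest_with_empty_lung_is_empty(self):
        masks = {"lung": self._masks([])}
        assert filter_test_slices(exam_type="chest", organ_masks=masks, n_slices=8) == []

    def test_missing_required_mask_rejected(self):
        with pytest.raises(KeyError):
            filter_test_slices(exam_type="head", organ_masks={"lung": self._masks([1])}, n_slices=8)


class TestNormalizationStats:
    def test_training_only_stats(self, abdomen_pair):
        stats = NormalizationStats.from_training_pairs([abdomen_pair])
        z = stats.normalize("abdomen", abdomen_pair.low.hu)
        assert abs(float(z.mean())) < 1e-9
        assert float(z.std()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationStats(mean={"head": 0.0}, std={"head": 0.0})


class TestEvaluateMethod:
    def test_identity_row_equals_ld_baseline(self, abdomen_pair):
        from ldct_benchmark.denoisers import get_denoiser

        spec = get_denoiser("identity")
        rec = evaluate_method(spec, [spec.train([], None, 0)], [abdomen_pair], ("SSIM",))
        keep = filter_test_slices(abdomen_pair)
        from ldct_benchmark.metrics import ssim

        for _, row in rec.iterrows():
            z = int(row.slice_index)
            assert z in keep
            expected = ssim(abdomen_pair.low.hu[z], abdomen_pair.high.hu[z])
            assert row.value == pytest.approx(expected, abs=1e-12)

    def test_deterministic_method_zero_std(self, abdomen_pair):
        from ldct_benchmark.denoisers import get_denoiser

        spec = get_denoiser("gaussian")
        state = spec.train([], None, 0)
        rec = evaluate_method(spec, [state, state], [abdomen_pair], ("SSIM",))
        table = metric_table(rec, {"gaussian": 1995})
        assert (table.summary["std"] == 0.0).all()

    def test_two_seed_hand_aggregation(self):
        rows = [("m", s, "head", "p0", z, "SSIM", v)
                for s, vals in ((0, (0.8, 0.9)), (1, (0.7, 0.8)))
                for z, v in enumerate(vals)]
        rec = pd.DataFrame(rows, columns=["method", "seed", "exam_type", "scan_id",
                                          "slice_index", "metric", "value"])
        table = metric_table(rec, {"m": 2020})
        mean, std = table.cell("m", "head", "SSIM")
        assert mean == pytest.approx(0.8)  # seed means .85 and .75
        assert std == pytest.approx(np.std([0.85, 0.75], ddof=1))


class TestExactTests:
    def test_textbook_case(self):
        _, p = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == 0.05  # 1 / C(6,3)

    def test_identical_permuted_samples_two_sided(self, rng):
        a = rng.normal(size=6)
        b = np.array(sorted(a, reverse=True))
        _, p = mann_whitney_u(a, b, alternative="two-sided")
        assert p >= 0.99

    def test_constant_samples_p_one(self):
        assert mann_whitney_u([3.0, 3.0], [3.0, 3.0, 3.0])[1] == 1.0

    def test_mwu_matches_enumeration_exhaustively(self, rng):
        # every size combination with n+m <= 10, random data with occasional ties
        for n, m in [(n, m) for n in range(1, 6) for m in range(1, 6) if n + m <= 10]:
            a = np.round(rng.normal(size=n), 1)
            b = np.round(rng.normal(size=m), 1)
            for alt in ("less", "greater", "two-sided"):
                _, p = mann_whitney_u(a, b, alternative=alt)
                assert p == pytest.approx(mwu_enumeration(a, b, alt), abs=1e-12)

    def test_mwu_random_n6_cases(self, rng):
        for _ in range(50):
            a = np.round(rng.normal(size=6), 1)
            b = np.round(rng.normal(size=6), 1)
            _, p = mann_whitney_u(a, b, alternative="two-sided")
            assert p == pytest.approx(mwu_enumeration(a, b, "two-sided"), abs=1e-12)

    def test_wilcoxon_all_positive_one_sided(self):
        p = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0], alternative="greater")
        assert p == pytest.approx(1 / 32)

    def test_wilcoxon_identical_pairs(self):
        assert wilcoxon_signed_rank([1.0] * 6, [1.0] * 6) == 1.0

    def test_wilcoxon_matches_enumeration(self, rng):
        for _ in range(50):
            a = np.round(rng.normal(size=8), 1)
            b = np.round(rng.normal(size=8), 1)
            for alt in ("greater", "two-sided"):
                p = wilcoxon_signed_rank(a, b, alternative=alt)
                assert p == pytest.approx(wilcoxon_enumeration(a, b, alt), abs=1e-12)


def _table(methods):
    """Construct a MetricTable from {method: (year, {(exam,metric): samples})}."""
    rows, samples = [], {}
    for method, (year, cells) in methods.items():
        for (exam, metric), vals in cells.items():
            vals = np.asarray(vals, dtype=float)
            rows.append({"method": method, "exam_type": exam, "metric": metric,
                         "mean": vals.mean(), "std": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                         "year": year})
            samples[(method, exam, metric)] = vals
    return MetricTable(summary=pd.DataFrame(rows), samples=samples)


class TestSignificanceMarks:
    def test_newer_method_beating_earlier_best_marked_better(self):
        table = _table({
            "LD": (0, {("head", "SSIM"): [0.5] * 5}),
            "old": (2017, {("head", "SSIM"): [0.70, 0.71, 0.69, 0.70, 0.72]}),
            "new": (2019, {("head", "SSIM"): [0.80, 0.81, 0.79, 0.80, 0.82]}),
        })
        marks = significance_marks(table, alpha=0.05)
        get = lambda m: marks[marks.method == m]["mark"].iloc[0]
        assert get("new") == "better"
        assert marks[marks.method == "new"]["comparator"].iloc[0] == "old"

    def test_earliest_method_compares_to_baseline(self):
        table = _table({
            "LD": (0, {("head", "SSIM"): [0.5] * 5}),
            "old": (2017, {("head", "SSIM"): [0.5] * 5}),
        })
        marks = significance_marks(table)
        row = marks[marks.method == "old"].iloc[0]
        assert row["comparator"] == "LD"
        assert row["mark"] == "none"  # identical samples

    def test_marks_invariant_to_seed_order(self):
        cells = {("head", "SSIM"): [0.70, 0.75, 0.72, 0.71, 0.74]}
        shuffled = {("head", "SSIM"): [0.74, 0.70, 0.72, 0.75, 0.71]}
        t1 = _table({"LD": (0, {("head", "SSIM"): [0.5] * 5}), "m": (2017, cells)})
        t2 = _table({"LD": (0, {("head", "SSIM"): [0.5] * 5}), "m": (2017, shuffled)})
        assert significance_marks(t1)["mark"].tolist() == significance_marks(t2)["mark"].tolist()

    def test_significantly_worse_marked_italic(self):
        table = _table({
            "LD": (0, {("head", "SSIM"): [0.5] * 5}),
            "old": (2017, {("head", "SSIM"): [0.80, 0.81, 0.79, 0.80, 0.82]}),
            "new": (2021, {("head", "SSIM"): [0.60, 0.61, 0.59, 0.60, 0.62]}),
        })
        marks = significance_marks(table)
        assert marks[marks.method == "new"]["mark"].iloc[0] == "worse"


class TestCompetitionRank:
    def test_hand_scores(self):
        np.testing.assert_array_equal(_competition_ranks(np.array([3.0, 5.0, 5.0, 9.0])),
                                      [1, 2, 2, 4])

    def test_single_method(self):
        table = _table({"m": (2020, {("head", "SSIM"): [0.7] * 3})})
        ranks = competition_rank(table)
        assert ranks.ranks["rank"].tolist() == [1]

    def test_full_table_with_tie_flag(self):
        table = _table({
            "a": (2017, {("head", "SSIM"): [0.9] * 3, ("head", "RMSE"): [5.0] * 3}),
            "b": (2018, {("head", "SSIM"): [0.8] * 3, ("head", "RMSE"): [6.0] * 3}),
            "c": (2019, {("head", "SSIM"): [0.8] * 3, ("head", "RMSE"): [6.0] * 3}),
        })
        ranks = competition_rank(table).ranks.set_index("method")
        assert ranks.loc["a", "rank"] == 1 and not ranks.loc["a", "tied"]
        assert ranks.loc["b", "rank"] == 2 and ranks.loc["c", "rank"] == 2
        assert bool(ranks.loc["b", "tied"]) and bool(ranks.loc["c", "tied"])

    def test_dominated_method_preserves_existing_order(self):
        base = {
            "a": (2017, {("head", "SSIM"): [0.9] * 3}),
            "b": (2018, {("head", "SSIM"): [0.8] * 3}),
        }
        with_dominated = dict(base)
        with_dominated["z"] = (2019, {("head", "SSIM"): [0.1] * 3})
        r1 = competition_rank(_table(base)).ranks.set_index("method")["rank"]
        r2 = competition_rank(_table(with_dominated)).ranks.set_index("method")["rank"]
        assert (r1["a"] < r1["b"]) and (r2["a"] < r2["b"]) and r2["z"] == 3

    def test_rank_invariant_under_monotone_metric_transform(self):
        table = _table({
            "a": (2017, {("head", "SSIM"): [0.9] * 3, ("head", "PSNR"): [30.0] * 3}),
            "b": (2018, {("head", "SSIM"): [0.7] * 3, ("head", "PSNR"): [28.0] * 3}),
            "c": (2019, {("head", "SSIM"): [0.8] * 3, ("head", "PSNR"): [26.0] * 3}),
        })
        transformed = _table({
            "a": (2017, {("head", "SSIM"): [np.exp(0.9)] * 3, ("head", "PSNR"): [30.0] * 3}),
            "b": (2018, {("head", "SSIM"): [np.exp(0.7)] * 3, ("head", "PSNR"): [28.0] * 3}),
            "c": (2019, {("head", "SSIM"): [np.exp(0.8)] * 3, ("head", "PSNR"): [26.0] * 3}),
        })
        r1 = competition_rank(table).ranks.set_index("method")["rank"]
        r2 = competition_rank(transformed).ranks.set_index("method")["rank"]
        assert r1.equals(r2)

    def test_incomplete_grid_rejected(self):
        table = _table({
            "a": (2017, {("head", "SSIM"): [0.9] * 3, ("head", "PSNR"): [30.0] * 3}),
            "b": (2018, {("head", "SSIM"): [0.8] * 3}),
        })
        with pytest.raises(ValueError):
            competition_rank(table)


class TestHardSubset:
    def _records(self, values, methods=("m1", "m2")):
        rows = []
        for i, v in enumerate(values):
            for m in methods:
                rows.append({"method": m, "exam_type": "head", "scan_id": "s0",
                             "slice_index": i, "value": v})
        return pd.DataFrame(rows)

    def test_lowest_two_of_ten_at_q20(self):
        df = self._records(np.round(np.arange(0.1, 1.05, 0.1), 10))
        hs = ldct_hard_subset(df, q=20)
        assert hs.slices["head"] == [("s0", 0), ("s0", 1)]

    def test_q100_keeps_everything(self):
        df = self._records([0.5, 0.4, 0.3])
        assert len(ldct_hard_subset(df, 100).slices["head"]) == 3

    def test_subsets_nested_in_q(self):
        df = self._records(np.random.default_rng(0).uniform(size=25))
        prev = set()
        for q in (20, 40, 60, 100):
            cur = set(ldct_hard_subset(df, q).slices["head"])
            assert prev <= cur
            prev = cur

    def test_missing_method_slice_rejected(self):
        df = self._records([0.5, 0.4])
        df = df.drop(df.index[-1])
        with pytest.raises(ValueError):
            ldct_hard_subset(df, 50)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            HardSubsetSpec(q=0.0, slices={})


class TestHardSubsetOnSimulatedData:
    def test_baseline_ssim_non_increasing_as_q_shrinks(self, abdomen_pair, chest_pair):
        from ldct_benchmark.denoisers import get_denoiser

        spec = get_denoiser("identity")
        rec = evaluate_method(spec, [spec.train([], None, 0)],
                              [abdomen_pair, chest_pair], ("SSIM",))
        rec = rec.assign(method="LD")
        for exam in rec["exam_type"].unique():
            means = []
            for q in (100, 60, 40, 20):
                hs = ldct_hard_subset(rec, q)
                sel = [rec[(rec.exam_type == exam) & (rec.scan_id == sid)
                           & (rec.slice_index == z)]["value"].iloc[0]
                       for sid, z in hs.slices[exam]]
                means.append(float(np.mean(sel)))
            assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
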