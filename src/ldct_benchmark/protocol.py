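"""The benchmark evaluation protocol.

Patient-level 70/20/10 splitting per exam type, weighted slice sampling
(uniform over exam types and patients), test-slice filtering by organ
presence, metric aggregation over slices -> scans -> retrain seeds,
hard-subset construction (the q% of test slices with the lowest
method-averaged SSIM, per exam type), nonparametric significance marking
against the previously published best method, and competition ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ldct_benchmark._seeding import rng_from
from ldct_benchmark.metrics import DEFAULT_DATA_RANGE, IdenticalImagesError, psnr, rmse_hu, ssim, vif
from ldct_benchmark.sim.case import ScanPair

__all__ = [
    "SPLIT_FRACTIONS",
    "DatasetSplit",
    "NormalizationStats",
    "MetricTable",
    "RankTable",
    "HardSubsetSpec",
    "split_dataset",
    "sampling_weights",
    "filter_test_slices",
    "evaluate_method",
    "metric_table",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "significance_marks",
    "competition_rank",
    "ldct_hard_subset",
]

SPLIT_FRACTIONS = (0.7, 0.2, 0.1)  # train / validation / test
HIGHER_IS_BETTER = {"SSIM": True, "PSNR": True, "VIF": True, "RFS": True, "CNR": True,
                    "RMSE": False, "CT_DEV": False}
BASELINE_METHOD = "LD"


@dataclass
class DatasetSplit:
    """Patient-disjoint train/validation/test lists per exam type."""

    train: dict[str, list[str]]
    validation: dict[str, list[str]]
    test: dict[str, list[str]]
    seed: int

    def role_of(self, exam_type: str, patient_id: str) -> str:
        for role, table in (("train", self.train), ("validation", self.validation), ("test", self.test)):
            if patient_id in table.get(exam_type, []):
                return role
        raise KeyError(f"{patient_id} not in split for {exam_type}")


@dataclass(frozen=True)
class NormalizationStats:
    """Zero-mean/unit-variance statistics per exam type, from the training split only."""

    mean: dict[str, float]
    std: dict[str, float]

    def __post_init__(self) -> None:
        for e, s in self.std.items():
            if s <= 0:
                raise ValueError(f"std for {e} must be positive")

    def normalize(self, exam_type: str, hu: np.ndarray) -> np.ndarray:
        return (hu - self.mean[exam_type]) / self.std[exam_type]

    @classmethod
    def from_training_pairs(cls, pairs: list[ScanPair]) -> "NormalizationStats":
        mean, std = {}, {}
        by_exam: dict[str, list[np.ndarray]] = {}
        for p in pairs:
            by_exam.setdefault(p.exam_type, []).append(p.low.hu.ravel())
        for e, chunks in by_exam.items():
            v = np.concatenate(chunks)
            mean[e] = float(v.mean())
            std[e] = float(v.std())
        return cls(mean=mean, std=std)


@dataclass
class MetricTable:
    """Mean +/- std over retrain seeds per (method, exam_type, metric), plus raw samples."""

    summary: pd.DataFrame  # columns: method, exam_type, metric, mean, std, year
    samples: dict[tuple[str, str, str], np.ndarray]  # (method, exam_type, metric) -> per-seed values

    def cell(self, method: str, exam_type: str, metric: str) -> tuple[float, float]:
        row = self.summary[(self.summary.method == method) & (self.summary.exam_type == exam_type)
                           & (self.summary.metric == metric)]
        if row.empty:
            raise KeyError((method, exam_type, metric))
        return float(row["mean"].iloc[0]), float(row["std"].iloc[0])


@dataclass
class RankTable:
    """Competition ranks ("1224") over all (exam_type, metric) cells."""

    ranks: pd.DataFrame  # columns: method, score, rank, tied


@dataclass
class HardSubsetSpec:
    """The q% hardest test slices per exam type, identified by (scan_id, slice_index)."""

    q: float
    slices: dict[str, list[tuple[str, int]]]

    def __post_init__(self) -> None:
        if not (0.0 < self.q <= 100.0):
            raise ValueError("q must lie in (0, 100]")


# --------------------------------------------------------------------------
# splitting, weighting, slice filtering
# --------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [f * n for f in fractions]
    base = [math.floor(r) for r in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(manifest: dict | pd.DataFrame, seed: int) -> DatasetSplit:
    """Shuffle patients per exam type and partition 70/20/10 (largest remainder).

    ``manifest`` is either a dataset manifest dict with a ``"scans"`` list or
    a DataFrame with ``exam_type`` and ``patient_id`` columns.
    """
    if isinstance(manifest, dict):
        df = pd.DataFrame(manifest["scans"])
    else:
        df = manifest
    split: dict[str, dict[str, list[str]]] = {"train": {}, "validation": {}, "test": {}}
    rng = rng_from(seed, 41)
    for exam_type, group in df.groupby("exam_type", sort=True):
        patients = sorted(group["patient_id"].unique())
        if len(patients) < 3:
            raise ValueError(f"exam type {exam_type!r} has {len(patients)} patients; need >= 3")
        order = rng.permutation(len(patients))
        shuffled = [patients[i] for i in order]
        n_train, n_val, n_test = _largest_remainder(len(patients), SPLIT_FRACTIONS)
        split["train"][exam_type] = shuffled[:n_train]
        split["validation"][exam_type] = shuffled[n_train : n_train + n_val]
        split["test"][exam_type] = shuffled[n_train + n_val :]
    return DatasetSplit(train=split["train"], validation=split["validation"], test=split["test"], seed=int(seed))


def sampling_weights(training_slices: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Per-slice sampling weights making exam types and patients equiprobable.

    ``training_slices`` needs columns {exam_type, patient_id, slice_index}.
    weight = 1 / (E * P_e * S_p); the weights sum to 1.
    """
    df = pd.DataFrame(training_slices).copy()
    required = {"exam_type", "patient_id", "slice_index"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("empty training slice table")
    n_exams = df["exam_type"].nunique()
    patients_per_exam = df.groupby("exam_type")["patient_id"].nunique()
    slices_per_patient = df.groupby(["exam_type", "patient_id"])["slice_index"].count()
    if (slices_per_patient == 0).any():
        raise ValueError("patient with zero slices")
    p_e = df["exam_type"].map(patients_per_exam)
    s_p = df.set_index(["exam_type", "patient_id"]).index.map(slices_per_patient)
    df["weight"] = 1.0 / (n_exams * p_e.to_numpy() * np.asarray(s_p, dtype=float))
    return df


def filter_test_slices(scan: ScanPair | None = None, *, exam_type: str | None = None,
                       organ_masks: dict[str, np.ndarray] | None = None,
                       n_slices: int | None = None) -> list[int]:
    """Indices of test slices retained for evaluation.

    Head scans keep slices where the brain is present, chest scans where the
    lung is present, abdomen scans where the lung is absent (so an empty
    lung mask keeps every abdomen slice).
    """
    if scan is not None:
        exam_type = scan.exam_type
        organ_masks = scan.organ_masks
        n_slices = scan.high.hu.shape[0]
    assert exam_type is not None and organ_masks is not None
    required = {"head": "brain", "chest": "lung", "abdomen": "lung"}[exam_type]
    if required not in organ_masks:
        raise KeyError(f"{exam_type} scan lacks required mask {required!r}")
    mask = organ_masks[required]
    n_slices = n_slices or mask.shape[0]
    present = mask.reshape(mask.shape[0], -1).any(axis=1)
    if exam_type == "abdomen":
        return [z for z in range(n_slices) if not present[z]]
    return [z for z in range(n_slices) if present[z]]


# --------------------------------------------------------------------------
# metric evaluation
# --------------------------------------------------------------------------

_METRIC_FNS = {
    "SSIM": lambda t, r, dr: ssim(t, r, dr),
    "VIF": lambda t, r, dr: vif(t, r, data_range=dr),
    "RMSE": lambda t, r, dr: rmse_hu(t, r),
}


def _safe_psnr(t: np.ndarray, r: np.ndarray, dr: float) -> float:
    try:
        return psnr(t, r, dr)
    except IdenticalImagesError:
        return float("inf")


_METRIC_FNS["PSNR"] = _safe_psnr


def evaluate_method(
    spec,
    fitted_states_per_seed: list,
    test_pairs: list[ScanPair],
    metric_list: tuple[str, ...] = ("SSIM", "PSNR", "VIF"),
    data_range: float = DEFAULT_DATA_RANGE,
) -> pd.DataFrame:
    """Slice-level metric records for one method over all retrain seeds.

    Returns a tidy frame with columns {method, seed, exam_type, scan_id,
    slice_index, metric, value}. Aggregation to the scan, exam-type, and
    seed level is done by :func:`metric_table`. Failed scans are reported
    as rows with NaN values rather than silently dropped.
    """
    from ldct_benchmark.denoisers import apply_denoiser

    unknown = set(metric_list) - set(_METRIC_FNS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    if not fitted_states_per_seed:
        raise ValueError("at least one fitted state required")
    rows = []
    for seed_idx, state in enumerate(fitted_states_per_seed):
        for pair in test_pairs:
            keep = filter_test_slices(pair)
            try:
                denoised = apply_denoiser(spec, state, pair.low)
                for z in keep:
                    for metric in metric_list:
                        value = _METRIC_FNS[metric](denoised.hu[z], pair.high.hu[z], data_range)
                        rows.append((spec.name, seed_idx, pair.exam_type, pair.patient_id, z, metric, value))
            except Exception:  # noqa: BLE001 - failure recorded per (method, seed, scan)
                for z in keep:
                    for metric in metric_list:
                        rows.append((spec.name, seed_idx, pair.exam_type, pair.patient_id, z, metric, np.nan))
    return pd.DataFrame(rows, columns=["method", "seed", "exam_type", "scan_id", "slice_index", "metric", "value"])


def metric_table(records: pd.DataFrame, years: dict[str, int]) -> MetricTable:
    """Aggregate slice records: slices -> scan, scans -> exam type, then mean/std over seeds."""
    if records.empty:
        raise ValueError("no metric records")
    per_scan = records.groupby(["method", "seed", "exam_type", "scan_id", "metric"], sort=True)["value"].mean()
    per_seed = per_scan.groupby(["method", "seed", "exam_type", "metric"]).mean().reset_index()
    samples = {}
    for (method, exam_type, metric), g in per_seed.groupby(["method", "exam_type", "metric"], sort=True):
        samples[(method, exam_type, metric)] = g.sort_values("seed")["value"].to_numpy()
    agg = per_seed.groupby(["method", "exam_type", "metric"], sort=True)["value"].agg(["mean", "std"]).reset_index()
    agg["std"] = agg["std"].fillna(0.0)
    agg["year"] = agg["method"].map(lambda m: years.get(m, 0))
    return MetricTable(summary=agg, samples=samples)


# --------------------------------------------------------------------------
# nonparametric tests
# --------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(sample_a, sample_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; exact by enumeration when n + m <= 14.

    ``alternative``: "less" (a tends smaller than b), "greater", or
    "two-sided". Identical constant samples yield p = 1. The large-sample
    branch uses the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    u_obs = _u_statistic(a, b)
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    if n + m <= 14:
        idx = range(n + m)
        u_values = []
        for comb in itertools.combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u_values.append(_u_statistic(pooled[mask], pooled[~mask]))
        u_values = np.asarray(u_values)
        total = u_values.size
        p_le = np.sum(u_values <= u_obs) / total
        p_ge = np.sum(u_values >= u_obs) / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, float(p)
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return u_obs, float(res.pvalue)


def wilcoxon_signed_rank(deviations_a, deviations_b, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank test; exact by sign enumeration for n <= 12.

    Zero differences are dropped. All-zero differences yield p = 1.
    """
    a = np.asarray(deviations_a, dtype=float)
    b = np.asarray(deviations_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("paired samples of equal length >= 5 required")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    n = d.size
    if n <= 12:
        w_values = np.array([float(np.sum(ranks[list(signs)])) if signs else 0.0
                             for r in range(n + 1)
                             for signs in itertools.combinations(range(n), r)])
        total = w_values.size
        p_ge = np.sum(w_values >= w_obs) / total
        p_le = np.sum(w_values <= w_obs) / total
        if alternative == "greater":
            return float(p_ge)
        if alternative == "less":
            return float(p_le)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    res = sps.wilcoxon(a, b, alternative=alternative, correction=True, method="approx")
    return float(res.pvalue)


# --------------------------------------------------------------------------
# significance marks and ranking
# --------------------------------------------------------------------------

def significance_marks(table: MetricTable, alpha: float = 0.05, baseline: str = BASELINE_METHOD) -> pd.DataFrame:
    """Mark each (method, exam_type, metric) cell better/worse/none vs the previously published best.

    The comparator for a method is the method with the highest mean in that
    cell among methods with a strictly earlier publication year; methods
    with no earlier competitor compare against the low-dose baseline. Marks
    use one-sided Mann-Whitney tests at level ``alpha`` in each direction.
    """
    df = table.summary
    years = dict(zip(df["method"], df["year"]))
    out = []
    for (exam_type, metric), cell in df.groupby(["exam_type", "metric"], sort=True):
        higher_better = HIGHER_IS_BETTER.get(metric, True)
        for _, row in cell.iterrows():
            method = row["method"]
            if method == baseline:
                continue
            earlier = cell[(cell["method"] != baseline)
                           & (cell["method"].map(years) < years[method])]
            if earlier.empty:
                comparator = baseline
            else:
                comparator = (earlier.loc[earlier["mean"].idxmax() if higher_better
                                          else earlier["mean"].idxmin(), "method"])
            if comparator not in {m for (m, e, k) in table.samples if e == exam_type and k == metric}:
                raise KeyError(f"no samples for comparator {comparator!r}")
            mine = table.samples[(method, exam_type, metric)]
            theirs = table.samples[(comparator, exam_type, metric)]
            better_alt = "greater" if higher_better else "less"
            worse_alt = "less" if higher_better else "greater"
            _, p_better = mann_whitney_u(mine, theirs, alternative=better_alt)
            _, p_worse = mann_whitney_u(mine, theirs, alternative=worse_alt)
            mark = "better" if p_better < alpha else ("worse" if p_worse < alpha else "none")
            out.append((method, exam_type, metric, comparator, p_better, p_worse, mark))
    return pd.DataFrame(out, columns=["method", "exam_type", "metric", "comparator",
                                      "p_better", "p_worse", "mark"])


def _competition_ranks(scores: np.ndarray, lower_better: bool = True) -> np.ndarray:
    """"1224" ranks: ties share a rank; the next rank is skipped."""
    key = scores if lower_better else -scores
    return np.array([int(np.sum(key < k)) + 1 for k in key])


def competition_rank(table: MetricTable) -> RankTable:
    """Rank methods by summed per-cell ranks over all (exam_type, metric) cells."""
    df = table.summary
    methods = sorted(df["method"].unique())
    cells = df.groupby(["exam_type", "metric"], sort=True)
    totals = {m: 0 for m in methods}
    for (exam_type, metric), cell in cells:
        if set(cell["method"]) != set(methods):
            raise ValueError(f"incomplete metric grid in cell ({exam_type}, {metric})")
        higher_better = HIGHER_IS_BETTER.get(metric, True)
        means = cell.set_index("method")["mean"].reindex(methods).to_numpy()
        cell_ranks = _competition_ranks(means, lower_better=not higher_better)
        for m, r in zip(methods, cell_ranks):
            totals[m] += int(r)
    scores = np.array([totals[m] for m in methods], dtype=float)
    final = _competition_ranks(scores, lower_better=True)
    tied = np.array([np.sum(final == r) > 1 for r in final])
    out = pd.DataFrame({"method": methods, "score": scores, "rank": final, "tied": tied})
    return RankTable(ranks=out.sort_values(["rank", "method"]).reset_index(drop=True))


def ldct_hard_subset(per_slice_ssim: pd.DataFrame, q: float) -> HardSubsetSpec:
    """The q% of test slices with the lowest method-averaged SSIM, per exam type.

    ``per_slice_ssim`` needs columns {method, exam_type, scan_id,
    slice_index, value}; every method must cover every slice. Subset size is
    ceil(q * n / 100); ties break by (scan_id, slice_index) lexical order.
    """
    if not (0.0 < q <= 100.0):
        raise ValueError("q must lie in (0, 100]")
    df = per_slice_ssim
    pivot = df.pivot_table(index=["exam_type", "scan_id", "slice_index"], columns="method",
                           values="value", aggfunc="mean")
    if pivot.isna().any().any():
        raise ValueError("missing method-slice SSIM values")
    avg = pivot.mean(axis=1).reset_index().rename(columns={0: "avg_ssim"})
    slices: dict[str, list[tuple[str, int]]] = {}
    for exam_type, g in avg.groupby("exam_type", sort=True):
        g = g.sort_values(["avg_ssim", "scan_id", "slice_index"], kind="stable")
        k = math.ceil(q * len(g) / 100.0)
        slices[exam_type] = [(r.scan_id, int(r.slice_index)) for r in g.head(k).itertuples()]
    return HardSubsetSpec(q=float(q), slices=slices)
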