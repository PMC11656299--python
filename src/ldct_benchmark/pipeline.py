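"""Workspace-oriented pipeline: simulate -> (hpo) -> fit -> denoise -> evaluate -> rank.

Each stage reads and writes declared files inside a workspace directory and
embeds the run configuration fingerprint and seed in every artifact, so a
whole benchmark reproduces from a single config file and seed.

Workspace layout::

    <output_dir>/
      config.yaml          run configuration + fingerprint
      manifest.json        simulated dataset index
      volumes/             raw float32 volumes + JSON sidecars, masks
      states/              fitted denoiser states (.npz blob + .json metadata)
      denoised/            denoised volumes per (method, retrain seed)
      hpo/                 SMBO trial histories
      records/             slice-level metric records (CSV)
      tables/              metric table, significance marks, ranks (CSV/JSON)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ldct_benchmark._seeding import spawn_seeds
from ldct_benchmark.config import RunConfig
from ldct_benchmark.denoisers import (SmallCNNState, apply_denoiser, builtin_specs, get_denoiser)
from ldct_benchmark.protocol import (competition_rank, evaluate_method, ldct_hard_subset,
                                     metric_table, significance_marks, split_dataset)
from ldct_benchmark.sim import simulate_case
from ldct_benchmark.sim.io import load_scan_pair, read_manifest, save_scan_pair, write_manifest, write_volume_raw

log = logging.getLogger("ldct_benchmark")


def _ws(config: RunConfig) -> Path:
    ws = Path(config.output_dir)
    ws.mkdir(parents=True, exist_ok=True)
    return ws


def simulate_dataset(config: RunConfig, in_memory: bool = False):
    """Simulate the configured dataset; write volumes + manifest unless ``in_memory``."""
    sim_cfg = config.sim_config()
    case_seeds = spawn_seeds(config.seed, config.scans_per_type * len(config.exam_types))
    pairs = []
    k = 0
    for exam_type in config.exam_types:
        for i in range(config.scans_per_type):
            pair = simulate_case(exam_type, seed=case_seeds[k], config=sim_cfg,
                                 patient_id=f"{exam_type}-{i:03d}")
            pairs.append(pair)
            k += 1
            log.info("simulated %s (%d slices)", pair.patient_id, pair.low.hu.shape[0])
    if in_memory:
        return pairs
    ws = _ws(config)
    config.to_yaml(ws / "config.yaml")
    entries = [save_scan_pair(p, ws / "volumes") for p in pairs]
    write_manifest(entries, ws / "manifest.json", seed=config.seed,
                   config_fingerprint=config.fingerprint())
    return pairs


def load_dataset(config: RunConfig):
    ws = _ws(config)
    manifest = read_manifest(ws / "manifest.json")
    return [load_scan_pair(ws / "volumes", e) for e in manifest["scans"]]


def split_pairs(config: RunConfig, pairs):
    """Assign pairs to train/validation/test, honoring explicit split counts."""
    roles = {"train": [], "validation": [], "test": []}
    if config.split_counts is not None:
        n_tr, n_va, n_te = config.split_counts
        by_exam: dict[str, list] = {}
        for p in pairs:
            by_exam.setdefault(p.exam_type, []).append(p)
        for exam_pairs in by_exam.values():
            exam_pairs.sort(key=lambda p: p.patient_id)
            roles["train"] += exam_pairs[:n_tr]
            roles["validation"] += exam_pairs[n_tr : n_tr + n_va]
            roles["test"] += exam_pairs[n_tr + n_va : n_tr + n_va + n_te]
        return roles
    manifest_df = pd.DataFrame([{"exam_type": p.exam_type, "patient_id": p.patient_id} for p in pairs])
    split = split_dataset(manifest_df, config.seed)
    for p in pairs:
        roles[split.role_of(p.exam_type, p.patient_id)].append(p)
    return roles


# --------------------------------------------------------------------------
# fitted-state serialization: npz blob + JSON metadata
# --------------------------------------------------------------------------

def save_state(state, path: Path, *, method: str, seed: int, fingerprint: str) -> None:
    path = Path(path)
    meta = {"method": method, "seed": seed, "config_fingerprint": fingerprint}
    if isinstance(state, SmallCNNState):
        arrays = {f"w{i}": w for i, w in enumerate(state.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(state.biases)})
        np.savez(path, **arrays)
        meta.update({"kind": "cnn3", "mean": state.mean, "std": state.std,
                     "hyperparams": state.hyperparams, "final_loss": state.final_loss})
    else:
        payload = {k: v for k, v in state.items() if k != "history"}
        np.savez(path, _empty=np.zeros(1))
        meta.update({"kind": "dict", "state": payload})
    Path(str(path) + ".json").write_text(json.dumps(meta))


def load_state(path: Path):
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta["kind"] == "cnn3":
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        weights = [data[f"w{i}"] for i in range(3)]
        biases = [data[f"b{i}"] for i in range(3)]
        return SmallCNNState(weights, biases, meta["mean"], meta["std"],
                             meta["hyperparams"], meta["seed"], meta["final_loss"])
    return dict(meta["state"])


def fit_methods(config: RunConfig, pairs=None, persist: bool = True) -> dict[str, list]:
    """Train every configured method at each retrain seed on the training split."""
    builtin_specs()
    if pairs is None:
        pairs = load_dataset(config)
    roles = split_pairs(config, pairs)
    train_pairs = roles["train"] or pairs
    states: dict[str, list] = {}
    ws = _ws(config) if persist else None
    for method in config.methods:
        spec = get_denoiser(method)
        per_seed = []
        for s in range(config.retrain_seeds):
            state = spec.train(train_pairs, None, s)
            per_seed.append(state)
            if persist:
                out = ws / "states"
                out.mkdir(exist_ok=True)
                save_state(state, out / f"{method}_seed{s}.npz", method=method, seed=s,
                           fingerprint=config.fingerprint())
        states[method] = per_seed
        log.info("fitted %s for %d seeds", method, config.retrain_seeds)
    return states


def denoise_test_set(config: RunConfig, states: dict[str, list], pairs=None, persist: bool = True):
    """Apply each fitted state to the low-dose test volumes; write them out."""
    if pairs is None:
        pairs = load_dataset(config)
    roles = split_pairs(config, pairs)
    test_pairs = roles["test"] or pairs
    ws = _ws(config)
    outdir = ws / "denoised"
    written = []
    for method, per_seed in states.items():
        spec = get_denoiser(method)
        for s, state in enumerate(per_seed):
            for pair in test_pairs:
                vol = apply_denoiser(spec, state, pair.low)
                if persist:
                    outdir.mkdir(exist_ok=True)
                    p = outdir / f"{pair.patient_id}_{method}_seed{s}.raw"
                    write_volume_raw(vol, p)
                    written.append(p)
    return written


def evaluate_all(config: RunConfig, states: dict[str, list], pairs=None):
    """Metric records for the LD baseline and every method on the test split."""
    builtin_specs()
    if pairs is None:
        pairs = load_dataset(config)
    roles = split_pairs(config, pairs)
    test_pairs = roles["test"] or pairs
    identity = get_denoiser("identity")
    frames = [
        evaluate_method(identity, [identity.train([], None, 0)], test_pairs,
                        tuple(config.metrics), config.data_range).assign(method="LD")
    ]
    for method, per_seed in states.items():
        spec = get_denoiser(method)
        frames.append(evaluate_method(spec, per_seed, test_pairs, tuple(config.metrics), config.data_range))
    records = pd.concat(frames, ignore_index=True)
    ws = _ws(config)
    (ws / "records").mkdir(exist_ok=True)
    records.to_csv(ws / "records" / "slice_metrics.csv", index=False)
    return records


def rank_and_report(config: RunConfig, records: pd.DataFrame):
    """Aggregate, mark significance, rank, and build hard subsets; write tables."""
    years = {"LD": 0}
    for m in config.methods:
        years[m] = get_denoiser(m).year
    table = metric_table(records, years)
    marks = significance_marks(table, alpha=config.alpha)
    ranks = competition_rank(table)
    ssim_slices = records[records.metric == "SSIM"].groupby(
        ["method", "exam_type", "scan_id", "slice_index"], as_index=False)["value"].mean()
    subsets = {q: ldct_hard_subset(ssim_slices, q) for q in config.hard_q}
    ws = _ws(config)
    tdir = ws / "tables"
    tdir.mkdir(exist_ok=True)
    stamp = {"seed": config.seed, "config_fingerprint": config.fingerprint()}
    table.summary.to_csv(tdir / "metric_table.csv", index=False)
    marks.to_csv(tdir / "significance_marks.csv", index=False)
    ranks.ranks.to_csv(tdir / "rank_table.csv", index=False)
    (tdir / "metric_table.json").write_text(json.dumps(
        {**stamp, "rows": table.summary.to_dict(orient="records")}, indent=2))
    (tdir / "hard_subsets.json").write_text(json.dumps(
        {**stamp, "subsets": {str(q): s.slices for q, s in subsets.items()}}, indent=2, default=list))
    (tdir / "rank_table.json").write_text(json.dumps(
        {**stamp, "rows": ranks.ranks.to_dict(orient="records")}, indent=2))
    return table, marks, ranks, subsets


def rfs_records(config: RunConfig, states: dict[str, list], pairs=None) -> pd.DataFrame:
    """Radiomic feature similarity per (method, seed, scan) on the test split.

    For every scan and retrain seed, one feature matrix is built with the
    high-dose row (index 0), the low-dose row, and one row per method, all
    extracted inside the same high-dose organ mask; RFS is the cosine
    similarity of each min-max-normalized row against the high-dose row.
    """
    from ldct_benchmark.radiomics import FeatureMatrix, extract_features, rfs
    from ldct_benchmark.sim.phantom import ORGAN_FOR_EXAM

    if pairs is None:
        pairs = load_dataset(config)
    roles = split_pairs(config, pairs)
    test_pairs = roles["test"] or pairs
    methods = list(states)
    rows = []
    n_seeds = max(len(v) for v in states.values())
    for s in range(n_seeds):
        for pair in test_pairs:
            organ = ORGAN_FOR_EXAM[pair.exam_type]
            mask = pair.organ_masks[organ]
            if not mask.any():
                continue
            vectors = [
                extract_features(pair.high.hu, mask, scan_id=pair.patient_id, algorithm_index=0),
                extract_features(pair.low.hu, mask, scan_id=pair.patient_id, algorithm_index=1),
            ]
            names = {1: "LD"}
            for j, method in enumerate(methods, start=2):
                spec = get_denoiser(method)
                state = states[method][min(s, len(states[method]) - 1)]
                den = apply_denoiser(spec, state, pair.low)
                vectors.append(extract_features(den.hu, mask, scan_id=pair.patient_id, algorithm_index=j))
                names[j] = method
            matrix = FeatureMatrix.from_vectors(vectors)
            for rec in rfs(matrix):
                rows.append({"method": names[rec.algorithm_index], "seed": s,
                             "exam_type": pair.exam_type, "scan_id": rec.scan_id, "rfs": rec.rfs})
    return pd.DataFrame(rows)


def run_benchmark(config: RunConfig):
    """The full pipeline in one call; returns (table, marks, ranks, subsets)."""
    pairs = simulate_dataset(config)
    states = fit_methods(config, pairs)
    denoise_test_set(config, states, pairs)
    records = evaluate_all(config, states, pairs)
    return rank_and_report(config, records)
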