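"""End-to-end experiment orchestration: fit a roster of response models, evaluate, report.

``run_experiment`` ties the library together the way the full analysis is
meant to be run: generate (or load) a block-structured dataset, fit every
response model in the roster per voxel group, score them on the test blocks,
estimate noise ceilings from the test repeats, compare the best recurrent
and best feedforward model (bootstrap CI + threshold partition), run the
permutation test for the feedforward models, probe the recurrent models for
voxel-specific HRFs, and summarise internal representations (RDMs, optimal
lags). Results are returned as an :class:`ExperimentReport` and, when an
output directory is given, written as TSV/HDF5/JSON files, each stamped with
a checksum of the configuration that produced it.

Model names follow the family conventions: ``R-C``, ``R-CTD``, ``R-F`` for
the ridge family and ``L-10`` ... ``G-100`` for LSTM/GRU models of a given
hidden-layer size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import evaluate, probe, represent
from .data import EncodingDataset, load_dataset, split_validation
from .ridge import fit_ridge_from_dataset
from .rnn import TrainConfig, forward, init_model, train
from .synthetic import GroundTruth, SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "ExperimentReport", "StageError", "run_experiment", "fit_model"]

RIDGE_NAMES = ("R-C", "R-CTD", "R-F")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experiment run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    dataset_path: str | None = None  # load instead of simulate when set
    models: tuple[str, ...] = ("R-C", "G-10")
    n_perm: int = 0  # permutation test (feedforward models) when > 0
    n_boot: int = 10000
    alpha: float = 0.05
    threshold: float = 0.1
    tail_seconds: float = 45.0
    rnn: TrainConfig = field(default_factory=TrainConfig)
    n_ceiling_sim: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("model roster must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in self.models:
            if name not in RIDGE_NAMES and _parse_rnn_name(name) is None:
                raise ValueError(f"unknown model name {name!r}")

    def checksum(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land must not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_rnn_name(name: str):
    try:
        fam, size = name.split("-")
    except ValueError:
        return None
    if fam not in ("L", "G") or not size.isdigit():
        return None
    return ("LSTM" if fam == "L" else "GRU", int(size))


@dataclass
class ExperimentReport:
    """All artefacts of one run, as in-memory objects."""

    config: RunConfig
    performance: pd.DataFrame  # per-voxel r per model (+ group, ceiling)
    medians: pd.DataFrame  # per group x model: median r, ceiling, corrected
    comparison: dict | None
    permutation: dict
    hrfs: dict  # model -> list[EstimatedHRF]
    delays: pd.DataFrame | None
    rdm_correlations: dict
    lag_profiles: dict
    models: dict  # fitted model objects
    truth: GroundTruth | None
    history: dict  # RNN training histories


def fit_model(
    name: str, dataset: EncodingDataset, config: RunConfig, seed: int
):
    """Fit one roster member; returns (fitted-object-per-group, test r per voxel)."""
    test_pairs = list(dataset.blocks("test"))
    test_Y = np.concatenate([rb.values for _, rb in test_pairs])
    if name in RIDGE_NAMES:
        model, test_pred, _ = fit_ridge_from_dataset(
            dataset, name, config.tail_seconds
        )
        return {"all": model}, evaluate.voxel_performance(test_pred, test_Y), {}
    cell_type, size = _parse_rnn_name(name)
    train_ds, val_ds = split_validation(dataset, config.tail_seconds)
    groups = dataset.group_indices()
    fitted, history = {}, {}
    pred = np.zeros_like(test_Y)
    for gi, (gname, ix) in enumerate(sorted(groups.items())):
        sub_seed = int(np.random.SeedSequence([seed, gi]).generate_state(1)[0] % 2**31)
        model = init_model(
            cell_type, size, dataset.n_features, len(ix), seed=sub_seed, group=gname
        )
        tr = [(fb.values, rb.values[:, ix]) for fb, rb in train_ds.blocks("train")]
        va = [(fb.values, rb.values[:, ix]) for fb, rb in val_ds.blocks("validation")]
        model, hist = train(model, tr, va, config.rnn, seed=sub_seed)
        fitted[gname] = model
        history[gname] = hist
        offset = 0
        for fb, rb in test_pairs:
            pred[offset : offset + fb.n_samples, ix] = forward(model, fb.values)[0]
            offset += fb.n_samples
    return fitted, evaluate.voxel_performance(pred, test_Y), history


def run_experiment(config: RunConfig) -> ExperimentReport:
    """Run the full protocol described in the module docstring."""

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    truth = None
    with stage("dataset"):
        if config.dataset_path:
            dataset = load_dataset(config.dataset_path)
        else:
            dataset, truth = generate_dataset(config.synthetic, seed=config.seed)

    with stage("noise_ceiling"):
        rep_stacks = [
            rb.repeats for _, rb in dataset.blocks("test") if rb.repeats is not None
        ]
        if rep_stacks:
            ceiling = evaluate.noise_ceiling(
                np.concatenate(rep_stacks, axis=1),
                n_sim=config.n_ceiling_sim,
                seed=config.seed,
            )
        else:
            ceiling = np.full(dataset.n_voxels, np.nan)

    perf = pd.DataFrame({"group": list(dataset.voxel_groups), "ceiling": ceiling})
    fitted_models, histories = {}, {}
    with stage("fit"):
        for mi, name in enumerate(config.models):
            fitted, r, hist = fit_model(name, dataset, config, seed=config.seed + 1000 * mi)
            fitted_models[name] = fitted
            histories[name] = hist
            perf[name] = r

    groups = dataset.group_indices()
    with stage("aggregate"):
        rows = []
        for gname, ix in sorted(groups.items()):
            med_ceiling = float(np.median(ceiling[ix]))
            for name in config.models:
                med_r = float(np.median(perf[name].values[ix]))
                rows.append(
                    {
                        "group": gname,
                        "model": name,
                        "median_r": med_r,
                        "median_ceiling": med_ceiling,
                        "corrected_median_r": evaluate.ceiling_correct(med_r, med_ceiling)
                        if np.isfinite(med_ceiling)
                        else float("nan"),
                    }
                )
        medians = pd.DataFrame(rows)

    comparison = None
    with stage("compare"):
        rnn_names = [m for m in config.models if m not in RIDGE_NAMES]
        ridge_names = [m for m in config.models if m in RIDGE_NAMES]
        if rnn_names and ridge_names:
            best_rnn = max(rnn_names, key=lambda n: perf[n].median())
            best_ridge = max(ridge_names, key=lambda n: perf[n].median())
            boot = evaluate.bootstrap_compare(
                perf[best_rnn].values,
                perf[best_ridge].values,
                n_boot=config.n_boot,
                alpha=config.alpha,
                seed=config.seed,
            )
            thresh = evaluate.threshold_diff_analysis(
                perf[best_rnn].values, perf[best_ridge].values, config.threshold
            )
            comparison = {
                "model_a": best_rnn,
                "model_b": best_ridge,
                "bootstrap": boot,
                "threshold": thresh,
            }

    permutation = {}
    with stage("permutation"):
        if config.n_perm > 0:
            test_pairs = list(dataset.blocks("test"))
            test_Y = np.concatenate([rb.values for _, rb in test_pairs])
            for name in config.models:
                if name not in RIDGE_NAMES:
                    continue  # retraining an RNN per permutation is out of scale here

                def score(ds, _name=name):
                    _, pred, obs = fit_ridge_from_dataset(ds, _name, config.tail_seconds)
                    return evaluate.voxel_performance(pred, obs)

                permutation[name] = evaluate.permutation_test(
                    score, dataset, n_perm=config.n_perm, alpha=config.alpha, seed=config.seed
                )

    hrfs, delay_rows = {}, []
    with stage("probe_hrf"):
        n_test = int(sum(fb.n_samples for fb, _ in dataset.blocks("test")))
        best_r = perf[list(config.models)].max(axis=1).values
        selected = probe.select_voxels_for_hrf(best_r, n_test, config.alpha)
        for name in config.models:
            if name in RIDGE_NAMES:
                continue
            estimates = []
            for gname, model in sorted(fitted_models[name].items()):
                ix = groups[gname]
                ests = probe.estimate_hrfs(model, sampling_interval=dataset.sampling_interval)
                for local, est in enumerate(ests):
                    voxel = int(ix[local])
                    est = dataclasses.replace(est, voxel=voxel)
                    estimates.append(est)
                    if voxel in selected:
                        delay_rows.append(
                            {
                                "model": name,
                                "voxel": voxel,
                                "group": gname,
                                "delay_response": est.delay_response,
                                "delay_undershoot": est.delay_undershoot,
                                "degenerate": est.degenerate,
                            }
                        )
            hrfs[name] = estimates
    delays = pd.DataFrame(delay_rows) if delay_rows else None

    rdm_correlations, lag_profiles = {}, {}
    with stage("representation"):
        for name in config.models:
            if name in RIDGE_NAMES or not fitted_models[name]:
                continue
            per_stage = {s: [] for s in ("features", "layer1", "layer2", "predictions")}
            lag_l1, lag_l2 = [], []
            for gname, model in sorted(fitted_models[name].items()):
                pairs1, pairs2 = [], []
                min_T = None
                for bi, (fb, _) in enumerate(dataset.blocks("test")):
                    pred, h1, h2 = forward(model, fb.values)
                    if bi == 0:  # one block's RDMs per group is representative
                        step = max(1, fb.n_samples // 60)  # keep RDMs tractable
                        sl = slice(0, fb.n_samples, step)
                        per_stage["features"].append(
                            represent.compute_rdm(fb.values[sl], "features")
                        )
                        per_stage["layer1"].append(represent.compute_rdm(h1[sl], "layer1"))
                        per_stage["layer2"].append(represent.compute_rdm(h2[sl], "layer2"))
                        per_stage["predictions"].append(
                            represent.compute_rdm(pred[sl], "predictions")
                        )
                    pairs1.append((h1, fb.values))
                    pairs2.append((h2, fb.values))
                    min_T = fb.n_samples if min_T is None else min(min_T, fb.n_samples)
                max_lag = min(20, min_T - 1)
                lag_l1.append(represent.pooled_optimal_lags(pairs1, max_lag))
                lag_l2.append(represent.pooled_optimal_lags(pairs2, max_lag))
            avg = {s: represent.average_rdms(v) for s, v in per_stage.items() if v}
            rdm_correlations[name] = {
                f"{a}~{b}": represent.rdm_correlation(avg[a], avg[b])
                for a, b in (
                    ("features", "layer1"),
                    ("features", "layer2"),
                    ("layer1", "layer2"),
                    ("layer1", "predictions"),
                    ("layer2", "predictions"),
                )
            }
            lag_profiles[name] = {"layer1": lag_l1, "layer2": lag_l2}

    report = ExperimentReport(
        config=config,
        performance=perf,
        medians=medians,
        comparison=comparison,
        permutation=permutation,
        hrfs=hrfs,
        delays=delays,
        rdm_correlations=rdm_correlations,
        lag_profiles=lag_profiles,
        models=fitted_models,
        truth=truth,
        history=histories,
    )
    if config.out_dir:
        with stage("write"):
            _write_report(report)
    return report


def _write_report(report: ExperimentReport) -> None:
    out = pathlib.Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksum = report.config.checksum()

    def _tsv(df: pd.DataFrame, name: str):
        with open(out / name, "w") as fh:
            fh.write(f"# config_sha256={checksum}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    _tsv(report.performance, "performance.tsv")
    _tsv(report.medians, "group_medians.tsv")
    if report.delays is not None:
        _tsv(report.delays, "delays.tsv")

    summary = {"config_sha256": checksum, "models": list(report.config.models)}
    if report.comparison:
        boot = report.comparison["bootstrap"]
        thr = report.comparison["threshold"]
        summary["comparison"] = {
            "model_a": report.comparison["model_a"],
            "model_b": report.comparison["model_b"],
            "delta_median": boot.delta_median,
            "ci": [boot.ci_low, boot.ci_high],
            "significant": boot.significant,
            "fraction_differing": thr.fraction_differing,
            "fraction_favoring_a": thr.fraction_favoring_a,
        }
    summary["permutation"] = {
        name: {"p": res.p, "label": res.label, "significant": res.significant}
        for name, res in report.permutation.items()
    }
    summary["rdm_correlations"] = report.rdm_correlations
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)

    if report.hrfs:
        with h5py.File(out / "hrfs.h5", "w") as f:
            f.attrs["config_sha256"] = checksum
            for name, estimates in report.hrfs.items():
                g = f.create_group(name)
                for est in estimates:
                    d = g.create_dataset(f"voxel{est.voxel:05d}", data=est.samples)
                    d.attrs["degenerate"] = est.degenerate
                    if est.delay_response is not None:
                        d.attrs["delay_response"] = est.delay_response
                    if est.delay_undershoot is not None:
                        d.attrs["delay_undershoot"] = est.delay_undershoot

    log = {
        "config_sha256": checksum,
        "seed": report.config.seed,
        "config": dataclasses.asdict(report.config),
    }
    with open(out / "log.jsonl", "w") as fh:
        fh.write(json.dumps(log, sort_keys=True, default=str) + "\n")
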