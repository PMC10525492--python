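"""End-to-end experiment drivers: detection CV, sampling-rate sweep,
electrode-count comparison, and the interpretability bundle.

Each driver takes an :class:`ExperimentConfig`, derives every random stream
from the single global seed, writes its artifacts (JSON reports, CSV tables,
PNG figures, model checkpoints) under the output directory, and skips stages
whose configuration hash already matches a completed run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .evaluation import (
    FoldSummary, binary_metrics, confusion_matrix, multigroup_metrics,
)
from .io_formats import BACKGROUND_LABEL, Montage, STANDARD_21
from .models import (
    TrainingConfig, build_binary_cnn, build_multigroup_model, save_model,
    train_model,
)
from .preprocessing import (
    SplitSpec, class_weights, extract_windows, fir_lowpass, kfold_indices,
    make_splits, resample, stft_tensor,
)
from .synthetic import CohortConfig, default_signatures, simulate_cohort

logger = logging.getLogger("ictalkit")

__all__ = [
    "ExperimentConfig",
    "preprocess_cohort",
    "run_detection",
    "run_sr_sweep",
    "run_electrode_comparison",
    "run_interpretability",
]


@dataclass
class ExperimentConfig:
    """All knobs of the pipeline in one (YAML-serializable) place."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fir_cutoff_hz: float = 40.0
    target_hz: float = 250.0
    window_s: float = 1.0
    nfft: int = 64
    k_folds: int = 5
    binary_epochs: int = 20
    multigroup_epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    mi_windows: int = 1000
    mi_runs: int = 100
    am_runs: int = 100
    am_steps: int = 256
    sweep_rates: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 250.0)
    out_dir: str = "ictalkit_out"
    seed: int = 0

    def __post_init__(self):
        if any(r > self.cohort.sampling_rate_hz for r in self.sweep_rates):
            raise ValueError("sweep rates must not exceed the cohort rate")
        if self.target_hz > self.cohort.sampling_rate_hz:
            raise ValueError("target rate must not exceed the cohort rate")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        for k in ("sweep_rates",):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# stage bookkeeping
# ---------------------------------------------------------------------------


def _key_hash(key: dict) -> str:
    return hashlib.sha256(
        json.dumps(key, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage(out_dir, name, key: dict, fn):
    """Run ``fn`` unless a completed stage with the same config hash exists."""
    os.makedirs(out_dir, exist_ok=True)
    marker = os.path.join(out_dir, f"{name}.stage.json")
    h = _key_hash(key)
    if os.path.exists(marker):
        with open(marker) as fh:
            stored = json.load(fh)
        if stored.get("hash") == h:
            logger.info("stage %s: up to date, skipping", name)
            return stored["result"]
    t0 = time.time()
    logger.info("stage %s: running", name)
    result = fn()
    with open(marker, "w") as fh:
        json.dump({"hash": h, "elapsed_s": time.time() - t0, "result": result},
                  fh, indent=2, default=str)
    logger.info("stage %s: done in %.1f s", name, time.time() - t0)
    return result


# ---------------------------------------------------------------------------
# shared preprocessing
# ---------------------------------------------------------------------------


def preprocess_cohort(
    cohort, fir_cutoff_hz=40.0, target_hz=250.0, window_s=1.0, nfft=64,
    montage: Montage | None = None,
):
    """Filter, resample, window and transform a cohort.

    Returns ``(windows, tensors, labels)`` with tensors stacked as an array.
    """
    windows = []
    for rec, ann in cohort:
        if montage is not None:
            from .io_formats import select_channels

            rec = select_channels(rec, montage)
        rec = fir_lowpass(rec, fir_cutoff_hz)
        rec = resample(rec, target_hz)
        windows.extend(extract_windows(rec, ann, window_s))
    tensors = np.stack([stft_tensor(w, nfft).values for w in windows])
    labels = [w.label for w in windows]
    return windows, tensors, labels


def _binary(labels):
    return [BACKGROUND_LABEL if l == BACKGROUND_LABEL else "seiz" for l in labels]


def _train_cfg(cfg, epochs, labels, seed):
    return TrainingConfig(
        epochs=epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, class_weights=class_weights(labels),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def run_detection(cfg: ExperimentConfig) -> dict:
    """Cohort -> preprocessing -> k-fold binary CV -> fold-aggregated metrics."""

    def _run():
        cohort = simulate_cohort(cfg.cohort)
        windows, tensors, labels = preprocess_cohort(
            cohort, cfg.fir_cutoff_hz, cfg.target_hz, cfg.window_s, cfg.nfft
        )
        yb = _binary(labels)
        folds = kfold_indices(windows, k=cfg.k_folds, seed=cfg.seed)
        per_fold: dict[str, list[float]] = {}
        n_ch = tensors.shape[1]
        for fi, (tr, te) in enumerate(folds):
            tc = _train_cfg(cfg, cfg.binary_epochs, [yb[i] for i in tr],
                            cfg.seed + fi)
            model = build_binary_cnn((n_ch, 33, 8), seed=cfg.seed + fi,
                                     class_labels=("bckg", "seiz"))
            train_model(model, (tensors[tr], [yb[i] for i in tr]), None, tc)
            pred = model.predict(tensors[te])
            counts, _ = confusion_matrix([yb[i] for i in te], pred,
                                         labels=("bckg", "seiz"))
            rep = binary_metrics(counts, positive_index=1)
            for m, v in rep.metrics.items():
                per_fold.setdefault(m, []).append(v)
            if fi == 0:
                save_model(model, os.path.join(cfg.out_dir, "binary_fold0.npz"))
        summary = FoldSummary(per_fold)
        result = {
            "per_fold": per_fold,
            "summary": {m: list(v) for m, v in summary.summary().items()},
        }
        with open(os.path.join(cfg.out_dir, "detection_report.json"), "w") as fh:
            json.dump(result, fh, indent=2)
        return result

    key = {"cfg": cfg.to_dict(), "stage": "detection"}
    return _stage(cfg.out_dir, "detection", key, _run)


def run_sr_sweep(cfg: ExperimentConfig, rates=None,
                 tasks=("binary", "multigroup")) -> dict:
    """Train the selected models at each sampling rate; one report per rate
    per model."""
    rates = tuple(rates or cfg.sweep_rates)
    if list(rates) != sorted(rates):
        raise ValueError("rates must be sorted ascending")
    if any(r > cfg.cohort.sampling_rate_hz for r in rates):
        raise ValueError("rate above the cohort sampling rate")

    def _run():
        cohort = simulate_cohort(cfg.cohort)
        out: dict = {}
        for rate in rates:
            windows, tensors, labels = preprocess_cohort(
                cohort, cfg.fir_cutoff_hz, rate, cfg.window_s, cfg.nfft
            )
            n_ch = tensors.shape[1]
            entry: dict = {"tensor_shape": list(tensors.shape[1:])}
            if "binary" in tasks:
                yb = _binary(labels)
                tr, va, te = make_splits(windows, SplitSpec(seed=cfg.seed))
                tc = _train_cfg(cfg, cfg.binary_epochs, [yb[i] for i in tr],
                                cfg.seed)
                model = build_binary_cnn((n_ch, 33, 8), seed=cfg.seed)
                train_model(model, (tensors[tr], [yb[i] for i in tr]), None, tc)
                counts, _ = confusion_matrix(
                    [yb[i] for i in te], model.predict(tensors[te]),
                    labels=("bckg", "seiz"),
                )
                entry["binary"] = binary_metrics(counts).metrics
            if "multigroup" not in tasks:
                out[str(int(rate))] = entry
                continue
            # multigroup on seizure windows only
            sz = [i for i, l in enumerate(labels) if l != BACKGROUND_LABEL]
            sz_windows = [windows[i] for i in sz]
            sz_labels = [labels[i] for i in sz]
            classes = tuple(sorted(set(sz_labels)))
            trs, vas, tes = make_splits(sz_windows, SplitSpec(seed=cfg.seed))
            from .models import MultigroupConfig

            mg = build_multigroup_model(
                (n_ch, 33, 8), MultigroupConfig(n_out=len(classes)),
                seed=cfg.seed, class_labels=classes,
            )
            tcm = _train_cfg(cfg, cfg.multigroup_epochs,
                             [sz_labels[i] for i in trs], cfg.seed)
            train_model(mg, (tensors[sz][trs], [sz_labels[i] for i in trs]),
                        None, tcm)
            counts, _ = confusion_matrix(
                [sz_labels[i] for i in tes], mg.predict(tensors[sz][tes]),
                labels=classes,
            )
            entry["multigroup"] = multigroup_metrics(counts, classes).metrics
            out[str(int(rate))] = entry
        with open(os.path.join(cfg.out_dir, "sr_sweep_report.json"), "w") as fh:
            json.dump(out, fh, indent=2)
        return out

    key = {"cfg": cfg.to_dict(), "rates": list(rates), "tasks": list(tasks),
           "stage": "sr_sweep"}
    return _stage(cfg.out_dir, "sr_sweep", key, _run)


def run_electrode_comparison(cfg: ExperimentConfig, min_electrodes=8,
                             ablate=True, tasks=("binary", "multigroup")) -> dict:
    """MI ablation curve plus the fixed 21-vs-8 montage comparison."""
    from .electrode_importance import ablation_experiment, fixed_reduced_comparison

    def _run():
        cohort = simulate_cohort(cfg.cohort)
        windows, _, _ = preprocess_cohort(
            cohort, cfg.fir_cutoff_hz, cfg.target_hz, cfg.window_s, cfg.nfft
        )
        tc = TrainingConfig(epochs=cfg.binary_epochs, batch_size=cfg.batch_size,
                            learning_rate=cfg.learning_rate, seed=cfg.seed)
        result: dict = {}
        if ablate:
            rows = ablation_experiment(
                windows, STANDARD_21, min_electrodes, tc,
                mi_windows=min(cfg.mi_windows, len(windows)),
                mi_runs=max(1, cfg.mi_runs // 20), seed=cfg.seed,
            )
            result["ablation"] = [
                {"n_electrodes": r["n_electrodes"],
                 "montage": list(r["montage"]),
                 "metrics": r["report"].metrics}
                for r in rows
            ]
        comp = fixed_reduced_comparison(windows, tc, k=cfg.k_folds,
                                        seed=cfg.seed, tasks=tasks)
        result["folds"] = {
            f"{t}/{m}": fs.raw for (t, m), fs in comp["folds"].items()
        }
        result["comparison"] = comp["comparison"]
        with open(os.path.join(cfg.out_dir, "electrode_report.json"), "w") as fh:
            json.dump(result, fh, indent=2, default=float)
        return result

    key = {"cfg": cfg.to_dict(), "min_electrodes": min_electrodes,
           "ablate": ablate, "tasks": list(tasks), "stage": "electrodes"}
    return _stage(cfg.out_dir, "electrodes", key, _run)


def run_interpretability(cfg: ExperimentConfig, binary_model, multigroup_model,
                         cohort=None) -> dict:
    """AM panels (2 binary + one per type), MI topoplots, dSPM maps."""
    from .electrode_importance import mi_scores
    from .interpretability import (
        activation_maximization, am_panel_grid, channel_energy, render_topomap,
        topoplot,
    )
    from .source_reconstruction import (
        build_toy_forward, dspm_inverse, estimate_noise_cov, lateralization_index,
        onset_average,
    )

    os.makedirs(cfg.out_dir, exist_ok=True)
    if binary_model is None or multigroup_model is None:
        raise ValueError("trained checkpoints are required")
    cohort = cohort or simulate_cohort(cfg.cohort)
    montage = STANDARD_21
    result: dict = {}

    # --- activation maximization: 2 binary + one panel per seizure type
    patterns = []
    for ci, lab in enumerate(binary_model.class_labels):
        patterns.append(
            activation_maximization(binary_model, ci, n_runs=cfg.am_runs,
                                    steps=cfg.am_steps, seed=cfg.seed + ci)
        )
    for ci, lab in enumerate(multigroup_model.class_labels):
        patterns.append(
            activation_maximization(multigroup_model, ci, n_runs=cfg.am_runs,
                                    steps=cfg.am_steps, seed=cfg.seed + 100 + ci)
        )
    am_panel_grid(patterns, montage.names, montage,
                  path=os.path.join(cfg.out_dir, "am_panels.png"))
    np.savez_compressed(
        os.path.join(cfg.out_dir, "am_patterns.npz"),
        **{p.class_label: p.pattern for p in patterns},
    )
    result["am_panels"] = [p.class_label for p in patterns]
    result["am_final_activation"] = {
        p.class_label: p.final_activation for p in patterns
    }

    # --- MI topoplots per task
    windows, _, labels = preprocess_cohort(
        cohort, cfg.fir_cutoff_hz, cfg.target_hz, cfg.window_s, cfg.nfft
    )
    for task, labs in (("binary", _binary(labels)), ("multigroup", labels)):
        if task == "multigroup":
            keep = [i for i, l in enumerate(labels) if l != BACKGROUND_LABEL]
            data = np.stack([windows[i].data for i in keep])
            labs = [labels[i] for i in keep]
        else:
            data = np.stack([w.data for w in windows])
        rank = mi_scores(
            data, labs, n_windows=min(cfg.mi_windows, data.shape[0]),
            n_runs=max(1, cfg.mi_runs // 10), seed=cfg.seed,
            electrode_names=montage.names,
        )
        tm = topoplot(rank.normalized, montage)
        render_topomap(tm, os.path.join(cfg.out_dir, f"mi_topoplot_{task}.png"),
                       title=f"MI ({task})")
        result[f"mi_ranking_{task}"] = rank.ranked

    # --- dSPM maps per seizure type
    fwd = build_toy_forward(montage, seed=cfg.seed)
    sr = cfg.cohort.sampling_rate_hz
    dspm_summary = {}
    for sig in default_signatures(montage):
        found = None
        for rec, ann in cohort:
            for ev in ann.seizure_events():
                if ev.label == sig.label and ev.start_s >= 0.1:
                    found = (rec, ev)
                    break
            if found:
                break
        if not found:
            continue
        rec, ev = found
        cov = estimate_noise_cov(rec, ev.start_s)
        seg = rec.crop(ev.start_s, min(ev.stop_s, ev.start_s + 2.0))
        times = np.arange(seg.data.shape[1]) / sr
        est = dspm_inverse(fwd, cov, seg.data, times=times)
        amap = onset_average(est, (0.0, 2.0))
        li = lateralization_index(amap, fwd.source_space)
        dspm_summary[sig.label] = {**li, "focal": sig.focal}
        rows = np.column_stack(
            [fwd.source_space.positions,
             (fwd.source_space.hemisphere == "L").astype(float), amap]
        )
        np.savetxt(
            os.path.join(cfg.out_dir, f"dspm_{sig.label}.csv"), rows,
            delimiter=",", header="x,y,z,is_left,dspm", comments="",
        )
    result["dspm"] = dspm_summary
    with open(os.path.join(cfg.out_dir, "interpretability_report.json"), "w") as fh:
        json.dump(result, fh, indent=2, default=float)
    return result
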