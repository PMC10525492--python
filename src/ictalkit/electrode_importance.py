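"""Mutual-information electrode ranking and electrode-count experiments.

Each electrode's informative value is the mutual information between its raw
sample values and the window label, estimated per time index with an
equal-frequency 8-bin histogram (scale-invariant by construction), averaged
over time indices, windows subsamples, and repeated runs. The ablation
experiment retrains the binary detector while repeatedly dropping the
electrode with the minimal MI score; the fixed comparison contrasts the full
21-electrode montage against the reduced 8-electrode set under k-fold
cross-validation with the statistical tests from :mod:`ictalkit.evaluation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .evaluation import (
    FoldSummary,
    binary_metrics,
    compare_montages,
    confusion_matrix,
    multigroup_metrics,
)
from .io_formats import BACKGROUND_LABEL, Montage, REDUCED_8, STANDARD_21

__all__ = [
    "MIRanking",
    "mi_scores",
    "normalize_scores",
    "ablation_experiment",
    "fixed_reduced_comparison",
]


@dataclass
class MIRanking:
    electrodes: tuple[str, ...]
    raw: dict[str, float]
    normalized: dict[str, float]
    ranked: list[str]  # descending informative value

    def to_rows(self) -> list[dict]:
        return [
            {
                "electrode": e,
                "raw_mi": self.raw[e],
                "normalized_mi": self.normalized[e],
                "rank": r + 1,
            }
            for r, e in enumerate(self.ranked)
        ]


def normalize_scores(raw) -> dict[str, float] | np.ndarray:
    """Min-max map to [0, 1]; an all-equal input maps to all zeros."""
    if isinstance(raw, dict):
        vals = normalize_scores(np.array(list(raw.values()), dtype=float))
        return dict(zip(raw.keys(), (float(v) for v in vals)))
    x = np.asarray(raw, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one score")
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _equal_frequency_bins(x2: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based binning per column: (n, m) values -> integer bins."""
    n = x2.shape[0]
    order = np.argsort(x2, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[:, None], axis=0)
    return (ranks * n_bins) // n


def _discrete_mi(bins: np.ndarray, y: np.ndarray, n_bins: int, n_y: int):
    """MI(column bin; label) in nats for every column at once."""
    n, m = bins.shape
    code = (y[:, None] * n_bins + bins) + np.arange(m)[None, :] * (n_bins * n_y)
    counts = np.bincount(code.ravel(), minlength=m * n_bins * n_y).reshape(
        m, n_y, n_bins
    )
    p = counts / n
    py = p.sum(axis=2, keepdims=True)
    pb = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (py * pb))
    return np.nansum(term, axis=(1, 2))


def mi_scores(
    windows,
    labels=None,
    n_windows: int = 1000,
    n_runs: int = 100,
    seed: int = 0,
    n_bins: int = 8,
    electrode_names=None,
) -> MIRanking:
    """Rank electrodes by MI between raw window samples and window labels.

    ``windows`` is either an array (n, n_electrodes, n_samples) with
    ``labels`` given separately, or a list of LabeledWindow. Per run,
    ``n_windows`` windows are drawn without replacement; MI is estimated per
    electrode and time index with equal-frequency binning, averaged over
    time, then over runs.
    """
    if labels is None:
        labels = [w.label for w in windows]
        if electrode_names is None and getattr(windows[0], "channel_names", None):
            electrode_names = windows[0].channel_names
        windows = np.stack([w.data for w in windows])
    x = np.asarray(windows, dtype=float)
    n, n_el, n_t = x.shape
    if electrode_names is None:
        electrode_names = tuple(f"ch{i}" for i in range(n_el))
    electrode_names = tuple(electrode_names)
    if n_windows > n:
        raise ValueError(f"n_windows={n_windows} exceeds available {n}")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    y_all = np.array([uniq.index(l) for l in labels])

    rng = np.random.default_rng(seed)
    acc = np.zeros(n_el)
    for _ in range(n_runs):
        idx = rng.choice(n, size=n_windows, replace=False)
        x2 = x[idx].reshape(n_windows, n_el * n_t)
        bins = _equal_frequency_bins(x2, n_bins)
        mi = _discrete_mi(bins, y_all[idx], n_bins, len(uniq))
        acc += mi.reshape(n_el, n_t).mean(axis=1)
    raw_arr = acc / n_runs
    # a constant electrode has a single occupied bin -> exactly zero MI
    const = np.ptp(x, axis=(0, 2)) == 0
    raw_arr[const] = 0.0
    raw = dict(zip(electrode_names, (float(v) for v in raw_arr)))
    norm = normalize_scores(raw)
    ranked = sorted(electrode_names, key=lambda e: -raw[e])
    return MIRanking(electrode_names, raw, norm, ranked)


# ---------------------------------------------------------------------------
# Montage experiments
# ---------------------------------------------------------------------------


def _binary_labels(labels):
    return ["bckg" if l == BACKGROUND_LABEL else "seiz" for l in labels]


def _subset_window_data(windows, names):
    idx = [windows[0].channel_names.index(n) for n in names]
    return np.stack([w.data[idx] for w in windows])


def _train_eval_binary(windows, names, train_idx, test_idx, tcfg, seed):
    from .models import TrainingConfig, build_binary_cnn, train_model
    from .preprocessing import class_weights, stft_tensor

    x = _subset_window_data(windows, names)
    from .preprocessing import LabeledWindow

    tensors = np.stack(
        [
            stft_tensor(
                LabeledWindow(x[i], windows[i].label, windows[i].subject_id,
                              windows[i].event_index)
            ).values
            for i in range(len(windows))
        ]
    )
    yb = _binary_labels([w.label for w in windows])
    cw = class_weights([yb[i] for i in train_idx])
    tcfg = TrainingConfig(
        epochs=tcfg.epochs, batch_size=tcfg.batch_size,
        learning_rate=tcfg.learning_rate, class_weights=cw, seed=tcfg.seed,
    )
    model = build_binary_cnn((len(names), 33, 8), seed=seed)
    train_model(model, (tensors[train_idx], [yb[i] for i in train_idx]), None, tcfg)
    pred = model.predict(tensors[test_idx])
    counts, _ = confusion_matrix(
        [yb[i] for i in test_idx], pred, labels=("bckg", "seiz")
    )
    return binary_metrics(counts, positive_index=1)


def ablation_experiment(
    windows,
    montage: Montage = STANDARD_21,
    min_electrodes: int = 8,
    train_cfg=None,
    mi_windows: int = 200,
    mi_runs: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Drop the minimum-MI electrode step by step, retraining the detector.

    ``windows`` are time-domain LabeledWindows over the full montage. Returns
    one row per montage size from ``len(montage.names)`` down to
    ``min_electrodes`` with the montage used and its test metrics.
    """
    from .models import TrainingConfig
    from .preprocessing import SplitSpec, make_splits

    if min_electrodes < 2:
        raise ValueError("min_electrodes must be >= 2")
    train_cfg = train_cfg or TrainingConfig(epochs=3, seed=seed)
    names = list(montage.names)
    yb = _binary_labels([w.label for w in windows])
    tr, va, te = make_splits(windows, SplitSpec(train=0.7, val=0.1, test=0.2,
                                                seed=seed))
    test_idx = sorted(va + te)
    rows = []
    step = 0
    while len(names) >= min_electrodes:
        x = _subset_window_data(windows, names)
        ranking = mi_scores(
            x, yb, n_windows=min(mi_windows, x.shape[0]), n_runs=mi_runs,
            seed=seed + step, electrode_names=names,
        )
        report = _train_eval_binary(windows, names, tr, test_idx, train_cfg,
                                    seed=seed + step)
        rows.append(
            {"n_electrodes": len(names), "montage": tuple(names),
             "report": report, "ranking": ranking}
        )
        if len(names) == min_electrodes:
            break
        names.remove(ranking.ranked[-1])
        step += 1
    return rows


def fixed_reduced_comparison(
    windows,
    train_cfg=None,
    k: int = 5,
    seed: int = 0,
    montages: dict[str, Montage] | None = None,
    tasks=("binary", "multigroup"),
) -> dict:
    """21- vs 8-electrode montage, both tasks, k-fold CV + statistics.

    Returns per (task, montage) a FoldSummary of per-fold metrics and, per
    task and metric, the Welch / Mann-Whitney comparison across montages.
    """
    from .models import (
        TrainingConfig, build_binary_cnn, build_multigroup_model, train_model,
    )
    from .preprocessing import class_weights, kfold_indices, stft_tensor

    train_cfg = train_cfg or TrainingConfig(epochs=3, seed=seed)
    montages = montages or {"standard21": STANDARD_21, "reduced8": REDUCED_8}
    out: dict = {"folds": {}, "comparison": {}}
    for task in tasks:
        if task == "binary":
            task_windows = list(windows)
            get_labels = lambda ws: _binary_labels([w.label for w in ws])
        else:
            task_windows = [w for w in windows if w.label != BACKGROUND_LABEL]
            get_labels = lambda ws: [w.label for w in ws]
        labels_all = get_labels(task_windows)
        class_set = tuple(sorted(set(labels_all)))
        folds = kfold_indices(task_windows, k=k, seed=seed)
        for mname, montage in montages.items():
            per_fold: dict[str, list[float]] = {}
            for fi, (tr, te) in enumerate(folds):
                x = _subset_window_data(task_windows, montage.names)
                from .preprocessing import LabeledWindow

                tensors = np.stack(
                    [
                        stft_tensor(LabeledWindow(x[i], labels_all[i], "", 0)).values
                        for i in range(len(task_windows))
                    ]
                )
                cw = class_weights([labels_all[i] for i in tr])
                tc = TrainingConfig(
                    epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
                    learning_rate=train_cfg.learning_rate, class_weights=cw,
                    seed=seed + fi,
                )
                shape = (len(montage.names), 33, 8)
                if task == "binary":
                    model = build_binary_cnn(shape, seed=seed + fi,
                                             class_labels=class_set)
                else:
                    from .models import MultigroupConfig

                    model = build_multigroup_model(
                        shape,
                        MultigroupConfig(n_out=len(class_set)),
                        seed=seed + fi, class_labels=class_set,
                    )
                train_model(model, (tensors[tr], [labels_all[i] for i in tr]),
                            None, tc)
                pred = model.predict(tensors[te])
                counts, _ = confusion_matrix([labels_all[i] for i in te], pred,
                                             labels=class_set)
                if task == "binary":
                    rep = binary_metrics(counts, positive_index=class_set.index("seiz"))
                else:
                    rep = multigroup_metrics(counts, labels=class_set)
                for metric, value in rep.metrics.items():
                    per_fold.setdefault(metric, []).append(value)
            out["folds"][(task, mname)] = FoldSummary(per_fold)
        m0, m1 = list(montages)
        out["comparison"][task] = {}
        for metric in out["folds"][(task, m0)].raw:
            a = out["folds"][(task, m0)].raw[metric]
            b = out["folds"][(task, m1)].raw[metric]
            if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out["comparison"][task][metric] = compare_montages(a, b)
    return out
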