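"""Activation maximization and scalp topographic maps.

Activation maximization ascends the pre-softmax logit of a target class with
respect to the model input (softmax itself is avoided because its saturation
kills gradients), starting from small Gaussian noise, with an L2 penalty to
keep patterns bounded and backtracking step halving so the objective is
non-decreasing over accepted steps. Patterns from independent runs are
averaged. Per-electrode energies of the resulting pattern are projected onto
a schematic head with radial-basis interpolation (the classic topoplot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Montage, STANDARD_21

__all__ = [
    "AMPattern",
    "TopoMap",
    "activation_maximization",
    "channel_energy",
    "topoplot",
    "render_topomap",
    "am_panel_grid",
]


@dataclass
class AMPattern:
    class_label: str
    pattern: np.ndarray  # model input shape
    n_runs: int
    final_activation: float  # mean final objective over runs
    initial_activation: float = float("nan")  # mean objective at initialization


@dataclass
class TopoMap:
    values: dict[str, float]  # per-electrode, in [0, 1]
    grid: np.ndarray  # (res, res), NaN outside the head circle
    extent: tuple[float, float, float, float]
    montage: Montage


def activation_maximization(
    model,
    class_index: int,
    n_runs: int = 100,
    steps: int = 256,
    step_size: float = 0.1,
    l2_decay: float = 1e-3,
    seed: int = 0,
    init_scale: float = 0.1,
    max_halvings: int = 10,
    nonnegative: bool = False,
) -> AMPattern:
    """Average gradient-ascent prototype input for one output unit.

    Each run initializes the input from N(0, init_scale^2), maximizes
    ``logit[class_index] - l2_decay * ||x||^2`` for ``steps`` accepted steps
    (step size halved on an objective decrease, up to ``max_halvings``
    times), and the runs' final inputs are averaged. With
    ``nonnegative=True`` the ascent is projected onto x >= 0 after every
    step (and initialized from folded noise), which confines prototypes to
    the model's actual input domain when inputs are spectral magnitudes.
    """
    if not 0 <= class_index < len(model.class_labels):
        raise IndexError(f"class_index {class_index} out of range")
    rng = np.random.default_rng(seed)
    shape = (1,) + tuple(model.input_shape)

    def objective(x):
        logit = model.predict_logits(x)[0, class_index]
        return float(logit - l2_decay * (x**2).sum())

    patterns, finals, initials = [], [], []
    for _ in range(n_runs):
        x = rng.normal(0.0, init_scale, size=shape)
        if nonnegative:
            x = np.abs(x)
        obj = objective(x)
        initials.append(obj)
        eta = step_size
        for _ in range(steps):
            g = model.input_gradient(x, class_index) - 2 * l2_decay * x
            accepted = False
            for _ in range(max_halvings + 1):
                x_new = x + eta * g
                if nonnegative:
                    x_new = np.maximum(x_new, 0.0)
                obj_new = objective(x_new)
                if obj_new >= obj:
                    x, obj, accepted = x_new, obj_new, True
                    break
                eta *= 0.5
            if not accepted:
                break  # converged: no step improves the objective
        patterns.append(x[0])
        finals.append(obj)
    return AMPattern(
        class_label=model.class_labels[class_index],
        pattern=np.mean(patterns, axis=0),
        n_runs=n_runs,
        final_activation=float(np.mean(finals)),
        initial_activation=float(np.mean(initials)),
    )


def channel_energy(p: AMPattern | np.ndarray, channel_names=None) -> dict[str, float]:
    """Per-electrode L2 norm of a pattern over (frequency x time), min-max
    normalized to [0, 1] (all-equal energies map to zero)."""
    pattern = p.pattern if isinstance(p, AMPattern) else np.asarray(p)
    energy = np.sqrt((pattern**2).sum(axis=tuple(range(1, pattern.ndim))))
    lo, hi = energy.min(), energy.max()
    norm = np.zeros_like(energy) if hi - lo == 0 else (energy - lo) / (hi - lo)
    names = channel_names or [f"ch{i}" for i in range(len(energy))]
    return {n: float(v) for n, v in zip(names, norm)}


def topoplot(
    values: dict[str, float],
    montage: Montage = STANDARD_21,
    resolution: int = 64,
) -> TopoMap:
    """Interpolate per-electrode scalars onto a disc grid (head seen from
    above, nose up); thin-plate-spline RBF, NaN-masked outside the circle."""
    from scipy.interpolate import RBFInterpolator

    unknown = sorted(set(values) - set(montage.names))
    if unknown:
        raise ValueError(f"electrodes not in montage: {unknown}")
    names = [n for n in montage.names if n in values]
    pts = np.array([montage.positions_2d[montage.index(n)] for n in names])
    vals = np.array([values[n] for n in names])
    # virtual ring outside the head tames thin-plate extrapolation overshoot;
    # its value (the data minimum) keeps constant maps exactly constant
    ang = np.linspace(0, 2 * np.pi, 17)[:-1]
    ring = 1.25 * np.stack([np.sin(ang), np.cos(ang)], axis=1)
    pts = np.concatenate([pts, ring])
    vals = np.concatenate([vals, np.full(len(ring), vals.min())])
    rbf = RBFInterpolator(pts, vals, kernel="thin_plate_spline")
    lim = 1.1  # A1/A2 project slightly outside the unit circle
    axis = np.linspace(-lim, lim, resolution)
    gx, gy = np.meshgrid(axis, axis)
    flat = np.stack([gx.ravel(), gy.ravel()], axis=1)
    grid = rbf(flat).reshape(resolution, resolution)
    grid[gx**2 + gy**2 > 1.0] = np.nan
    return TopoMap(dict(zip(names, vals.tolist())), grid, (-lim, lim, -lim, lim),
                   montage)


def render_topomap(tm: TopoMap, path=None, ax=None, title: str | None = None):
    """Draw a TopoMap with head circle and electrode markers; save if asked."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(tm.grid, origin="lower", extent=tm.extent, cmap="viridis")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1.5)
    ax.add_patch(circle)
    for name, val in tm.values.items():
        x, y = tm.montage.positions_2d[tm.montage.index(name)]
        ax.plot(x, y, "k.", ms=3)
    ax.set_xticks([]), ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=8)
    if created and path is not None:
        fig = ax.figure
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return ax


def am_panel_grid(patterns: list[AMPattern], channel_names, montage=STANDARD_21,
                  path=None):
    """One topoplot panel per AM pattern (class grid figure)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(patterns)
    ncol = min(n, 5)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow))
    axes = np.atleast_1d(axes).ravel()
    for ax in axes[n:]:
        ax.axis("off")
    for pat, ax in zip(patterns, axes):
        tm = topoplot(channel_energy(pat, channel_names), montage)
        render_topomap(tm, ax=ax, title=pat.class_label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
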