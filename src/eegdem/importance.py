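"""Per-channel importance scores and topographic scalp maps.

Tree ensembles expose impurity-based importances directly; any model with
predictions can be scored by permutation importance (mean accuracy drop when
one channel's column is shuffled).  Scores are normalised to sum to 1 and
rendered on a 10-20 head map with thin-plate-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import feature_columns
from .montage import MontageSpec


@dataclass(frozen=True)
class ChannelImportance:
    scores: dict[str, float]  # channel -> normalised non-negative score
    task: str = ""
    measure: str = ""
    overlap: float | None = None

    def __post_init__(self) -> None:
        vals = np.array(list(self.scores.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("importance scores must be non-negative")
        if vals.size and abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError("importance scores must be normalised to sum 1")

    @property
    def ranking(self) -> list[str]:
        """Channels by descending score; ties broken by montage order."""
        names = list(self.scores)
        return sorted(names, key=lambda n: (-self.scores[n], names.index(n)))

    def scores_array(self, channel_names) -> np.ndarray:
        return np.array([self.scores[n] for n in channel_names], dtype=float)


def _normalise(raw: np.ndarray, channel_names) -> dict[str, float]:
    raw = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = raw.sum()
    if total == 0:
        raw = np.ones_like(raw)  # fully uninformative model -> uniform
        total = raw.sum()
    return {n: float(v / total) for n, v in zip(channel_names, raw)}


def tree_importance(model, channel_names, **context) -> ChannelImportance:
    """Impurity-based importances of a tree ensemble, mapped to channels."""
    if not hasattr(model, "feature_importances_"):
        raise TypeError(
            f"model {type(model).__name__} exposes no feature importances; "
            "use permutation_importance instead"
        )
    raw = np.asarray(model.feature_importances_, dtype=float)
    if raw.size != len(channel_names):
        raise ValueError("importances/channel count mismatch")
    return ChannelImportance(_normalise(raw, channel_names), **context)


def permutation_importance(
    model,
    test_rows: pd.DataFrame,
    metric: str = "accuracy",
    n_repeats: int = 10,
    seed: int = 0,
    **context,
) -> ChannelImportance:
    """Mean accuracy drop per shuffled channel, negatives clipped to zero."""
    from .classify import confusion, metrics

    cols = feature_columns(test_rows)
    X = test_rows[cols].to_numpy(dtype=float)
    y = test_rows["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("permutation importance needs both classes in test rows")

    def score(Xm: np.ndarray) -> float:
        value = metrics(confusion(y, model.predict(Xm)))[metric]
        if value is None:
            raise ValueError(f"metric {metric!r} undefined on these rows")
        return value

    rng = np.random.default_rng(seed)
    baseline = score(X)
    drops = np.zeros(len(cols))
    for j in range(len(cols)):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(y)), j]
            drops[j] += baseline - score(Xp)
    drops /= n_repeats
    return ChannelImportance(_normalise(drops, cols), **context)


def rank_report(imp: ChannelImportance) -> list[dict]:
    """Descending channel ranking with scores, ready for serialisation."""
    return [{"channel": n, "score": imp.scores[n]} for n in imp.ranking]


def _thin_plate_field(
    positions: np.ndarray, values: np.ndarray, grid_n: int = 101
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from scipy.interpolate import RBFInterpolator

    rbf = RBFInterpolator(positions, values, kernel="thin_plate_spline")
    g = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(g, g)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    field = rbf(pts).reshape(grid_n, grid_n)
    field[gx**2 + gy**2 > 1.0] = np.nan  # clip to the head disc
    return gx, gy, field


def interpolate_scalp(imp: ChannelImportance, montage: MontageSpec, grid_n: int = 101):
    """The interpolated scalp field (gx, gy, values), NaN outside the head."""
    values = imp.scores_array(montage.channel_names)
    return _thin_plate_field(montage.positions_array(), values, grid_n)


def render_topomap(imp: ChannelImportance, montage: MontageSpec, out_path) -> None:
    """Head-outline topographic map of the importance scores (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if set(imp.scores) != set(montage.channel_names):
        raise ValueError("importance channels do not match the montage")
    gx, gy, field = interpolate_scalp(imp, montage)
    pos = montage.positions_array()

    fig, ax = plt.subplots(figsize=(5, 5))
    mesh = ax.pcolormesh(gx, gy, field, shading="auto", cmap="viridis")
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="black", lw=1.5)  # head
    ax.plot([-0.1, 0.0, 0.1], [0.995, 1.1, 0.995], color="black", lw=1.5)  # nose
    for side in (-1, 1):
        ax.plot(
            side * (1.0 + 0.06 * np.abs(np.sin(theta[:100]))),
            0.25 * np.cos(theta[:100]) - 0.0,
            color="black",
            lw=1.0,
        )
    ax.scatter(pos[:, 0], pos[:, 1], s=12, color="black", zorder=3)
    for name, (x, y) in zip(montage.channel_names, pos):
        ax.annotate(name, (x, y), textcoords="offset points", xytext=(3, 3), fontsize=7)
    fig.colorbar(mesh, ax=ax, shrink=0.8, label="normalised importance")
    title = " ".join(
        str(p)
        for p in (imp.task, imp.measure, None if imp.overlap is None else f"overlap={imp.overlap}")
        if p
    )
    ax.set_title(title or "channel importance")
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(out_path, dpi=120, bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)
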