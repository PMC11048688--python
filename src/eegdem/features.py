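"""Windowed complexity and entropy features, computed per channel per window.

Five measures, each reducing one 1 s single-channel window to one scalar, so
a 19-channel window yields a 19-column feature row:

* ``svd_entropy`` — Shannon entropy (base 2) of the normalised singular
  values of a time-delay embedding matrix.
* ``higuchi_fd`` — Higuchi's fractal dimension: slope of mean curve length
  against interval length on log-log axes (1 for a line, 2 for white noise).
* ``zero_crossing_rate`` — fraction of adjacent sample pairs whose product
  is strictly negative.
* ``dfa`` — detrended fluctuation analysis scaling exponent: slope of
  log RMS fluctuation of the integrated, per-box-detrended series against
  log box size (0.5 for white noise, 1.5 for Brownian motion).
* ``hjorth`` — activity (variance), mobility and complexity; collapsed to
  one column as the mean of mobility and complexity by ``hjorth_scalar``.

All measures are implemented from their defining formulas; the public scalar
functions delegate to batched kernels that ``extract_feature_table`` reuses
across all windows and channels at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windowing import WindowSet

logger = logging.getLogger(__name__)

#: Annotation columns of a FeatureTable; everything after them is a channel.
META_COLS = ("subject_id", "group", "window_index")

MEASURES = ("svd", "hfd", "zcr", "dfa", "hjorth")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The channel (feature) columns of a FeatureTable."""
    skip = set(META_COLS) | {"label", "is_synthetic"}
    return [c for c in table.columns if c not in skip]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class SVDEntropyConfig:
    order: int = 3   # embedding dimension M
    delay: int = 1   # embedding lag in samples

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("embedding order must be >= 2")
        if self.delay < 1:
            raise ValueError("embedding delay must be >= 1")


@dataclass(frozen=True)
class HiguchiConfig:
    kmax: int = 10

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")


@dataclass(frozen=True)
class DFAConfig:
    box_sizes: tuple[int, ...] | None = None  # default: 12 log-spaced in [4, w//4]
    detrend_order: int = 1

    def scales_for(self, w: int) -> np.ndarray:
        if self.box_sizes is not None:
            scales = np.unique(np.asarray(self.box_sizes, dtype=int))
        else:
            scales = np.unique(
                np.round(np.geomspace(4, max(4, w // 4), 12)).astype(int)
            )
        scales = scales[(scales >= self.detrend_order + 2) & (scales < w)]
        if scales.size < 4:
            raise ValueError(
                f"need >= 4 distinct DFA scales for window of {w} samples"
            )
        return scales


@dataclass(frozen=True)
class HjorthResult:
    activity: float
    mobility: float
    complexity: float


def _check_window(x: np.ndarray, min_len: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D window")
    if x.size < min_len:
        raise ValueError(f"window too short: {x.size} < {min_len}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    return x


# ---------------------------------------------------------------------------
# SVD entropy


def _svd_entropy_batch(X: np.ndarray, cfg: SVDEntropyConfig) -> np.ndarray:
    """SVD entropy for each row of X (n_signals, w), in bits."""
    order, delay = cfg.order, cfg.delay
    w = X.shape[1]
    rows = w - (order - 1) * delay
    if rows < 1:
        raise ValueError(
            f"embedding (order={order}, delay={delay}) infeasible for w={w}"
        )
    idx = np.arange(rows)[:, None] + np.arange(order)[None, :] * delay
    Y = X[:, idx]                                  # (B, rows, order)
    gram = np.einsum("bij,bik->bjk", Y, Y)         # (B, order, order)
    eigvals = np.linalg.eigvalsh(gram)
    sv = np.sqrt(np.clip(eigvals, 0.0, None))      # singular values of Y
    # zero out eigensolver noise so rank-deficient embeddings (e.g. a
    # constant window) give exact entropies
    tol = sv.max(axis=1, keepdims=True) * 1e-7
    sv = np.where(sv > tol, sv, 0.0)
    total = sv.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, sv / total, 0.0)
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=1)


def svd_entropy(x: np.ndarray, cfg: SVDEntropyConfig = SVDEntropyConfig()) -> float:
    """Entropy of the normalised singular values of the delay embedding.

    Bounded by log2(order); 0 for a constant window (rank-1 embedding).
    """
    x = _check_window(x)
    return float(_svd_entropy_batch(x[None, :], cfg)[0])


# ---------------------------------------------------------------------------
# Higuchi fractal dimension


def _higuchi_batch(X: np.ndarray, cfg: HiguchiConfig) -> np.ndarray:
    """Higuchi FD per row of X (n_signals, w)."""
    B, N = X.shape
    if not (2 <= cfg.kmax < N / 2):
        raise ValueError(f"kmax={cfg.kmax} must satisfy 2 <= kmax < w/2 (w={N})")
    ks = np.arange(1, cfg.kmax + 1)
    L = np.zeros((B, ks.size))
    for j, k in enumerate(ks):
        Lm = np.zeros(B)
        for m in range(k):  # 0-based start phase (1-based m in the usual notation)
            sub = X[:, m::k]
            n_i = sub.shape[1] - 1  # floor((N - 1 - m) / k) steps
            if n_i < 1:
                continue
            dist = np.abs(np.diff(sub, axis=1)).sum(axis=1)
            norm = (N - 1) / (n_i * k)  # curve-length normalisation y
            Lm += dist * norm / k
        L[:, j] = Lm / k
    # D = slope of ln L(k) vs ln(1/k); fit only over k with positive length
    out = np.empty(B)
    log_inv_k = np.log(1.0 / ks)
    for b in range(B):
        valid = L[b] > 0
        if valid.sum() < 2:
            out[b] = 1.0  # flat line: curve length vanishes at every scale
            continue
        slope = np.polyfit(log_inv_k[valid], np.log(L[b, valid]), 1)[0]
        out[b] = slope
    return out


def higuchi_fd(x: np.ndarray, cfg: HiguchiConfig = HiguchiConfig()) -> float:
    """Higuchi fractal dimension; 1.0 for a straight line, ~2 for white noise."""
    x = _check_window(x, min_len=2 * cfg.kmax + 1)
    return float(_higuchi_batch(x[None, :], cfg)[0])


# ---------------------------------------------------------------------------
# zero-crossing rate


def _zcr_batch(X: np.ndarray) -> np.ndarray:
    prod = X[:, 1:] * X[:, :-1]
    return (prod < 0).sum(axis=1) / (X.shape[1] - 1)


def zero_crossing_rate(x: np.ndarray) -> float:
    """Fraction of adjacent pairs with a strict sign change (s_t * s_{t-1} < 0).

    Pairs touching an exactly-zero sample contribute nothing, so the measure
    is sensitive to sampling phase on signals that hit zero exactly.
    """
    x = _check_window(x)
    return float(_zcr_batch(x[None, :])[0])


# ---------------------------------------------------------------------------
# detrended fluctuation analysis


def _dfa_batch(X: np.ndarray, cfg: DFAConfig, *, strict: bool = True) -> np.ndarray:
    """DFA exponent per row.  strict=False yields NaN instead of raising."""
    B, w = X.shape
    scales = cfg.scales_for(w)
    y = np.cumsum(X - X.mean(axis=1, keepdims=True), axis=1)
    F = np.empty((B, scales.size))
    t_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for j, n in enumerate(scales):
        nb = w // n
        seg = y[:, : nb * n].reshape(B, nb, n)
        if n not in t_cache:
            V = np.vander(np.arange(n, dtype=float), cfg.detrend_order + 1)
            t_cache[n] = (V, np.linalg.pinv(V))
        V, pinv = t_cache[n]
        coef = seg @ pinv.T                       # (B, nb, order+1)
        resid = seg - coef @ V.T
        F[:, j] = np.sqrt(np.mean(resid**2, axis=(1, 2)))
    bad = F <= 0
    if bad.any():
        if strict:
            b, j = np.argwhere(bad)[0]
            raise ValueError(
                f"DFA fluctuation vanished at scale n={scales[j]} "
                "(signal is exactly polynomial at that scale)"
            )
        F = np.where(bad, np.nan, F)
    logn = np.log(scales.astype(float))
    logF = np.log(F)
    logn_c = logn - logn.mean()
    slope = (logF - logF.mean(axis=1, keepdims=True)) @ logn_c / (logn_c @ logn_c)
    return slope


def dfa(x: np.ndarray, cfg: DFAConfig = DFAConfig()) -> float:
    """DFA scaling exponent alpha of one window."""
    x = _check_window(x, min_len=8)
    return float(_dfa_batch(x[None, :], cfg)[0])


# ---------------------------------------------------------------------------
# Hjorth parameters


def _hjorth_batch(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(activity, mobility, complexity) per row; NaN where variance vanishes."""
    var0 = X.var(axis=1)
    d1 = np.diff(X, axis=1)
    d2 = np.diff(d1, axis=1)
    var1 = d1.var(axis=1)
    var2 = d2.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mobility = np.sqrt(var1 / var0)
        complexity = np.sqrt(var2 / var1) / mobility
    mobility = np.where(var0 > 0, mobility, np.nan)
    complexity = np.where((var0 > 0) & (var1 > 0), complexity, np.nan)
    return var0, mobility, complexity


def hjorth(x: np.ndarray) -> HjorthResult:
    """Hjorth activity (variance, uV^2), mobility and complexity.

    The derivative is the first difference without sampling-rate scaling, so
    mobility is per-sample and dimensionless.
    """
    x = _check_window(x, min_len=3)
    act, mob, comp = _hjorth_batch(x[None, :])
    if not np.isfinite(mob[0]):
        raise ValueError("Hjorth mobility undefined for a constant window")
    return HjorthResult(float(act[0]), float(mob[0]), float(comp[0]))


def hjorth_scalar(x: np.ndarray) -> float:
    """Single-column Hjorth summary: (mobility + complexity) / 2."""
    h = hjorth(x)
    return (h.mobility + h.complexity) / 2.0


# ---------------------------------------------------------------------------
# feature tables


def _default_cfg(measure: str):
    return {
        "svd": SVDEntropyConfig(),
        "hfd": HiguchiConfig(),
        "dfa": DFAConfig(),
        "zcr": None,
        "hjorth": None,
    }[measure]


def _batch_values(flat: np.ndarray, measure: str, cfg) -> np.ndarray:
    if measure == "svd":
        return _svd_entropy_batch(flat, cfg)
    if measure == "hfd":
        return _higuchi_batch(flat, cfg)
    if measure == "zcr":
        return _zcr_batch(flat)
    if measure == "dfa":
        return _dfa_batch(flat, cfg, strict=False)
    if measure == "hjorth":
        _, mob, comp = _hjorth_batch(flat)
        return (mob + comp) / 2.0
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def extract_feature_table(
    windows: WindowSet, measure: str, cfg=None
) -> pd.DataFrame:
    """One row per window, one column per channel for the selected measure.

    Rows where extraction is undefined on any channel (e.g. a constant
    channel for Hjorth) are dropped, with the count logged.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if cfg is None:
        cfg = _default_cfg(measure)
    n_w, n_ch, w = windows.windows.shape
    channels = list(windows.channel_names)
    if n_w == 0:
        return pd.DataFrame(columns=list(META_COLS) + channels)
    flat = windows.windows.reshape(n_w * n_ch, w)
    values = _batch_values(flat, measure, cfg).reshape(n_w, n_ch)
    keep = np.all(np.isfinite(values), axis=1)
    if not keep.all():
        logger.warning(
            "dropped %d/%d windows with undefined %s values for %s",
            (~keep).sum(), n_w, measure, windows.subject_id,
        )
    table = pd.DataFrame(values[keep], columns=channels)
    table.insert(0, "window_index", np.nonzero(keep)[0])
    table.insert(0, "group", windows.group)
    table.insert(0, "subject_id", windows.subject_id)
    return table.reset_index(drop=True)


def extract_cohort_features(
    recordings, window_spec, measure: str, cfg=None
) -> pd.DataFrame:
    """Segment every recording and stack the per-subject feature tables."""
    from .windowing import segment

    parts = [
        extract_feature_table(segment(rec, window_spec), measure, cfg)
        for rec in recordings
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=list(META_COLS))
    return pd.concat(parts, ignore_index=True)
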