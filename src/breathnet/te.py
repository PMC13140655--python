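"""Transfer-entropy estimation for event-sampled series.

Transfer entropy (TE) quantifies directed information flow: the reduction
in uncertainty about the target's future, lambda breaths ahead, given the
source's present, beyond what the target's own present already provides.
With embedding dimension 1 for both histories,

    TE(X -> Y) = sum p(y[t+lam], y[t], x[t])
                 * log2( p(y[t+lam] | y[t], x[t]) / p(y[t+lam] | y[t]) )

estimated by the plug-in rule on a discretised sample of triplets.  Two
partitions are available: equal-frequency (quantile) binning, the default,
and an adaptive recursive partition of the triplet space (median splits
with a chi-square uniformity stop).  Units are bits throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import BreathSeries

__all__ = ["TEConfig", "LagScanResult", "transfer_entropy", "lag_scan"]

#: log base is fixed so edge weights are comparable across runs (bits).
LOG_BASE = 2


@dataclass(frozen=True)
class TEConfig:
    """Estimator settings shared across a whole analysis.

    Parameters
    ----------
    lag : int
        Prediction horizon in respiratory cycles (default 5, ~15 s at
        typical breathing frequencies).
    partition : {"quantile_bins", "adaptive"}
        Discretisation scheme. ``quantile_bins`` uses equal-frequency bins
        per variable; ``adaptive`` recursively partitions the joint triplet
        space.
    n_bins : int
        Bins per dimension in quantile mode.  A series with at most
        ``n_bins`` distinct values keeps each distinct value as its own
        bin, so genuinely discrete inputs are tabulated exactly.
    min_triplets : int
        Minimum number of usable (future, present, source) triplets.
    """

    lag: int = 5
    partition: str = "quantile_bins"
    n_bins: int = 6
    min_triplets: int = 30

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be a positive integer")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.partition not in ("quantile_bins", "adaptive"):
            raise ValueError(f"unknown partition {self.partition!r}")


@dataclass
class LagScanResult:
    """TE profile over lags 1..max_lag with the detected plateau onset."""

    lags: np.ndarray
    te_values: np.ndarray
    plateau_lag: int


def _as_values(series) -> np.ndarray:
    if isinstance(series, BreathSeries):
        return series.values
    return np.asarray(series, dtype=float)


def discretize(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-frequency discretisation; ties at bin edges go to the lower bin.

    Returns integer labels and the number of occupied levels.  If the
    series has no more distinct values than bins, the distinct values
    themselves are the bins (exact tabulation of discrete data).
    """
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if distinct.size <= n_bins:
        labels = np.searchsorted(distinct, values)
        return labels, max(distinct.size, 1)
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    # side="left": a value equal to an edge lands in the lower bin
    labels = np.searchsorted(edges, values, side="left")
    n_levels = int(labels.max()) + 1
    return labels, n_levels


def _te_from_labels(xb: np.ndarray, yb: np.ndarray, bx: int, by: int,
                    lag: int) -> np.ndarray:
    """Plug-in TE (bits) for a batch of discretised sources.

    ``xb`` has shape (m, n): m candidate sources over the same n-breath
    grid as the single target ``yb``.  Used both for observed estimates
    (m=1) and for whole batches of shuffled surrogates.
    """
    xb = np.atleast_2d(xb)
    m, n = xb.shape
    n_trip = n - lag
    yf = yb[lag:]
    yp = yb[:n_trip]
    xp = xb[:, :n_trip]

    size = by * by * bx
    base = (yf * by + yp) * bx  # shape (n_trip,)
    codes = base[None, :] + xp + (np.arange(m) * size)[:, None]
    counts = np.bincount(codes.ravel(), minlength=m * size).astype(float)
    counts = counts.reshape(m, by, by, bx)  # axes: (batch, y_future, y_now, x_now)

    c_yfy = counts.sum(axis=3)   # (m, by, by)
    c_yx = counts.sum(axis=1)    # (m, by, bx)
    c_y = c_yfy.sum(axis=1)      # (m, by)

    num = counts * c_y[:, None, :, None]
    den = c_yx[:, None, :, :] * c_yfy[:, :, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * np.log2(num / den)
    term[counts == 0.0] = 0.0  # 0 * log 0 := 0
    te = term.sum(axis=(1, 2, 3)) / n_trip
    return np.clip(te, 0.0, None)


# ---------------------------------------------------------------------------
# Adaptive partition (recursive median splits, chi-square uniformity stop)

_CHI2_CRIT = stats.chi2.ppf(0.95, 7)  # 8 octants -> 7 degrees of freedom


def _ordinal_ranks(values: np.ndarray) -> np.ndarray:
    """Distinct 0..n-1 ranks; ties broken by position (deterministic)."""
    ranks = np.empty(values.size, dtype=int)
    ranks[np.argsort(values, kind="stable")] = np.arange(values.size)
    return ranks


def _te_adaptive(x: np.ndarray, y: np.ndarray, lag: int,
                 min_cell: int = 16) -> float:
    n_trip = x.size - lag
    a = _ordinal_ranks(y[lag:])        # target future
    b = _ordinal_ranks(y[:n_trip])     # target present
    c = _ordinal_ranks(x[:n_trip])     # source present
    pts = np.column_stack([a, b, c])

    final: list[tuple[np.ndarray, np.ndarray]] = []  # (lo, hi) half-open boxes
    stack = [(np.zeros(3, dtype=int), np.full(3, n_trip, dtype=int))]
    while stack:
        lo, hi = stack.pop()
        inside = np.all((pts >= lo) & (pts < hi), axis=1)
        cnt = int(inside.sum())
        if cnt == 0:
            continue
        if cnt < min_cell or np.any(hi - lo < 2):
            final.append((lo, hi))
            continue
        cell = pts[inside]
        mids = np.array([int(np.median(cell[:, d])) for d in range(3)])
        mids = np.maximum(np.minimum(mids, hi - 1), lo + 1)
        # counts in the 8 octants around the median point
        octant = ((cell[:, 0] >= mids[0]).astype(int) * 4
                  + (cell[:, 1] >= mids[1]).astype(int) * 2
                  + (cell[:, 2] >= mids[2]).astype(int))
        occ = np.bincount(octant, minlength=8).astype(float)
        expected = cnt / 8.0
        t_stat = ((occ - expected) ** 2 / expected).sum()
        if t_stat <= _CHI2_CRIT:
            final.append((lo, hi))
            continue
        for k in range(8):
            slo, shi = lo.copy(), hi.copy()
            for d, bit in enumerate((4, 2, 1)):
                if k & bit:
                    slo[d] = mids[d]
                else:
                    shi[d] = mids[d]
            stack.append((slo, shi))

    te = 0.0
    for lo, hi in final:
        inside = np.all((pts >= lo) & (pts < hi), axis=1)
        cnt = int(inside.sum())
        if cnt == 0:
            continue
        m_b = int(((b >= lo[1]) & (b < hi[1])).sum())
        m_ab = int(((a >= lo[0]) & (a < hi[0])
                    & (b >= lo[1]) & (b < hi[1])).sum())
        m_bc = int(((b >= lo[1]) & (b < hi[1])
                    & (c >= lo[2]) & (c < hi[2])).sum())
        te += (cnt / n_trip) * np.log2(cnt * m_b / (m_bc * m_ab))
    return max(te, 0.0)


# ---------------------------------------------------------------------------


def _validate_pair(x: np.ndarray, y: np.ndarray, config: TEConfig) -> None:
    if x.size != y.size:
        raise ValueError(f"source and target lengths differ ({x.size} vs {y.size})")
    usable = x.size - config.lag
    if usable < config.min_triplets:
        raise ValueError(
            f"only {usable} usable triplets at lag {config.lag}; "
            f"at least {config.min_triplets} required")


def transfer_entropy(source, target, config: TEConfig = TEConfig()) -> float:
    """Estimate TE(source -> target) in bits at ``config.lag`` breaths.

    A constant source or target has a degenerate partition; the estimate
    is defined as 0 and a warning is emitted.
    """
    x = _as_values(source)
    y = _as_values(target)
    _validate_pair(x, y, config)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant source or target: TE defined as 0 bits",
                      stacklevel=2)
        return 0.0
    if config.partition == "adaptive":
        return float(_te_adaptive(x, y, config.lag))
    xb, bx = discretize(x, config.n_bins)
    yb, by = discretize(y, config.n_bins)
    return float(_te_from_labels(xb[None, :], yb, bx, by, config.lag)[0])


def lag_scan(source, target, config: TEConfig = TEConfig(), max_lag: int = 5,
             tolerance: float = 0.10, eps: float = 1e-12) -> LagScanResult:
    """TE at every lag 1..max_lag, with plateau-onset detection.

    The plateau lag is the smallest lag after which every successive
    relative change ``|TE(l+1)-TE(l)| / max(TE(l), eps)`` stays below
    ``tolerance``; if no lag qualifies, it is ``max_lag``.
    """
    lags = np.arange(1, max_lag + 1)
    te_values = np.array([
        transfer_entropy(source, target,
                         TEConfig(lag=int(l), partition=config.partition,
                                  n_bins=config.n_bins,
                                  min_triplets=config.min_triplets))
        for l in lags
    ])
    plateau = int(max_lag)
    rel = np.abs(np.diff(te_values)) / np.maximum(te_values[:-1], eps)
    for i in range(rel.size + 1):
        if np.all(rel[i:] < tolerance):
            plateau = int(lags[i])
            break
    return LagScanResult(lags=lags, te_values=te_values, plateau_lag=plateau)
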