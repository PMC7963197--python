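"""Pairwise waveform similarity and timing-lag analysis.

Waveform similarity between two subjects' activation coefficients (or
single-muscle envelope profiles) is the maximum of the normalized
cross-correlation of the mean-centered signals (MATLAB ``xcorr(...,'coeff')``
behavior): ``r_max`` measures shape similarity irrespective of a time shift,
and the lag at which the maximum occurs measures the timing offset, expressed
as % of the movement cycle (1% = 2 of the 200 points).

Sign convention (used package-wide): positive lag means the second signal
``y`` is *delayed* relative to the first ``x``.  For between-group pairs the
untrained subject is always ``x`` and the trained subject ``y``.

Group-level indexes average the pairwise values over all unordered
within-group pairs (n(n-1)/2 each) and all between-group pairs (n_a * n_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal as sps

from .preprocess import CYCLE_POINTS


@dataclass
class PairSimilarity:
    id_a: str
    id_b: str
    signal: int | str          # synergy index or muscle label
    r_max: float
    lag_pct: float             # % of cycle, positive = id_b delayed
    r_vector: float | None = None  # Pearson r of W columns (synergy pairs)


@dataclass
class GroupIndex:
    group_pair: str            # e.g. "within-UNE", "within-EXP", "between"
    signal: int | str
    n_pairs: int
    mean_rmax: float
    sd_rmax: float
    mean_lag: float
    sd_lag: float
    mean_rvec: float | None = None
    sd_rvec: float | None = None
    pairs: list[PairSimilarity] = field(default_factory=list)


def xcorr_rmax_lag(x: np.ndarray, y: np.ndarray, max_lag: int = 100,
                   cycle_points: int = CYCLE_POINTS) -> tuple[float, float]:
    """Peak normalized cross-correlation and its lag in % of cycle.

    Both signals are mean-centered; the correlation is normalized by the
    product of their root energies so the zero-lag autocorrelation of a signal
    with itself is exactly 1.  The linear (non-circular) correlation is scanned
    over lags in ``[-max_lag, +max_lag]`` points; ties go to the smallest
    ``|lag|`` (then to the negative lag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
    if denom == 0:
        raise ValueError("zero-variance signal")
    # correlate(y, x)[k] = sum_n x[n] y[n + lag_k]: peak at positive lag when
    # y is a delayed copy of x
    c = sps.correlate(yc, xc, mode="full") / denom
    lags = sps.correlation_lags(yc.size, xc.size, mode="full")
    keep = np.abs(lags) <= max_lag
    c, lags = c[keep], lags[keep]
    best = c.max()
    cand = lags[c >= best - 1e-12]
    lag = min(cand, key=lambda k: (abs(k), k))
    return float(best), float(lag) * 100.0 / cycle_points


def vector_similarity(w_a: np.ndarray, w_b: np.ndarray) -> float:
    """Pearson correlation between two muscle-weight vectors."""
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.shape != w_b.shape or w_a.size < 3:
        raise ValueError("weight vectors must be equal length >= 3")
    if np.std(w_a) == 0 or np.std(w_b) == 0:
        raise ValueError("zero-variance weight vector")
    return float(np.corrcoef(w_a, w_b)[0, 1])


def _signals_2d(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def pairwise_group_index(signals_by_subject: dict[str, np.ndarray],
                         groups: dict[str, str],
                         weights_by_subject: dict[str, np.ndarray] | None = None,
                         group_order: tuple[str, str] | None = None,
                         max_lag: int = 100,
                         signal_labels: list | None = None) -> list[GroupIndex]:
    """Within- and between-group pairwise similarity indexes.

    ``signals_by_subject`` maps each subject to a (k x 200) array of waveforms
    (k synergy activations, or one muscle profile); ``weights_by_subject``
    optionally maps subjects to (muscles x k) weight matrices whose matched
    columns get Pearson ``r_vector`` values.  Between-group pairs always put
    the first group of ``group_order`` as ``x`` (its delay is the negative
    direction).  Returns one :class:`GroupIndex` per (group-pair, signal).
    """
    if group_order is None:
        seen = list(dict.fromkeys(groups.values()))
        if len(seen) != 2:
            raise ValueError(f"expected exactly 2 groups, got {seen}")
        group_order = (seen[0], seen[1])
    ga, gb = group_order
    members = {g: sorted(s for s, grp in groups.items() if grp == g)
               for g in group_order}
    for g, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects for a within index")

    n_signals = _signals_2d(next(iter(signals_by_subject.values()))).shape[0]
    labels = signal_labels if signal_labels is not None else list(range(n_signals))

    pair_sets = {
        f"within-{ga}": list(combinations(members[ga], 2)),
        f"within-{gb}": list(combinations(members[gb], 2)),
        "between": [(a, b) for a in members[ga] for b in members[gb]],
    }
    out = []
    for name, pairs in pair_sets.items():
        for k in range(n_signals):
            plist = []
            for a, b in pairs:
                sa = _signals_2d(signals_by_subject[a])[k]
                sb = _signals_2d(signals_by_subject[b])[k]
                r_max, lag = xcorr_rmax_lag(sa, sb, max_lag=max_lag)
                rv = None
                if weights_by_subject is not None:
                    rv = vector_similarity(weights_by_subject[a][:, k],
                                           weights_by_subject[b][:, k])
                plist.append(PairSimilarity(a, b, labels[k], r_max, lag, rv))
            def _sd(v):
                return float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            rmaxs = np.array([p.r_max for p in plist])
            lagv = np.array([p.lag_pct for p in plist])
            gi = GroupIndex(group_pair=name, signal=labels[k],
                            n_pairs=len(plist),
                            mean_rmax=float(rmaxs.mean()), sd_rmax=_sd(rmaxs),
                            mean_lag=float(lagv.mean()), sd_lag=_sd(lagv),
                            pairs=plist)
            if weights_by_subject is not None:
                rvec = np.array([p.r_vector for p in plist])
                gi.mean_rvec = float(rvec.mean())
                gi.sd_rvec = _sd(rvec)
            out.append(gi)
    return out
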