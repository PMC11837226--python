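"""Flare-feature correlations, bout-triggered averages and persistence.

Correlations between the binary flaring indicator and continuous features
are point-biserial (Pearson with 0/1 coding), computed on frames where at
least one of the pair is flaring to avoid inflating correlations in
low-flaring records; the shuffle control permutes the masked feature values.
Peri-event time histograms average a feature in +/-3 s windows around
isolated bout onsets/offsets.  Persistence summarizes engagement decay by
an exponential fit to 8-s-binned flare proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import DEFAULT_FRAME_RATE


# --------------------------------------------------------------------------
# correlations

def coflaring_filter(flare_a: np.ndarray, flare_b: np.ndarray) -> np.ndarray:
    """Boolean mask of frames where either of the pair is flaring."""
    flare_a = np.asarray(flare_a)
    flare_b = np.asarray(flare_b)
    if flare_a.shape != flare_b.shape:
        raise ValueError("flare series must have equal length")
    return (flare_a != 0) | (flare_b != 0)


@dataclass
class CorrelationResult:
    r: float
    n: int
    zero_assigned: bool = False


def flare_feature_correlation(flare: np.ndarray, feature: np.ndarray,
                              mask: np.ndarray | None = None) -> CorrelationResult:
    """Point-biserial correlation between a binary flare series and a feature.

    If the focal fish never flares on the masked frames the correlation is
    assigned 0 (flagged).  A zero-variance feature gives r = NaN
    (not applicable).
    """
    flare = (np.asarray(flare) != 0).astype(float)
    feature = np.asarray(feature, dtype=float)
    if flare.shape != feature.shape:
        raise ValueError("flare and feature must have equal length")
    if mask is not None:
        flare = flare[np.asarray(mask, dtype=bool)]
        feature = feature[np.asarray(mask, dtype=bool)]
    n = flare.size
    if n == 0 or flare.sum() == 0:
        return CorrelationResult(r=0.0, n=n, zero_assigned=True)
    if np.ptp(flare) == 0 or np.ptp(feature) == 0:
        return CorrelationResult(r=float("nan"), n=n)
    r = float(stats.pearsonr(flare, feature).statistic)
    return CorrelationResult(r=r, n=n)


def shuffle_control(flare: np.ndarray, feature: np.ndarray,
                    mask: np.ndarray | None = None,
                    seed: int | None = None) -> CorrelationResult:
    """Correlation after a full random permutation of the masked feature."""
    feature = np.asarray(feature, dtype=float)
    flare = np.asarray(flare)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        flare = flare[mask]
        feature = feature[mask]
    rng = np.random.default_rng(seed)
    return flare_feature_correlation(flare, rng.permutation(feature))


@dataclass
class CorrelationReport:
    observed: np.ndarray         # per-fish observed r
    shuffled: np.ndarray         # per-fish shuffled-control r
    t_statistic: float
    p_value: float
    zero_assigned: np.ndarray    # per-fish flag


def cohort_correlation_test(observed, shuffled,
                            zero_assigned=None) -> CorrelationReport:
    """Two-sided paired t-test of observed vs shuffled r across fish."""
    observed = np.asarray(observed, dtype=float)
    shuffled = np.asarray(shuffled, dtype=float)
    if observed.shape != shuffled.shape:
        raise ValueError("observed and shuffled must pair up")
    res = stats.ttest_rel(observed, shuffled)
    za = (np.zeros(observed.shape, dtype=bool) if zero_assigned is None
          else np.asarray(zero_assigned, dtype=bool))
    return CorrelationReport(observed=observed, shuffled=shuffled,
                             t_statistic=float(res.statistic),
                             p_value=float(res.pvalue), zero_assigned=za)


# --------------------------------------------------------------------------
# bout selection and peri-event time histograms

@dataclass
class BoutEvent:
    kind: str       # "onset" or "offset"
    frame: int      # onset: first flaring frame; offset: first non-flaring frame
    qualifies: bool


def select_bouts(flare: np.ndarray, frame_rate: float = DEFAULT_FRAME_RATE,
                 isolation_s: float = 3.0) -> list[BoutEvent]:
    """Find flare bout onsets/offsets and mark isolated ones as qualifying.

    An onset qualifies when there was no flaring in the preceding
    ``isolation_s`` seconds and flaring persists for the following
    ``isolation_s`` seconds; an offset qualifies symmetrically.  Events
    within ``isolation_s`` of either record boundary never qualify.
    """
    flare = (np.asarray(flare) != 0).astype(np.int8)
    n = flare.size
    w = int(round(isolation_s * frame_rate))
    d = np.diff(flare, prepend=0, append=0)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)

    events = []
    for t in onsets:
        ok = (t - w >= 0 and t + w <= n
              and flare[t - w:t].sum() == 0 and flare[t:t + w].all())
        events.append(BoutEvent("onset", int(t), bool(ok)))
    for t in offsets:
        ok = (t - w >= 0 and t + w <= n
              and flare[t - w:t].all() and flare[t:t + w].sum() == 0)
        events.append(BoutEvent("offset", int(t), bool(ok)))
    events.sort(key=lambda e: e.frame)
    return events


@dataclass
class PETH:
    kind: str
    window_s: float
    frame_rate: float
    traces: np.ndarray | None    # (n_events, 2*w+1)
    mean: np.ndarray | None
    sem: np.ndarray | None
    n_events: int

    @property
    def time_axis(self) -> np.ndarray:
        w = int(round(self.window_s * self.frame_rate))
        return np.arange(-w, w + 1) / self.frame_rate


def peth(events: list[BoutEvent], feature: np.ndarray,
         frame_rate: float = DEFAULT_FRAME_RATE, window_s: float = 3.0,
         kind: str | None = None, normalize: bool = False) -> PETH:
    """Average a feature in +/-``window_s`` windows around qualifying events.

    ``kind`` restricts to onsets or offsets.  With ``normalize=True`` each
    window is min-max normalized (``normalize_elevation``) before averaging.
    Zero qualifying events yields an empty-result sentinel (n_events = 0),
    not an exception.
    """
    feature = np.asarray(feature, dtype=float)
    w = int(round(window_s * frame_rate))
    frames = [e.frame for e in events
              if e.qualifies and (kind is None or e.kind == kind)
              and e.frame - w >= 0 and e.frame + w + 1 <= feature.size]
    label = kind or "all"
    if not frames:
        return PETH(kind=label, window_s=window_s, frame_rate=frame_rate,
                    traces=None, mean=None, sem=None, n_events=0)
    traces = np.stack([feature[f - w:f + w + 1] for f in frames])
    if normalize:
        traces = np.stack([normalize_elevation(tr)[0] for tr in traces])
    mean = traces.mean(axis=0)
    if len(frames) > 1:
        sem = traces.std(axis=0, ddof=1) / np.sqrt(len(frames))
    else:
        sem = np.zeros_like(mean)
    return PETH(kind=label, window_s=window_s, frame_rate=frame_rate,
                traces=traces, mean=mean, sem=sem, n_events=len(frames))


def normalize_elevation(window: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalize one peri-event window to [0, 1].

    Returns (normalized, degenerate): a constant window maps to all zeros
    with the degenerate flag set.
    """
    window = np.asarray(window, dtype=float)
    lo, hi = window.min(), window.max()
    if hi == lo:
        return np.zeros_like(window), True
    return (window - lo) / (hi - lo), False


# --------------------------------------------------------------------------
# persistence (engagement decay)

@dataclass
class PersistenceCurve:
    bin_s: float
    bin_proportions: np.ndarray
    bin_times: np.ndarray            # bin centers, s from exposure start
    amplitude: float = float("nan")  # A in A*exp(-t/tau) + c
    tau: float = float("nan")
    offset: float = float("nan")
    fit_success: bool = False
    fit_message: str = ""
    crossings: dict = field(default_factory=dict)   # fraction -> time (s) or None

    @property
    def fitted_max(self) -> float:
        return self.amplitude + self.offset


def _exp_model(t, A, tau, c):
    return A * np.exp(-t / tau) + c


def fit_engagement_decay(bin_times: np.ndarray, bin_props: np.ndarray,
                         tau_starts=(10.0, 60.0, 300.0)):
    """Bounded least-squares fit of A*exp(-t/tau)+c with multi-start tau.

    Deterministic given the data; returns (A, tau, c, success, message).
    """
    t = np.asarray(bin_times, dtype=float)
    y = np.asarray(bin_props, dtype=float)
    A0 = max(float(y.max() - y.min()), 1e-6)
    c0 = max(float(y.min()), 0.0)
    best = None
    for tau0 in tau_starts:
        try:
            res = optimize.least_squares(
                lambda p: _exp_model(t, *p) - y,
                x0=[A0, tau0, c0],
                bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]))
        except Exception as exc:          # pragma: no cover - scipy internal
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return (float("nan"), float("nan"), float("nan"), False,
                "exponential fit did not converge")
    A, tau, c = (float(v) for v in best.x)
    return A, tau, c, True, ""


def crossing_time(A: float, tau: float, c: float, fraction: float):
    """Time at which A*exp(-t/tau)+c falls to fraction * (A + c); None if never."""
    target = fraction * (A + c)
    if A <= 0 or target <= c:
        return None
    return float(tau * np.log(A / (target - c)))


def persistence(flare: np.ndarray, frame_rate: float = DEFAULT_FRAME_RATE,
                bin_s: float = 8.0, fractions=(0.75, 0.5),
                rolling_s: float = 0.357,
                rolling_on: str = "frames") -> PersistenceCurve:
    """Engagement-decay curve of a binary flare series.

    The series is smoothed by a centered rolling mean of width ``rolling_s``
    seconds (applied at frame resolution by default; ``rolling_on='bins'``
    applies it to the binned series instead), averaged in ``bin_s``-second
    bins, and fit with a decaying exponential.  Crossing times are where the
    fitted curve reaches each fraction of its maximum (value at t = 0).
    """
    flare = (np.asarray(flare) != 0).astype(float)
    frames_per_bin = int(round(bin_s * frame_rate))
    n_bins = flare.size // frames_per_bin
    if n_bins < 2:
        raise ValueError("record must cover at least 2 bins")

    if rolling_on == "frames":
        w = max(1, int(round(rolling_s * frame_rate)))
        sm = pd.Series(flare).rolling(w, center=True, min_periods=1).mean().to_numpy()
        props = sm[:n_bins * frames_per_bin].reshape(n_bins, frames_per_bin).mean(axis=1)
    elif rolling_on == "bins":
        props = flare[:n_bins * frames_per_bin].reshape(
            n_bins, frames_per_bin).mean(axis=1)
        w = max(1, int(round(rolling_s / bin_s)))
        props = pd.Series(props).rolling(w, center=True, min_periods=1).mean().to_numpy()
    else:
        raise ValueError("rolling_on must be 'frames' or 'bins'")

    times = (np.arange(n_bins) + 0.5) * bin_s
    return fit_persistence_curve(times, props, bin_s, fractions)


def fit_persistence_curve(bin_times, bin_props, bin_s: float = 8.0,
                          fractions=(0.75, 0.5)) -> PersistenceCurve:
    """Fit the exponential and compute crossings for pre-binned proportions
    (used directly for cohort averages of per-fish bins)."""
    bin_times = np.asarray(bin_times, dtype=float)
    bin_props = np.asarray(bin_props, dtype=float)
    A, tau, c, ok, msg = fit_engagement_decay(bin_times, bin_props)
    curve = PersistenceCurve(bin_s=bin_s, bin_proportions=bin_props,
                             bin_times=bin_times, amplitude=A, tau=tau,
                             offset=c, fit_success=ok, fit_message=msg)
    if ok:
        curve.crossings = {f: crossing_time(A, tau, c, f) for f in fractions}
    return curve


def persistence_cohort(flare_list, frame_rate: float = DEFAULT_FRAME_RATE,
                       bin_s: float = 8.0, fractions=(0.75, 0.5),
                       rolling_s: float = 0.357,
                       rolling_on: str = "frames") -> PersistenceCurve:
    """Average per-fish binned proportions across individuals, then fit."""
    curves = [persistence(f, frame_rate, bin_s, fractions, rolling_s, rolling_on)
              for f in flare_list]
    n_bins = min(c.bin_proportions.size for c in curves)
    mean_props = np.mean([c.bin_proportions[:n_bins] for c in curves], axis=0)
    times = curves[0].bin_times[:n_bins]
    return fit_persistence_curve(times, mean_props, bin_s, fractions)
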