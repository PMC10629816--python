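"""Per-nucleus and spatial summary statistics of MS2 trajectories.

Implements the standard live-imaging quantification rules: a nucleus is
actively transcribing when its signal exceeds an intensity threshold;
activation time is the first threshold crossing; the transcription window is
the total time above threshold; mRNA output is the integral under the
trajectory; the Pol II loading rate is the initial slope of the smoothed
trajectory after activation; and spatial profiles are obtained by binning
nuclei along the dorsoventral axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import Trace

__all__ = [
    "NucleusFeatures",
    "SpatialProfile",
    "ActivityTimeCourse",
    "default_threshold",
    "call_activity",
    "mrna_output",
    "mean_amplitude",
    "pol2_loading_rate",
    "bin_by_position",
    "profile_steepness",
    "activity_time_course",
    "compare_groups",
    "extract_features",
    "TraceFeatureExtractor",
]


@dataclass(frozen=True)
class NucleusFeatures:
    """Scalar features of one nucleus; undefined values are NaN."""

    nucleus_id: str
    genotype: str
    dv_position: float
    active: bool
    activation_time: float  # minutes from movie start; NaN if inactive
    window: float  # minutes above threshold
    mean_amplitude: float  # AU; NaN if inactive
    mrna_output: float  # AU*min
    loading_rate: float  # AU/min; NaN if not measurable


@dataclass(frozen=True)
class SpatialProfile:
    """A feature binned along the DV axis (bins partition [-1, 1])."""

    bin_centers: np.ndarray
    bin_mean: np.ndarray  # NaN for empty bins
    bin_sem: np.ndarray
    bin_count: np.ndarray


@dataclass(frozen=True)
class ActivityTimeCourse:
    t: np.ndarray  # seconds
    active_per_frame: np.ndarray
    cumulative_active: np.ndarray
    half_activation_time: float  # minutes; NaN if no nucleus activates


def default_threshold(trace: Trace, n_baseline: int = 3, n_sd: float = 3.0) -> float:
    """Intensity threshold: baseline mean + ``n_sd`` baseline SDs.

    The baseline is estimated from the first ``n_baseline`` frames, before
    appreciable transcription has accumulated.
    """
    base = trace.intensity[:n_baseline]
    return float(base.mean() + n_sd * base.std(ddof=0))


def call_activity(trace: Trace, threshold: float) -> tuple[bool, float, float]:
    """Classify a nucleus as active and measure its activation time and window.

    Returns ``(active, activation_time_min, window_min)``.  A nucleus is
    active iff any sample exceeds the threshold; the activation time is the
    time of the first crossing; the window is (frames above threshold) x
    frame interval.  Inactive nuclei get ``(False, nan, 0.0)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    above = trace.intensity > threshold
    if not above.any():
        return False, float("nan"), 0.0
    first = int(np.argmax(above))
    dt_min = trace.frame_interval / 60.0
    return True, trace.t[first] / 60.0, float(above.sum()) * dt_min


def mrna_output(trace: Trace, threshold: float | None = None) -> float:
    """Total mRNA production proxy: trapezoidal integral of intensity (AU*min).

    If a ``threshold`` is given, inactive nuclei (never above threshold)
    report 0, matching the convention that only actively transcribing nuclei
    contribute.
    """
    if threshold is not None and not (trace.intensity > threshold).any():
        return 0.0
    return float(np.trapezoid(trace.intensity, trace.t / 60.0))


def mean_amplitude(trace: Trace, threshold: float) -> float:
    """Mean MS2 signal over the frames above threshold (NaN if inactive)."""
    above = trace.intensity > threshold
    if not above.any():
        return float("nan")
    return float(trace.intensity[above].mean())


def pol2_loading_rate(
    trace: Trace,
    threshold: float,
    span: float = 0.15,
    interp_factor: int = 10,
    n_points: int = 30,
) -> float:
    """Initial slope of the smoothed trajectory after activation (AU/min).

    The trace is LOESS-smoothed, linearly interpolated ``interp_factor``-fold,
    and the least-squares slope of the first ``n_points`` interpolated points
    above threshold is returned.  NaN if fewer than 3 usable points.
    """
    t_min = trace.t / 60.0
    smooth = lowess(trace.intensity, t_min, frac=span, return_sorted=False)
    fine_t = np.linspace(t_min[0], t_min[-1], (t_min.size - 1) * interp_factor + 1)
    fine_y = np.interp(fine_t, t_min, smooth)
    above = np.flatnonzero(fine_y > threshold)
    if above.size < 3:
        return float("nan")
    sel = above[:n_points]
    slope, _ = np.polyfit(fine_t[sel], fine_y[sel], 1)
    return float(slope)


def bin_by_position(
    values: np.ndarray, positions: np.ndarray, n_bins: int = 16
) -> SpatialProfile:
    """Bin a per-nucleus feature into equal-width DV bins over [-1, 1].

    Single-member bins report SEM 0; empty bins report NaN mean.  NaN feature
    values are ignored within a bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.shape != positions.shape:
        raise ValueError("values and positions must have equal length")
    if positions.size and (positions.min() < -1 or positions.max() > 1):
        raise ValueError("positions must lie in [-1, 1]")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(positions, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        v = values[idx == b]
        v = v[~np.isnan(v)]
        count[b] = v.size
        if v.size:
            mean[b] = v.mean()
            sem[b] = 0.0 if v.size == 1 else v.std(ddof=1) / np.sqrt(v.size)
    return SpatialProfile(bin_centers=centers, bin_mean=mean, bin_sem=sem, bin_count=count)


def profile_steepness(profile: SpatialProfile) -> float:
    """Maximum |d(mean)/d(position)| of a spatial profile.

    Quantifies the sharpness of the expression boundary.  Central differences
    on interior bins, one-sided at the edges; empty bins are dropped.
    """
    ok = ~np.isnan(profile.bin_mean)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-empty bins")
    deriv = np.gradient(profile.bin_mean[ok], profile.bin_centers[ok])
    return float(np.abs(deriv).max())


def activity_time_course(traces: list[Trace], threshold: float) -> ActivityTimeCourse:
    """Per-frame and cumulative counts of actively transcribing nuclei.

    The half-activation time is the first time at which the cumulative count
    of ever-active nuclei reaches half its final value (NaN if none activate).
    """
    if not traces:
        raise ValueError("no traces")
    t = traces[0].t
    for tr in traces[1:]:
        if tr.t.size != t.size or not np.allclose(tr.t, t):
            raise ValueError("traces must share a common time grid")
    above = np.vstack([tr.intensity > threshold for tr in traces])
    per_frame = above.sum(axis=0)
    ever = np.maximum.accumulate(above, axis=1)
    cumulative = ever.sum(axis=0)
    final = cumulative[-1]
    if final == 0:
        half = float("nan")
    else:
        half = float(t[int(np.argmax(cumulative >= final / 2))] / 60.0)
    return ActivityTimeCourse(
        t=t, active_per_frame=per_frame, cumulative_active=cumulative, half_activation_time=half
    )


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test between feature groups; returns (t, p).

    Pooled-variance Student's t by default; Welch's correction behind a flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def extract_features(
    traces: list[Trace], threshold: float | None = None, span: float = 0.15
) -> pd.DataFrame:
    """Extract :class:`NucleusFeatures` for every trace into a DataFrame.

    ``threshold=None`` applies the per-trace baseline policy of
    :func:`default_threshold`.
    """
    rows = []
    for tr in traces:
        thr = default_threshold(tr) if threshold is None else threshold
        active, act_t, window = call_activity(tr, thr)
        rows.append(
            {
                "nucleus_id": tr.nucleus_id,
                "genotype": tr.genotype,
                "dv_position": tr.dv_position,
                "active": active,
                "activation_time_min": act_t,
                "window_min": window,
                "mean_amplitude_au": mean_amplitude(tr, thr),
                "mrna_output_aumin": mrna_output(tr, thr),
                "loading_rate_aupermin": pol2_loading_rate(tr, thr, span=span) if active else float("nan"),
            }
        )
    return pd.DataFrame(rows)


class TraceFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a list of traces to a per-nucleus feature table.

    Parameters
    ----------
    threshold : float or None
        Absolute intensity threshold (AU); ``None`` uses the per-trace
        baseline policy (baseline mean + 3 SD over the first 3 frames).
    span : float
        LOESS span used when measuring the Pol II loading rate.
    """

    def __init__(self, threshold: float | None = None, span: float = 0.15):
        self.threshold = threshold
        self.span = span

    def fit(self, X: list[Trace], y=None):  # noqa: N803 - sklearn API
        if not isinstance(X, (list, tuple)) or not all(isinstance(t, Trace) for t in X):
            raise TypeError("X must be a list of Trace objects")
        self.n_traces_ = len(X)
        return self

    def transform(self, X: list[Trace]) -> pd.DataFrame:  # noqa: N803
        return extract_features(list(X), threshold=self.threshold, span=self.span)
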