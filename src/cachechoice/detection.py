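"""Offline annotation of site interactions from per-site ROI video.

Each cache site is watched by a small region of interest. Two correlation
traces are computed per site: R_b, the Pearson correlation of every frame
with a baseline image of the empty site (averaged over the first frames),
and R_p, the correlation of every frame with the previous frame. A cache
darkens the site and produces a *sustained* drop in R_b; a retrieval
restores it; any flap opening produces a *transient* deviation visible in
R_p. R_b is normalized (median subtracted, divided by its standard
deviation, so thresholds are in SD units); R_p has a 200-frame centered
moving average subtracted (thresholds in raw correlation units).

Candidate events are peaks in the negative-going traces; they are
classified by comparing the mean normalized R_b in windows before and
after the peak (the reference workflow classified candidates by manual
review; the automated classifier here is validated on synthetic stacks).

The module also provides the real-time seed-count low-pass filter used to
debounce occupancy counts: y_n = 0.01 x_n + 0.99 y_{n-1}, rounded to the
nearest integer, which delays a step by about one second at typical frame
rates so that brief checks are not counted as caches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks


@dataclass
class RoiTrace:
    """Correlation traces for one site ROI."""

    rb: np.ndarray        # normalized baseline correlation, SD units
    rp: np.ndarray        # previous-frame correlation, moving average removed
    rb_raw: np.ndarray
    rp_raw: np.ndarray
    valid: np.ndarray     # frames with defined correlations


@dataclass
class DetectedEvent:
    frame: int
    kind: str             # "cache" | "retrieval" | "check"


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of (T, P) against (P,); nan if constant."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the edges."""
    kernel = np.ones(window)
    num = np.convolve(np.nan_to_num(x), kernel, mode="same")
    den = np.convolve(np.isfinite(x).astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def compute_traces(
    frames: np.ndarray, baseline_n: int = 100, ma_window: int = 200
) -> RoiTrace:
    """Baseline- and previous-frame correlation traces for a frame stack.

    ``frames`` is (T, H, W) with lights-off frames already excluded.
    Constant (zero-variance) frames yield undefined correlations; they are
    masked with a warning.
    """
    T = frames.shape[0]
    if T < baseline_n:
        raise ValueError(f"need at least {baseline_n} frames, got {T}")
    flat = frames.reshape(T, -1).astype(float)
    baseline = flat[:baseline_n].mean(axis=0)

    rb_raw = _pearson_rows(flat, baseline)
    rp_raw = np.empty(T)
    rp_raw[0] = np.nan
    a, b = flat[1:], flat[:-1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rp_raw[1:] = np.where(den > 0, num / den, np.nan)

    valid = np.isfinite(rb_raw)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} frame(s) with undefined correlation masked"
        )
    if valid.any():
        med = np.nanmedian(rb_raw)
        sd = np.nanstd(rb_raw)
    else:
        med, sd = 0.0, 0.0
    rb = (rb_raw - med) / sd if sd > 0 else np.zeros_like(rb_raw)
    rp = rp_raw - _moving_average(rp_raw, ma_window)
    return RoiTrace(rb=rb, rp=rp, rb_raw=rb_raw, rp_raw=rp_raw, valid=valid)


@dataclass
class DetectionParams:
    """Peak-detection and classification parameters.

    Peak heights follow the trace units: R_b in SD after normalization,
    R_p in correlation units after moving-average subtraction. A candidate
    whose post-window mean R_b sits below ``sustained_sd`` is "sustained".
    """

    min_peak_distance: int = 100
    rb_min_height: float = 10.0
    rp_min_height: float = 0.3
    window: int = 300         # frames for the pre/post sustained test
    margin: int = 10          # frames skipped around the peak itself
    step_sd: float = 5.0      # pre-to-post R_b change, in noise-SD units


def detect_events(
    trace: RoiTrace, params: DetectionParams | None = None
) -> list[DetectedEvent]:
    """Candidate caches, retrievals and checks from one site's traces.

    Peaks are found on the negated traces with the configured minimum
    height and separation, merged across the two traces, and classified:
    a sustained pre-to-post drop of the baseline correlation -> cache; a
    sustained recovery -> retrieval; a transient dip -> check. The
    sustained test compares window means of the raw baseline correlation
    in units of its frame-to-frame noise (estimated from the median
    absolute successive difference), which stays valid when the site is
    occupied for long stretches and the global SD is dominated by the
    occupancy bimodality.
    """
    if params is None:
        params = DetectionParams()
    rb, rp = trace.rb, trace.rp
    rb_raw = trace.rb_raw
    d = np.diff(rb_raw[np.isfinite(rb_raw)])
    noise_sd = 1.4826 * np.median(np.abs(d)) / np.sqrt(2.0) if d.size else 0.0
    noise_sd = max(noise_sd, 1e-12)
    T = rb.shape[0]
    if T == 0:
        raise ValueError("empty trace")
    pk_b, _ = find_peaks(
        np.nan_to_num(-rb),
        height=params.rb_min_height,
        distance=params.min_peak_distance,
    )
    pk_p, _ = find_peaks(
        np.nan_to_num(-rp),
        height=params.rp_min_height,
        distance=params.min_peak_distance,
    )
    candidates = []
    for f in sorted(np.concatenate([pk_b, pk_p])):
        if not candidates or f - candidates[-1] >= params.min_peak_distance:
            candidates.append(int(f))

    events = []
    for f in candidates:
        pre_lo = max(f - params.margin - params.window, 0)
        pre = rb_raw[pre_lo: max(f - params.margin, pre_lo + 1)]
        post = rb_raw[f + params.margin: f + params.margin + params.window]
        if post.size == 0 or pre.size == 0:
            continue
        step = (np.nanmean(post) - np.nanmean(pre)) / noise_sd
        if step < -params.step_sd:
            kind = "cache"
        elif step > params.step_sd:
            kind = "retrieval"
        else:
            kind = "check"
        events.append(DetectedEvent(frame=f, kind=kind))
    return events


def seed_count_filter(raw_counts, round_output: bool = True) -> np.ndarray:
    """Real-time low-pass filter for the arena seed count.

    y_0 = 0; y_n = 0.01 x_n + 0.99 y_{n-1}. The rounded output is what the
    closed-loop controller consumes; a unit step first rounds to 1 after
    ceil(ln 0.5 / ln 0.99) = 69 frames (about 1.2 s at 57 fps), so
    transient flap openings never register as caches.
    """
    x = np.asarray(raw_counts, dtype=float)
    y = np.zeros_like(x)
    for n in range(1, x.shape[0]):
        y[n] = 0.01 * x[n] + 0.99 * y[n - 1]
    if round_output:
        return np.rint(y).astype(int)
    return y
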