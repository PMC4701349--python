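"""Lateral-histogram extraction and preprocessing.

A strip's lateral histogram is the mean pixel intensity for each position
along the flow axis, averaged across the strip width.  The control and test
lines appear as dips in this profile.  Before classification the profile is

1. resampled to a fixed 100 bins (quadratic interpolation),
2. baseline-corrected by subtracting a RANSAC-fitted linear illumination
   model ``y = a*i + b``,
3. aligned: the minimum of each half is found and a +-15-bin window around
   each is kept, giving a 62-bin profile with the control line centered in
   the first 31 bins and the test line in the last 31.

Alcohol strips take a shorter path: resample directly to 62 bins and
subtract the mean of the first 15 bins (a white stretch of membrane that
tracks illumination), with no peak alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .config import HistogramParams
from .errors import HistogramError

STAGES = ("raw", "resampled100", "baseline_corrected", "aligned62", "alcohol62")

# Rec. 601 luma weights, the standard RGB -> grayscale projection.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class LateralHistogram:
    """A 1-D intensity profile tagged with its preprocessing stage."""

    values: np.ndarray
    stage: str
    strip_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise HistogramError(f"unknown stage {self.stage!r}")
        expected = {"resampled100": 100, "aligned62": 62, "alcohol62": 62}
        n = expected.get(self.stage)
        if n is not None and self.values.size != n:
            raise HistogramError(
                f"stage {self.stage} requires {n} bins, got {self.values.size}")


def _as_gray(window_image: np.ndarray, channel: str = "luminance") -> np.ndarray:
    img = np.asarray(window_image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        if channel == "luminance":
            return img @ _LUMA
        idx = {"R": 0, "G": 1, "B": 2}.get(channel)
        if idx is None:
            raise HistogramError(f"unknown channel {channel!r}")
        return img[:, :, idx]
    raise HistogramError("window must be a 2-D grayscale or RGB image")


def extract_profile(window_image: np.ndarray, channel: str = "luminance",
                    strip_id: str | None = None) -> LateralHistogram:
    """Mean intensity per flow-axis position (rows), averaged across width.

    ``profile[i] = (1/n) * sum_j s(i, j)`` with ``i`` indexing rows along
    the strip's flow axis and ``j`` the ``n`` columns across its width.
    """
    gray = _as_gray(window_image, channel)
    if gray.size == 0 or gray.shape[1] == 0:
        raise HistogramError("empty histogram window")
    return LateralHistogram(values=gray.mean(axis=1), stage="raw",
                            strip_id=strip_id)


def resample(hist: LateralHistogram, n_bins: int = 100) -> LateralHistogram:
    """Resample a raw profile to ``n_bins`` by quadratic spline interpolation.

    The profile is parameterized on [0, 1] and evaluated at ``n_bins``
    equispaced nodes, so the endpoints are preserved exactly and any profile
    that is globally quadratic is reproduced exactly.
    """
    y = hist.values
    if y.size < 3:
        raise HistogramError("quadratic resampling needs at least 3 samples")
    x = np.linspace(0.0, 1.0, y.size)
    spline = make_interp_spline(x, y, k=2)
    out = spline(np.linspace(0.0, 1.0, n_bins))
    stage = "resampled100" if n_bins == 100 else "raw"
    return LateralHistogram(values=out, stage=stage, strip_id=hist.strip_id,
                            metadata=dict(hist.metadata))


def baseline_correct(hist: LateralHistogram,
                     params: HistogramParams | None = None,
                     seed: int = 0) -> LateralHistogram:
    """Subtract a robust linear illumination baseline ``a*i + b``.

    The line is fitted by RANSAC (inlier band = ``baseline_threshold_frac``
    of the profile's dynamic range) and refitted on the inliers by least
    squares, so the narrow line dips are treated as outliers and survive
    the subtraction.  ``(a, b)`` land in the metadata.
    """
    params = params or HistogramParams()
    y = hist.values
    if y.size < 2:
        raise HistogramError("baseline fit needs at least 2 points")
    i = np.arange(y.size, dtype=float)
    span = float(y.max() - y.min())
    if span == 0.0:
        a, b = 0.0, float(y[0])
    else:
        est = RANSACRegressor(
            estimator=LinearRegression(),
            min_samples=2,
            residual_threshold=params.baseline_threshold_frac * span,
            max_trials=params.baseline_max_trials,
            random_state=seed,
        )
        est.fit(i[:, None], y)
        a = float(est.estimator_.coef_[0])
        b = float(est.estimator_.intercept_)
    meta = dict(hist.metadata)
    meta.update(baseline_slope=a, baseline_intercept=b)
    return LateralHistogram(values=y - (a * i + b), stage="baseline_corrected",
                            strip_id=hist.strip_id, metadata=meta)


def _centered_window(start_limit: int, stop_limit: int, minimum: int,
                     half: int) -> slice:
    """31-bin window around ``minimum``, shifted inward at segment borders."""
    width = 2 * half + 1
    start = int(np.clip(minimum - half, start_limit, stop_limit - width))
    return slice(start, start + width)


def align_peaks(hist: LateralHistogram,
                params: HistogramParams | None = None) -> LateralHistogram:
    """Line up the control and test dips into a fixed 62-bin profile.

    The 100-bin profile is split into halves (bins 1-50 and 50-100, the
    middle bin shared).  The minimum of each half is located (ties broken
    toward the lowest index) and a +-15-bin window around each is kept,
    control half first: 31 + 31 = 62 bins.
    """
    params = params or HistogramParams()
    if hist.stage != "baseline_corrected":
        raise HistogramError("align_peaks expects a baseline-corrected profile")
    y = hist.values
    n = y.size
    mid = n // 2
    half = params.half_window
    m1 = int(np.argmin(y[:mid]))
    m2 = (mid - 1) + int(np.argmin(y[mid - 1:]))
    w1 = _centered_window(0, mid, m1, half)
    w2 = _centered_window(mid - 1, n, m2, half)
    meta = dict(hist.metadata)
    meta.update(h_min1=m1, h_min2=m2)
    return LateralHistogram(values=np.concatenate([y[w1], y[w2]]),
                            stage="aligned62", strip_id=hist.strip_id,
                            metadata=meta)


def alcohol_normalize(hist: LateralHistogram,
                      params: HistogramParams | None = None) -> LateralHistogram:
    """Subtract the mean of the first 15 bins from a 62-bin alcohol profile.

    The leading stretch of the alcohol strip is bare membrane, so its mean
    tracks illumination; after subtraction the first 15 bins average to
    exactly zero.
    """
    params = params or HistogramParams()
    y = hist.values
    if y.size != params.n_bins_final:
        raise HistogramError(
            f"alcohol normalization expects {params.n_bins_final} bins, got {y.size}")
    offset = float(y[:params.n_av].mean())
    meta = dict(hist.metadata)
    meta.update(illumination_offset=offset)
    return LateralHistogram(values=y - offset, stage="alcohol62",
                            strip_id=hist.strip_id, metadata=meta)


def preprocess_line_strip(window_image: np.ndarray,
                          params: HistogramParams | None = None,
                          seed: int = 0,
                          strip_id: str | None = None) -> LateralHistogram:
    """Full non-alcohol chain: extract -> resample(100) -> baseline -> align."""
    params = params or HistogramParams()
    raw = extract_profile(window_image, params.channel, strip_id)
    resampled = resample(raw, params.n_bins)
    corrected = baseline_correct(resampled, params, seed)
    return align_peaks(corrected, params)


def preprocess_alcohol_strip(window_image: np.ndarray,
                             params: HistogramParams | None = None,
                             seed: int = 0,
                             strip_id: str | None = None) -> LateralHistogram:
    """Alcohol chain: extract -> resample(62) -> first-15-bin normalization.

    Baseline removal is off by default for this path (the leading-bin
    offset already absorbs illumination) but can be enabled via
    ``params.alcohol_baseline``.
    """
    params = params or HistogramParams()
    raw = extract_profile(window_image, params.channel, strip_id)
    resampled = resample(raw, params.n_bins_final)
    values, meta = resampled.values, dict(resampled.metadata)
    if params.alcohol_baseline:
        corrected = baseline_correct(resampled, params, seed)
        values, meta = corrected.values, dict(corrected.metadata)
    return alcohol_normalize(
        LateralHistogram(values=values, stage="raw", strip_id=strip_id,
                         metadata=meta), params)
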