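"""Focal-adhesion morphometry and Y27632-response analysis.

Works from integer-labelled masks plus matching intensity images
(segmentation itself is out of scope): per-FA area, length (maximal Feret
diameter) and mean fluorescence, log-normal fits of the size distribution,
photobleaching correction against a reference channel, and exponential
decay fits of the FA fluorescence after contractility inhibition.

The decay model is  I(t) = plateau + (1 - plateau) * exp(-rate * t)  with
I(0) = 1; its initial slope is  100 * rate * (1 - plateau)  %/min.  The
plateau term is needed because constitutively active (semi-open) variants
hold FAs at a force-independent level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from skimage.measure import regionprops_table

__all__ = [
    "FaRecord",
    "SizeDistributionFit",
    "DecayFit",
    "measure_fas",
    "fa_intensity_series",
    "fit_size_distribution",
    "bleach_correct",
    "fit_decay",
    "SMALL_AREA_UM2",
    "SHORT_LENGTH_UM",
]

SMALL_AREA_UM2 = 1.0   # FAs below this area count as "small"
SHORT_LENGTH_UM = 2.0  # FAs below this length count as "short"


@dataclass
class FaRecord:
    id: int
    area: float             # um^2
    length: float           # um, maximal Feret diameter
    mean_intensity: float
    frame: int
    size_class: str         # small / large  (half-open: small iff area < 1)
    length_class: str       # short / long   (short iff length < 2)


def measure_fas(
    label_image: np.ndarray,
    intensity_image: np.ndarray,
    pixel_size: float,
    frame: int = 0,
) -> pd.DataFrame:
    """Per-label area / Feret length / mean intensity table.

    Returns one row per labelled FA with half-open class assignments
    (small iff area < 1 um^2; short iff length < 2 um).  An empty mask
    yields an empty table.
    """
    label_image = np.asarray(label_image)
    intensity_image = np.asarray(intensity_image)
    if label_image.shape != intensity_image.shape:
        raise ValueError("label and intensity images must have the same shape")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if label_image.max() == 0:
        return pd.DataFrame(columns=[
            "id", "area", "length", "mean_intensity", "frame",
            "size_class", "length_class",
        ])
    props = regionprops_table(
        label_image, intensity_image,
        properties=("label", "area", "feret_diameter_max", "mean_intensity"),
    )
    area = props["area"] * pixel_size**2
    length = props["feret_diameter_max"] * pixel_size
    return pd.DataFrame({
        "id": props["label"].astype(int),
        "area": area,
        "length": length,
        "mean_intensity": props["mean_intensity"],
        "frame": frame,
        "size_class": np.where(area < SMALL_AREA_UM2, "small", "large"),
        "length_class": np.where(length < SHORT_LENGTH_UM, "short", "long"),
    })


def fa_intensity_series(
    label_image: np.ndarray, frames: list[np.ndarray] | np.ndarray
) -> np.ndarray:
    """(n_frames, n_fas) mean intensity per FA per frame, via bincount.

    Fast path for time-lapse stacks: avoids regionprops when only the
    per-FA mean trace is needed.
    """
    lab = np.asarray(label_image).ravel()
    n = int(lab.max())
    sizes = np.bincount(lab, minlength=n + 1)[1:]
    out = np.empty((len(frames), n))
    for t, frame in enumerate(frames):
        sums = np.bincount(lab, weights=np.asarray(frame, dtype=float).ravel(),
                           minlength=n + 1)[1:]
        out[t] = sums / np.maximum(sizes, 1)
    return out


# ---------------------------------------------------------------------------
# Size distribution

@dataclass
class SizeDistributionFit:
    family: str               # "lognormal"
    mu: float                 # log-space location
    sigma: float              # log-space scale (> 0)
    mu_ci95: tuple[float, float]
    sigma_ci95: tuple[float, float]
    n: int

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))


def fit_size_distribution(areas, min_n: int = 20) -> SizeDistributionFit:
    """Maximum-likelihood log-normal fit of FA areas with 95% CIs.

    The MLE is the sample mean/SD of log areas; CIs are normal-theory for
    mu and chi-square for sigma.  Non-positive areas are rejected with the
    offending values listed; an all-equal sample is a degenerate input.
    """
    a = np.asarray(areas, dtype=float)
    if len(a) < min_n:
        raise ValueError(f"need >= {min_n} areas, got {len(a)}")
    bad = a[a <= 0]
    if len(bad):
        raise ValueError(f"non-positive areas: {np.unique(bad)[:10]}")
    x = np.log(a)
    n = len(x)
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma < 1e-12:
        raise ValueError("degenerate sample: all areas equal (sigma -> 0)")
    se_mu = sigma / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    mu_ci = (mu - tcrit * se_mu, mu + tcrit * se_mu)
    chi_lo, chi_hi = stats.chi2.ppf([0.975, 0.025], n - 1)
    sigma_ci = (sigma * np.sqrt((n - 1) / chi_lo),
                sigma * np.sqrt((n - 1) / chi_hi))
    return SizeDistributionFit("lognormal", mu, sigma, mu_ci, sigma_ci, n)


# ---------------------------------------------------------------------------
# Bleaching and decay

def bleach_correct(
    series: np.ndarray,
    reference: np.ndarray,
    smooth_window: int = 5,
) -> np.ndarray:
    """Divide out photobleaching measured on a reference channel.

    corrected(t) = series(t) * reference(0) / reference(t), with the
    reference smoothed by a centred moving average first.  Series and
    reference must share a time base (equal length).
    """
    s = np.asarray(series, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.shape != r.shape:
        raise ValueError("series and reference must share a time base")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        rp = np.pad(r, pad, mode="edge")
        r = np.convolve(rp, kernel, mode="valid")[: len(s)]
    if np.any(r <= 0):
        raise ValueError("reference reaches zero; cannot correct")
    return s * r[0] / r


@dataclass
class DecayFit:
    rate: float               # 1/min, >= 0
    plateau: float            # fraction of the initial level retained
    initial_slope: float      # %/min at t = 0 (= 100 * rate * (1 - plateau))
    rate_ci95: tuple[float, float]
    slope_ci95: tuple[float, float]
    bleach_corrected: bool
    flagged: bool             # True when the fit is unreliable (CI spans 0)


def _decay_model(t, rate, plateau):
    return plateau + (1.0 - plateau) * np.exp(-rate * t)


def fit_decay(
    times: np.ndarray,
    series: np.ndarray,
    per_fa: np.ndarray | None = None,
    bleach_corrected: bool = True,
    n_bootstrap: int = 200,
    seed: int = 0,
    allow_plateau: bool = True,
) -> DecayFit:
    """Fit I(t) = plateau + (1-plateau) exp(-rate t) to a normalised series.

    ``series`` must start at 1 (normalised to the treatment time origin) and
    hold >= 6 points.  When the (n_frames, n_fas) matrix ``per_fa`` is
    given, 95% CIs come from bootstrap resampling over FAs; otherwise from
    the curve_fit covariance.  A wildly non-monotone series is fitted
    anyway but flagged, with the CI covering zero.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(series, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and series must have equal length")
    if len(y) < 6:
        raise ValueError("need >= 6 time points")
    if abs(y[0] - 1.0) > 0.05:
        raise ValueError("series must be normalised to 1 at t = 0")

    bounds = ([0.0, 0.0], [np.inf, 1.0]) if allow_plateau \
        else ([0.0, 0.0], [np.inf, 1e-12])

    def _fit(yy):
        p0 = [max(1e-3, -(yy[1] - yy[0]) / max(t[1] - t[0], 1e-9)),
              float(np.clip(yy.min(), bounds[0][1],
                            min(bounds[1][1], 0.99)))]
        try:
            popt, pcov = curve_fit(_decay_model, t, yy, p0=p0, bounds=bounds,
                                   maxfev=5000)
        except RuntimeError:
            return np.array([0.0, float(np.clip(yy.min(), 0, 1))]), None
        # a flat series makes (rate, plateau) unidentifiable with plateau -> 1;
        # prefer the zero-rate model when it explains the data as well
        sse_full = float(np.sum((yy - _decay_model(t, *popt)) ** 2))
        sse_flat = float(np.sum((yy - yy.mean()) ** 2))
        # AIC-style allowance for the two extra parameters of the full model
        if sse_flat <= sse_full * (1.0 + 4.0 / len(yy)):
            return np.array([0.0, float(np.clip(yy.mean(), 0.0, 1.0))]), None
        return popt, pcov

    popt, pcov = _fit(y)
    rate, plateau = float(popt[0]), float(popt[1])
    slope = 100.0 * rate * (1.0 - plateau)

    rng = np.random.default_rng(seed)
    if per_fa is not None:
        per_fa = np.asarray(per_fa, dtype=float)
        n_fas = per_fa.shape[1]
        rates, slopes = [], []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, n_fas, n_fas)
            yy = per_fa[:, pick].mean(axis=1)
            yy = yy / yy[0]
            bo, _ = _fit(yy)
            rates.append(bo[0])
            slopes.append(100.0 * bo[0] * (1.0 - bo[1]))
        rate_ci = tuple(np.percentile(rates, [2.5, 97.5]))
        slope_ci = tuple(np.percentile(slopes, [2.5, 97.5]))
    elif pcov is not None and np.all(np.isfinite(pcov)):
        se = np.sqrt(max(pcov[0, 0], 0.0))
        rate_ci = (max(rate - 1.96 * se, 0.0), rate + 1.96 * se)
        dslope = 100.0 * (1.0 - plateau) * 1.96 * se
        slope_ci = (max(slope - dslope, 0.0), slope + dslope)
    else:
        rate_ci = (0.0, np.inf)
        slope_ci = (0.0, np.inf)

    resid = y - _decay_model(t, rate, plateau)
    flagged = bool(np.std(resid) > 0.15) or (slope >= 0.3 and slope_ci[0] <= 0.0)
    return DecayFit(rate, plateau, slope, tuple(map(float, rate_ci)),
                    tuple(map(float, slope_ci)), bleach_corrected, flagged)
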