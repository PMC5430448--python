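"""Minimal localization and measurement harness.

A deliberately simple pipeline: local-maximum candidate
detection, symmetric 2D Gaussian least-squares fitting, quality filtering on
the fitted width (sigma), the normalized fit residual and the photon count,
plus the structural measurements used to quantify simulation artefacts
(ring periodicity along an axon axis, double-Gaussian line separation) and
ground-truth drift subtraction.

The localizer always fits a symmetric Gaussian regardless of the PSF model
that generated the data — exactly the model mismatch whose consequences the
simulator is designed to expose.

Localizations are returned as a pandas DataFrame with columns
``frame`` (0-based, matching stack page order), ``x_nm``, ``y_nm``,
``sigma_nm``, ``photons``, ``residual``, ``accepted``.  Coordinates are in
sample-plane nm with the origin at the field-of-view corner, x along
columns and y along rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from stormsim.camera import CameraConfig
from stormsim.drift import DriftTrajectory

__all__ = [
    "Localization",
    "localize",
    "threshold_localizations",
    "percentile_thresholds",
    "measure_ring_periodicity",
    "fit_transverse_walls",
    "measure_line_separation",
    "subtract_known_drift",
]

COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "photons", "residual", "accepted"]


@dataclass
class Localization:
    frame: int
    x_nm: float
    y_nm: float
    sigma_nm: float
    photons: float
    residual: float
    accepted: bool = True


def _fit_gaussian(window: np.ndarray, sigma_guess: float):
    """Least-squares fit of A exp(-r^2 / 2 s^2) + b on a square pixel window.

    Returns (A, x, y, sigma, b, residual_norm, converged); x, y in pixel
    units relative to the window corner (pixel centres at half-integers).
    """
    n = window.shape[0]
    yy, xx = np.mgrid[0:n, 0:n] + 0.5
    xf = xx.ravel()
    yf = yy.ravel()
    data = window.ravel().astype(float)
    b0 = float(np.median(data))
    a0 = max(float(data.max() - b0), 1e-3)
    w = np.clip(data - b0, 0.0, None)
    tot = w.sum()
    if tot > 0:
        x0 = float((w * xf).sum() / tot)
        y0 = float((w * yf).sum() / tot)
    else:
        x0 = y0 = n / 2.0
    p0 = np.array([a0, x0, y0, sigma_guess, b0])

    def resid(p):
        a, x, y, s, b = p
        g = np.exp(-((xf - x) ** 2 + (yf - y) ** 2) / (2.0 * s * s))
        return a * g + b - data

    def jac(p):
        a, x, y, s, b = p
        dx = xf - x
        dy = yf - y
        g = np.exp(-(dx**2 + dy**2) / (2.0 * s * s))
        j = np.empty((data.size, 5))
        j[:, 0] = g
        j[:, 1] = a * g * dx / (s * s)
        j[:, 2] = a * g * dy / (s * s)
        j[:, 3] = a * g * (dx**2 + dy**2) / (s**3)
        j[:, 4] = 1.0
        return j

    try:
        res = optimize.least_squares(
            resid,
            p0,
            jac=jac,
            method="lm",
            xtol=1e-8,
            ftol=1e-8,
            max_nfev=100,
        )
    except Exception:
        return None
    a, x, y, s, b = res.x
    s = abs(s)  # the model depends on s^2 only
    if a <= 0 or s < 0.05 or not (0.0 <= x <= n and 0.0 <= y <= n):
        return None
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return a, x, y, s, b, rms / a, res.success


def localize(
    stack: np.ndarray,
    camera: CameraConfig,
    detection_threshold: float | None = None,
    fit_window: int = 7,
    sigma_guess_px: float = 1.3,
) -> pd.DataFrame:
    """Detect and fit single-molecule spots in every frame of a stack.

    Candidates are local maxima of the background-subtracted frame.  The
    background estimate is the per-pixel temporal median of the stack:
    emitters blink sparsely in time, so the median captures everything
    static — baseline, uniform background and structured fluorescence
    background of any spatial width — without generating candidates by
    itself.  (A spatial median filter fails here: a structured-background
    ridge narrower than the filter window survives the subtraction intact.)
    For stacks too short for a stable temporal median, a spatial median
    filter is used instead.
    ``detection_threshold`` is in ADU above that background; when omitted,
    a per-pixel threshold of five standard deviations of the camera noise
    model at the local background level is used (shot noise on a bright
    structured background is much larger than on the dark field, so a
    global threshold either floods or starves).  Non-convergent fits are
    kept with ``accepted=False`` rather than raised.
    Photon counts are fitted Gaussian volumes divided by the camera's mean
    ADU-per-photon gain.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    half = fit_window // 2
    px = camera.pixel_size
    a_e = camera.adu_per_electron
    gain = camera.em_gain if camera.em_register else 1.0
    excess = 2.0 if camera.em_register else 1.0
    read_var = (a_e * camera.readout_noise_sigma) ** 2
    bg_static = (
        np.median(stack, axis=0).astype(float) if stack.shape[0] >= 20 else None
    )
    rows: list[tuple] = []
    for f in range(stack.shape[0]):
        frame = stack[f].astype(float)
        if bg_static is not None:
            bg_map = bg_static
        else:
            bg_map = ndimage.median_filter(frame, size=2 * fit_window - 1)
        above = frame - bg_map
        if detection_threshold is None:
            photons = np.clip(bg_map - camera.baseline, 0.0, None)
            photons /= camera.adu_per_photon
            electrons = camera.quantum_efficiency * photons
            noise_sd = np.sqrt(
                excess * (a_e * gain) ** 2 * electrons + read_var
            )
            thr = 5.0 * np.maximum(noise_sd, 0.5)
        else:
            thr = detection_threshold
        maxima = (above == ndimage.maximum_filter(above, size=3)) & (above > thr)
        ii, jj = np.nonzero(maxima)
        keep = (
            (ii >= half)
            & (ii < frame.shape[0] - half)
            & (jj >= half)
            & (jj < frame.shape[1] - half)
        )
        for i, j in zip(ii[keep], jj[keep]):
            window = frame[i - half : i + half + 1, j - half : j + half + 1]
            fit = _fit_gaussian(window, sigma_guess_px)
            if fit is None:
                continue
            a, x, y, s, b, residual, converged = fit
            x_nm = (j - half + x) * px
            y_nm = (i - half + y) * px
            photons = 2.0 * np.pi * a * s * s / camera.adu_per_photon
            rows.append(
                (f, x_nm, y_nm, s * px, photons, residual, bool(converged))
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["accepted"] = df["accepted"].astype(bool)
    return df


def threshold_localizations(
    locs: pd.DataFrame,
    sigma_range: tuple[float, float] | None = None,
    residual_max: float | None = None,
    photon_min: float | None = None,
) -> pd.DataFrame:
    """Filter localizations by fitted sigma, residual and photon number.

    A pure, order-preserving filter; each criterion is optional.  Raises on
    inverted sigma ranges.
    """
    mask = locs["accepted"].to_numpy(copy=True)
    if sigma_range is not None:
        lo, hi = sigma_range
        if lo > hi:
            raise ValueError("inverted sigma_range")
        s = locs["sigma_nm"].to_numpy()
        mask &= (s >= lo) & (s <= hi)
    if residual_max is not None:
        mask &= locs["residual"].to_numpy() <= residual_max
    if photon_min is not None:
        mask &= locs["photons"].to_numpy() >= photon_min
    return locs[mask].reset_index(drop=True)


def percentile_thresholds(
    locs: pd.DataFrame,
    sigma_pct: tuple[float, float] = (2.0, 90.0),
    residual_pct: float = 90.0,
) -> tuple[tuple[float, float], float]:
    """Scenario-calibrated thresholds from the localization distribution.

    Returns (sigma_range, residual_max) at the given percentiles of the
    accepted localizations; used as default quality windows when no absolute
    thresholds are configured.
    """
    ok = locs[locs["accepted"]]
    s = np.percentile(ok["sigma_nm"], list(sigma_pct))
    r = float(np.percentile(ok["residual"], residual_pct))
    return (float(s[0]), float(s[1])), r


def measure_ring_periodicity(
    locs: pd.DataFrame,
    axis,
    bin_nm: float = 5.0,
    min_spacing_nm: float = 100.0,
) -> float:
    """Mean inter-peak spacing of localizations projected on the axon axis.

    Projects (x, y) onto the in-plane ``axis`` direction, histograms at
    ``bin_nm`` resolution, detects peaks above half the global maximum and
    returns the mean distance between consecutive peaks.  Returns NaN when
    fewer than two peaks are resolvable.
    """
    a = np.asarray(axis, dtype=float)[:2]
    a = a / np.linalg.norm(a)
    proj = locs["x_nm"].to_numpy() * a[0] + locs["y_nm"].to_numpy() * a[1]
    if proj.size < 2:
        return float("nan")
    edges = np.arange(proj.min() - bin_nm, proj.max() + 2 * bin_nm, bin_nm)
    hist, edges = np.histogram(proj, bins=edges)
    if hist.max() == 0:
        return float("nan")
    dist = max(int(min_spacing_nm / bin_nm), 1)
    peaks, _ = signal.find_peaks(hist, height=0.5 * hist.max(), distance=dist)
    if len(peaks) < 2:
        return float("nan")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(np.mean(np.diff(centers[peaks])))


def _double_gaussian(p, t):
    a1, a2, m1, m2, s, b = p
    return (
        a1 * np.exp(-((t - m1) ** 2) / (2 * s * s))
        + a2 * np.exp(-((t - m2) ** 2) / (2 * s * s))
        + b
    )


def fit_transverse_walls(
    transverse_nm,
    bin_nm: float = 10.0,
    min_separation_nm: float = 50.0,
) -> tuple[float, float]:
    """Positions of the two peaks of a bimodal transverse profile.

    Histograms the transverse coordinate, fits a shared-width two-Gaussian
    mixture by least squares and returns the two fitted means (sorted).
    Returns (nan, nan) when the profile is not resolvably bimodal.
    """
    t = np.asarray(transverse_nm, dtype=float)
    if t.size < 10:
        return float("nan"), float("nan")
    edges = np.arange(t.min() - bin_nm, t.max() + 2 * bin_nm, bin_nm)
    hist, edges = np.histogram(t, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    dist = max(int(min_separation_nm / bin_nm), 1)
    peaks, _ = signal.find_peaks(hist, height=0.3 * hist.max(), distance=dist)
    if len(peaks) < 2:
        return float("nan"), float("nan")
    order = np.argsort(hist[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    p0 = np.array(
        [hist[p1], hist[p2], centers[p1], centers[p2], max(2 * bin_nm, 15.0), 0.0]
    )

    def resid(p):
        return _double_gaussian(p, centers) - hist

    res = optimize.least_squares(resid, p0, max_nfev=2000)
    a1, a2, m1, m2, s, b = res.x
    if not res.success or min(a1, a2) <= 0:
        return float("nan"), float("nan")
    lo, hi = sorted((float(m1), float(m2)))
    return lo, hi


def measure_line_separation(
    transverse_nm,
    bin_nm: float = 10.0,
    min_separation_nm: float = 50.0,
) -> float:
    """Separation of two parallel lines from the transverse profile.

    Histograms the transverse coordinate of the localizations, fits a
    shared-width two-Gaussian mixture by least squares and returns the
    distance between the fitted means.  Returns NaN when the profile is not
    resolvably bimodal.
    """
    lo, hi = fit_transverse_walls(
        transverse_nm, bin_nm=bin_nm, min_separation_nm=min_separation_nm
    )
    return float(hi - lo)


def subtract_known_drift(locs: pd.DataFrame, traj: DriftTrajectory) -> pd.DataFrame:
    """Undo the simulated drift using the known trajectory.

    Shifts each localization by minus the drift offset of its frame
    (frames 0-based, matching the trajectory).  Raises on frames outside
    the trajectory.
    """
    frames = locs["frame"].to_numpy().astype(int)
    if frames.size and (frames.min() < 0 or frames.max() >= traj.n_frames):
        raise ValueError("localization frame outside drift trajectory")
    out = locs.copy()
    if frames.size:
        out["x_nm"] = out["x_nm"].to_numpy() - traj.offsets[frames, 0]
        if traj.offsets.shape[1] > 1:
            out["y_nm"] = out["y_nm"].to_numpy() - traj.offsets[frames, 1]
    return out
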