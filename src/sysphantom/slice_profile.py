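"""Slice-profile and slice-thickness measurement from the paired wedges.

The phantom carries two opposed 10-degree wedges.  A 4 mm x 50 mm
rectangular ROI over each wedge is averaged across its short dimension to
give the edge response function (ERF); the ERF derivative is the projected
slice profile.  With projected widths w1, w2 of the two wedges, the tilt of
the image plane relative to the wedge base is

    theta = 1/2 arcsin[ (w2 - w1) sin(2 * 10 deg) / (w2 + w1) ],

the effective wedge angles are 10 deg +/- theta, and

* NEMA method: each derivative profile's position axis is scaled by
  tan(10 deg +/- theta) and the slice thickness is the FWHM (by linear
  interpolation) of the corrected profile, averaged over the two wedges.
* Automated method: a continuous flat-ramp-flat piecewise-linear model is
  least-squares fitted to each ERF (breakpoints free, grid search plus
  local refinement); the thickness is t = 1/2 (w1 + w2) tan(10 deg), whose
  first-order tilt error cancels when both orientations are averaged.

The wedge height (10 mm) bounds the measurable thickness; inputs implying
t > 10 mm are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import WedgeSpec


@dataclass
class SliceProfileResult:
    t_sl_mm: float                    # FWHM-based (NEMA) thickness
    t_auto_mm: float | None           # piecewise-linear thickness
    t_auto_uncertainty_mm: float | None
    theta_deg: float                  # slice-plane misalignment
    w1_mm: float
    w2_mm: float
    profile: np.ndarray | None = None   # (position mm, relative excitation)
    smoothing_width: int = 0            # derivative smoothing, in samples

    def __post_init__(self):
        if self.t_sl_mm is not None and self.t_sl_mm <= 0:
            raise ValueError("slice thickness must be positive")


def edge_response(image, roi, axis=0, pixel_mm=1.0, smooth=0):
    """Column-averaged ERF over a rectangular ROI, and its derivative.

    ``roi`` is a pair of index slices; the profile runs along ``axis``.
    The derivative uses central differences with optional boxcar smoothing
    of odd width ``smooth`` (reported because smoothing biases the FWHM).
    Returns (positions mm, erf, derivative).
    """
    sub = image[roi]
    if sub.size == 0:
        raise ValueError("ROI clipped by image bounds")
    erf = sub.mean(axis=1 - axis)
    pos = np.arange(len(erf)) * pixel_mm
    der = np.gradient(erf, pixel_mm)
    if smooth and smooth > 1:
        if smooth % 2 == 0:
            raise ValueError("smoothing width must be odd")
        k = np.ones(smooth) / smooth
        der = np.convolve(der, k, mode="same")
    return pos, erf, der


def fwhm(pos, profile):
    """Full width at half maximum, linear interpolation at the crossings."""
    p = np.asarray(profile, dtype=float)
    half = p.max() / 2.0
    above = p >= half
    if not np.any(above):
        raise ValueError("profile never reaches half maximum")
    i0 = int(np.argmax(above))
    i1 = len(p) - 1 - int(np.argmax(above[::-1]))
    if i0 == 0 or i1 == len(p) - 1:
        raise ValueError("half-maximum crossings outside the profile")
    x_lo = np.interp(half, [p[i0 - 1], p[i0]], [pos[i0 - 1], pos[i0]])
    x_hi = np.interp(half, [p[i1 + 1], p[i1]], [pos[i1 + 1], pos[i1]])
    return float(x_hi - x_lo)


def tilt_angle_deg(w1, w2, wedge_angle_deg=10.0):
    """Slice-plane tilt from the two projected widths."""
    arg = (w2 - w1) * np.sin(np.deg2rad(2 * wedge_angle_deg)) / (w2 + w1)
    return float(np.rad2deg(0.5 * np.arcsin(arg)))


def _check_thickness(t, wedge: WedgeSpec):
    if t > wedge.height_mm:
        raise ValueError(
            f"implied slice thickness {t:.2f} mm exceeds the wedge height "
            f"{wedge.height_mm:.0f} mm (maximum measurable thickness)")


def nema_thickness(pos1, der1, pos2, der2, wedge: WedgeSpec | None = None
                   ) -> SliceProfileResult:
    """NEMA wedge method from the two derivative (slice-profile) curves.

    Profile 1 is the positive-inclination wedge (effective angle
    10 deg + theta), profile 2 the negative one.  Swapping the inputs flips
    the sign of theta and leaves the thickness unchanged.
    """
    wedge = wedge or WedgeSpec()
    w1 = fwhm(pos1, der1)
    w2 = fwhm(pos2, der2)
    theta = tilt_angle_deg(w1, w2, wedge.wedge_angle_deg)
    a1 = np.deg2rad(wedge.wedge_angle_deg + theta)
    a2 = np.deg2rad(wedge.wedge_angle_deg - theta)
    t1 = w1 * np.tan(a1)
    t2 = w2 * np.tan(a2)
    t = 0.5 * (t1 + t2)
    _check_thickness(t, wedge)
    # angle-corrected profile from the positive wedge
    prof = np.column_stack([pos1 * np.tan(a1), der1 / max(der1.max(), 1e-12)])
    return SliceProfileResult(t_sl_mm=float(t), t_auto_mm=None,
                              t_auto_uncertainty_mm=None,
                              theta_deg=theta, w1_mm=w1, w2_mm=w2,
                              profile=prof)


def fit_piecewise_ramp(pos, erf):
    """Continuous flat-ramp-flat least-squares fit of an ERF.

    Returns (x0, x1, low, high, rmse): breakpoints, plateau levels and the
    fit RMSE.  Breakpoints are found by a coarse grid search refined with
    Nelder-Mead; levels are solved linearly at each breakpoint pair.
    """
    pos = np.asarray(pos, dtype=float)
    y = np.asarray(erf, dtype=float)

    def levels_and_sse(x0, x1):
        if not (pos[0] <= x0 < x1 <= pos[-1]):
            return None, None, np.inf
        ramp = np.clip((pos - x0) / (x1 - x0), 0.0, 1.0)
        A = np.column_stack([1.0 - ramp, ramp])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        return coef[0], coef[1], float(r @ r)

    n = len(pos)
    cand = pos[:: max(1, n // 40)]
    best = (np.inf, None)
    for i, x0 in enumerate(cand[:-1]):
        for x1 in cand[i + 1:]:
            if x1 - x0 < 3 * (pos[1] - pos[0]):
                continue
            sse = levels_and_sse(x0, x1)[2]
            if sse < best[0]:
                best = (sse, (x0, x1))
    if best[1] is None:
        raise ValueError("ramp shorter than 3 samples")
    res = minimize(lambda p: levels_and_sse(p[0], p[1])[2], best[1],
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12})
    x0, x1 = res.x
    lo, hi, sse = levels_and_sse(x0, x1)
    if x1 - x0 < 3 * (pos[1] - pos[0]):
        raise ValueError("ramp shorter than 3 samples")
    rmse = np.sqrt(sse / max(len(y) - 4, 1))
    return float(x0), float(x1), float(lo), float(hi), float(rmse)


def _width_uncertainty(pos, x0, x1, lo, hi, rmse):
    """Breakpoint uncertainty propagated from the fit residual level.

    The ramp slope is (hi-lo)/w; a breakpoint shifts by ~ rmse/slope *
    sqrt(2/m) where m is the number of samples informing each breakpoint."""
    w = x1 - x0
    slope = abs(hi - lo) / max(w, 1e-12)
    dx = pos[1] - pos[0]
    m = max(w / dx, 1.0)
    return rmse / max(slope, 1e-12) * np.sqrt(2.0 / m)


def automated_thickness(pos1, erf1, pos2, erf2, wedge: WedgeSpec | None = None
                        ) -> SliceProfileResult:
    """Piecewise-linear (automated) method: t = 1/2 (w1 + w2) tan(10 deg)."""
    wedge = wedge or WedgeSpec()
    x0a, x1a, loa, hia, ra = fit_piecewise_ramp(pos1, erf1)
    x0b, x1b, lob, hib, rb = fit_piecewise_ramp(pos2, erf2)
    w1 = x1a - x0a
    w2 = x1b - x0b
    tan_w = np.tan(np.deg2rad(wedge.wedge_angle_deg))
    t = 0.5 * (w1 + w2) * tan_w
    _check_thickness(t, wedge)
    theta = tilt_angle_deg(w1, w2, wedge.wedge_angle_deg)
    u1 = _width_uncertainty(pos1, x0a, x1a, loa, hia, ra)
    u2 = _width_uncertainty(pos2, x0b, x1b, lob, hib, rb)
    u_t = 0.5 * np.hypot(u1, u2) * tan_w
    return SliceProfileResult(t_sl_mm=float(t), t_auto_mm=float(t),
                              t_auto_uncertainty_mm=float(u_t),
                              theta_deg=theta, w1_mm=float(w1), w2_mm=float(w2))


def analyze_wedge_image(image, rois, pixel_mm, wedge: WedgeSpec | None = None,
                        smooth=0):
    """Full analysis of a wedge slice image: returns (nema, automated).

    ``rois`` maps orientation (+1 / -1) to the pair of index slices of the
    4 mm x 50 mm rectangle of each wedge.
    """
    wedge = wedge or WedgeSpec()
    pos_p, erf_p, der_p = edge_response(image, rois[+1], 0, pixel_mm, smooth)
    pos_n, erf_n, der_n = edge_response(image, rois[-1], 0, pixel_mm, smooth)
    # the negative wedge descends along +x; flip so both ERFs ascend
    erf_n = erf_n[::-1]
    der_n = der_n[::-1]
    nema = nema_thickness(pos_p, np.abs(der_p), pos_n, np.abs(der_n), wedge)
    auto = automated_thickness(pos_p, erf_p, pos_n, erf_n, wedge)
    for r in (nema, auto):
        r.smoothing_width = smooth
    return nema, auto
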