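"""T1 and T2 relaxometry fits for the parameter arrays.

Three per-ROI fits are provided, all by nonlinear least squares with
standard errors from the Jacobian-based covariance:

* inversion recovery (magnitude):  S(TI) = |A (1 - (1 + delta) e^{-TI/T1})|
  The absolute-value model is fitted directly (no polarity restoration),
  since magnitude images are the common denominator across scanners; the
  optimizer restarts from several log-spaced T1 seeds to escape the
  non-smooth signal-null region.
* variable flip angle (spoiled GRE):
  S(a) = S90 sin a (1 - E1) / (1 - E1 cos a),  E1 = e^{-TR/T1},
  initialized from the linearized (S/sin a vs S/tan a) form.
* spin echo: S(TE) = S0 e^{-TE/T2}, with optional exclusion of points below
  an estimated noise floor and of an anomalous first echo.

Deviation from a reference value is reported as 100 (Tm - Tr) / Tr (%).
Relaxation rates vs paramagnetic salt concentration are fitted as a line
R = r C + R_water with the intercept fixed to the measured water rate
(relaxivity r in 1/(mM s); rates in 1/s are 1000 / T[ms]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import ImageVolume


@dataclass
class ROISeries:
    """Signal of one ROI across a series (TI, TE or flip sweep)."""

    roi_id: int
    x_values: np.ndarray           # TI ms | TE ms | flip degrees
    mean_signals: np.ndarray
    voxel_signals: np.ndarray | None = None   # (n_x, n_voxels)
    roi_diameter_mm: float = 10.0

    def __post_init__(self):
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.mean_signals = np.asarray(self.mean_signals, dtype=float)
        if len(self.x_values) < 3:
            raise ValueError("a series needs at least 3 points")
        if np.any(np.diff(self.x_values) <= 0):
            raise ValueError("x values must be strictly increasing")


def extract_roi_series(volumes: list[ImageVolume], centers_mm, x_key: str,
                       roi_diameter_mm=10.0) -> list[ROISeries]:
    """Circular/spherical ROI means (and voxel arrays) across a series."""
    xs = np.array([float(v.meta[x_key]) for v in volumes])
    order = np.argsort(xs)
    xs = xs[order]
    vols = [volumes[i] for i in order]
    r = roi_diameter_mm / 2.0
    out = []
    ref = vols[0]
    spacing = np.asarray(ref.spacing, dtype=float)
    for rid, c in enumerate(np.atleast_2d(centers_mm), start=1):
        idx_c = ref.world_to_index(c)[0]
        half = np.ceil(r / spacing).astype(int) + 1
        lo = np.maximum(np.round(idx_c).astype(int) - half, 0)
        hi = np.minimum(np.round(idx_c).astype(int) + half,
                        np.array(ref.data.shape) - 1)
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        d2 = [((a - idx_c[d]) * spacing[d]) ** 2 for d, a in enumerate(ax)]
        # in-plane (or 3D) ROI: ignore axes thicker than the ROI (2D slices)
        shp = [len(a) for a in ax]
        dist2 = np.zeros(shp)
        for d, t in enumerate(d2):
            if spacing[d] <= roi_diameter_mm:
                sh = [1, 1, 1]
                sh[d] = len(t)
                dist2 = dist2 + t.reshape(sh)
        m = dist2 <= r * r
        sigs = []
        for v in vols:
            box = v.data[tuple(slice(l, h + 1) for l, h in zip(lo, hi))]
            sigs.append(box[m])
        sigs = np.array(sigs)
        out.append(ROISeries(rid, xs, sigs.mean(axis=1), sigs, roi_diameter_mm))
    return out


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class T1IRFit:
    T1: float
    A: float
    delta: float
    T1_stderr: float
    A_stderr: float = np.nan
    delta_stderr: float = np.nan
    mode: str = "roi_mean"


@dataclass
class VFAFit:
    T1: float
    S90: float
    T1_stderr: float
    S90_stderr: float = np.nan


@dataclass
class T2Fit:
    T2: float
    S0: float
    T2_stderr: float
    S0_stderr: float = np.nan
    n_points_used: int = 0
    excluded_points: list = field(default_factory=list)   # (index, reason)


@dataclass
class RelaxivityFit:
    relaxivity: float          # 1/(mM s)
    intercept_rate: float      # 1/s
    relaxivity_stderr: float
    residuals: np.ndarray = None


# ---------------------------------------------------------------------------
# T1 inversion recovery
# ---------------------------------------------------------------------------

def _ir_model(TI, A, T1, delta):
    return np.abs(A * (1.0 - (1.0 + delta) * np.exp(-TI / T1)))


def fit_t1_ir_arrays(TI, y) -> T1IRFit:
    """Magnitude-IR fit of one signal curve (multi-start over T1 seeds)."""
    TI = np.asarray(TI, dtype=float)
    y = np.asarray(y, dtype=float)
    ymax = float(y.max())
    best = None
    seeds = np.geomspace(0.2 * TI[1], 2.0 * TI[-1], 8)
    for t1_0 in seeds:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, cov = curve_fit(
                    _ir_model, TI, y, p0=[ymax, t1_0, 0.9],
                    bounds=([0.0, 1e-3, 0.0], [np.inf, np.inf, 1.2]),
                    maxfev=5000)
        except RuntimeError:
            continue
        sse = float(np.sum((_ir_model(TI, *p) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, p, cov)
    if best is None:
        raise RuntimeError("inversion-recovery fit did not converge")
    _, p, cov = best
    err = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    return T1IRFit(T1=float(p[1]), A=float(p[0]), delta=float(p[2]),
                   T1_stderr=float(err[1]), A_stderr=float(err[0]),
                   delta_stderr=float(err[2]))


def fit_t1_ir(series: ROISeries, mode="roi_mean", TR=None) -> T1IRFit:
    """Fit the IR model to a ROI series.

    ``roi_mean`` fits the averaged ROI signal; ``voxel_map`` fits every
    voxel independently and averages the T1 map over the ROI (the map mean
    carries the SD of the voxel estimates as its stderr).
    """
    if len(series.x_values) < 4:
        raise ValueError("need at least 4 inversion times")
    if mode == "roi_mean":
        fit = fit_t1_ir_arrays(series.x_values, series.mean_signals)
        fit.mode = mode
        if TR is not None and fit.T1 > TR:
            warnings.warn("fitted T1 exceeds TR; the IR model assumes TR >> T1")
        return fit
    if mode == "voxel_map":
        if series.voxel_signals is None:
            raise ValueError("voxel_map mode needs voxel signals")
        t1s = []
        for v in range(series.voxel_signals.shape[1]):
            try:
                t1s.append(fit_t1_ir_arrays(series.x_values,
                                            series.voxel_signals[:, v]).T1)
            except RuntimeError:
                continue
        t1s = np.array(t1s)
        f = fit_t1_ir_arrays(series.x_values, series.mean_signals)
        return T1IRFit(T1=float(t1s.mean()), A=f.A, delta=f.delta,
                       T1_stderr=float(t1s.std(ddof=1) / np.sqrt(len(t1s))),
                       mode=mode)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# T1 variable flip angle
# ---------------------------------------------------------------------------

def _vfa_model(alpha_deg, S90, T1, TR):
    a = np.deg2rad(alpha_deg)
    E1 = np.exp(-TR / T1)
    return S90 * np.sin(a) * (1.0 - E1) / (1.0 - E1 * np.cos(a))


def vfa_linearized_t1(alpha_deg, y, TR):
    """DESPOT1-style linearization: S/sin a = E1 (S/tan a) + S90 (1 - E1)."""
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    Y = y / np.sin(a)
    X = y / np.tan(a)
    slope, intercept = np.polyfit(X, Y, 1)
    slope = min(max(slope, 1e-6), 1.0 - 1e-9)
    T1 = -TR / np.log(slope)
    S90 = intercept / (1.0 - slope)
    return float(T1), float(S90)


def fit_t1_vfa(series: ROISeries, TR: float) -> VFAFit:
    """Nonlinear VFA fit, initialized from the linearized form."""
    if TR <= 0:
        raise ValueError("TR must be positive")
    alpha = series.x_values
    y = series.mean_signals
    if len(alpha) < 2:
        raise ValueError("need at least two distinct flip angles")
    t1_0, s90_0 = vfa_linearized_t1(alpha, y, TR)
    t1_0 = min(max(t1_0, 1.0), 1e5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, cov = curve_fit(lambda a, S90, T1: _vfa_model(a, S90, T1, TR),
                           alpha, y, p0=[abs(s90_0) + 1e-9, t1_0],
                           bounds=([0.0, 1e-3], [np.inf, np.inf]), maxfev=5000)
    ernst = np.rad2deg(np.arccos(np.exp(-TR / p[1])))
    if alpha.min() > ernst or alpha.max() < ernst:
        warnings.warn("all flip angles on one side of the Ernst angle; "
                      "the VFA fit is ill-conditioned")
    err = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    return VFAFit(T1=float(p[1]), S90=float(p[0]),
                  T1_stderr=float(err[1]), S90_stderr=float(err[0]))


def vfa_two_point_t1(a1_deg, s1, a2_deg, s2, TR):
    """Closed-form two-angle solution (exact on noiseless data)."""
    a1, a2 = np.deg2rad(a1_deg), np.deg2rad(a2_deg)
    X1, Y1 = s1 / np.tan(a1), s1 / np.sin(a1)
    X2, Y2 = s2 / np.tan(a2), s2 / np.sin(a2)
    E1 = (Y2 - Y1) / (X2 - X1)
    return float(-TR / np.log(E1))


# ---------------------------------------------------------------------------
# T2 spin echo
# ---------------------------------------------------------------------------

def estimate_noise_floor(background, multiplier=2.0):
    """Noise-floor level from a signal-free background ROI: mean + k SD."""
    bg = np.asarray(background, dtype=float).ravel()
    return float(bg.mean() + multiplier * bg.std(ddof=1))


def fit_t2_se(series: ROISeries, noise_floor: float | None = None,
              drop_first_echo: bool = False) -> T2Fit:
    """Monoexponential T2 fit with noise-floor / first-echo exclusion."""
    TE = series.x_values
    y = series.mean_signals
    excluded = []
    keep = np.ones(len(TE), dtype=bool)
    if drop_first_echo:
        keep[0] = False
        excluded.append((0, "first echo dropped (anomalously low signal)"))
    if noise_floor is not None:
        below = y < noise_floor
        for i in np.nonzero(below & keep)[0]:
            excluded.append((int(i), "below noise floor"))
        keep &= ~below
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable echo times after exclusions")
    TEk, yk = TE[keep], y[keep]
    t2_0 = max((TEk[-1] - TEk[0]) / max(np.log(max(yk[0], 1e-12) /
                                               max(yk[-1], 1e-12)), 0.1), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, cov = curve_fit(lambda t, S0, T2: S0 * np.exp(-t / T2), TEk, yk,
                           p0=[float(yk[0]), t2_0],
                           bounds=([0.0, 1e-3], [np.inf, np.inf]), maxfev=5000)
    err = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    return T2Fit(T2=float(p[1]), S0=float(p[0]), T2_stderr=float(err[1]),
                 S0_stderr=float(err[0]), n_points_used=int(keep.sum()),
                 excluded_points=excluded)


# ---------------------------------------------------------------------------
# Deviation and relaxivity
# ---------------------------------------------------------------------------

def deviation(measured: float, reference: float) -> float:
    """Signed percent deviation 100 (measured - reference) / reference."""
    if reference is None or not np.isfinite(reference) or reference <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (measured - reference) / reference


def fit_relaxivity(concentrations_mM, times_ms, water_rate_s: float | None = None
                   ) -> RelaxivityFit:
    """Relaxivity line R(C) = r C + R_water, rates in 1/s.

    With ``water_rate_s`` given, the intercept is fixed to the measured
    high-purity-water rate; otherwise both slope and intercept are free.
    """
    C = np.asarray(concentrations_mM, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be non-negative")
    if len(C) < 2:
        raise ValueError("need at least two concentrations")
    R = 1000.0 / np.asarray(times_ms, dtype=float)
    if water_rate_s is not None:
        y = R - water_rate_s
        r = float((C @ y) / (C @ C))
        resid = y - r * C
        dof = max(len(C) - 1, 1)
        stderr = float(np.sqrt((resid @ resid) / dof / (C @ C)))
        return RelaxivityFit(r, float(water_rate_s), stderr, resid)
    A = np.column_stack([C, np.ones_like(C)])
    coef, res_ss, *_ = np.linalg.lstsq(A, R, rcond=None)
    resid = R - A @ coef
    dof = max(len(C) - 2, 1)
    cov = np.linalg.inv(A.T @ A) * (resid @ resid) / dof
    return RelaxivityFit(float(coef[0]), float(coef[1]),
                         float(np.sqrt(cov[0, 0])), resid)
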