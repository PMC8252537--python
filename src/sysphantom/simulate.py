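"""Digital reference object (DRO) generator.

Renders synthetic phantom image series under the standard signal models so
that every analysis stage can be validated against known ground truth:

* inversion recovery (IR):      S(TI) = |A (1 - (1 + delta) exp(-TI/T1))|
* spoiled gradient echo (VFA):  S(a)  = S90 sin a (1-E1)/(1 - E1 cos a),
  E1 = exp(-TR/T1), with its maximum at the Ernst angle cos aE = E1
* spin echo (SE):               S(TE) = S0 exp(-TE/T2)

Rendering pipeline: each sphere is painted with its model signal at the
acquisition settings, with anti-aliased partial volume via supersampling;
sphere centers are displaced by a (similarity + smooth polynomial)
distortion field; intensities are multiplied by a smooth receive-bias
field; Rician magnitude noise is applied last.  Output is deterministic
given the configuration and seed.

Gibbs ringing is not simulated by default; the resolution module provides a
finite-k-space analytic rendering mode for the resolution insets where
truncation artifacts matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

from .geometry import PhantomLayout, SpherePose, WedgeSpec
from .io import ImageVolume


def load_reference_table() -> dict:
    """The bundled (synthetic) reference relaxation-time table at 3 T, 20 C."""
    with resources.files("sysphantom.data").joinpath(
            "reference_synthetic_3T.json").open() as f:
        return json.load(f)


# ---------------------------------------------------------------------------
# Signal models
# ---------------------------------------------------------------------------

def signal_ir(PD, T1, TI, delta=1.0, A_scale=1.0):
    """Magnitude inversion-recovery signal |A (1 - (1+delta) e^{-TI/T1})|.

    ``A = PD * A_scale`` is the fully relaxed amplitude and ``delta`` the
    inversion efficiency (1 for a perfect 180 deg pulse).
    """
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0):
        raise ValueError("T1 must be positive")
    A = PD * A_scale
    return np.abs(A * (1.0 - (1.0 + delta) * np.exp(-np.asarray(TI, float) / T1)))


def signal_vfa(PD, T1, TR, alpha_deg, S90_scale=1.0):
    """Steady-state spoiled-GRE amplitude for flip angle ``alpha_deg``."""
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0) or TR <= 0:
        raise ValueError("TR and T1 must be positive")
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    E1 = np.exp(-TR / T1)
    S90 = PD * S90_scale
    return S90 * np.sin(a) * (1.0 - E1) / (1.0 - E1 * np.cos(a))


def signal_se(PD, T2, TE, S0_scale=1.0):
    """Monoexponential spin-echo decay S0 e^{-TE/T2}."""
    T2 = np.asarray(T2, dtype=float)
    if np.any(T2 <= 0):
        raise ValueError("T2 must be positive")
    return PD * S0_scale * np.exp(-np.asarray(TE, float) / T2)


def ernst_angle_deg(TR, T1):
    """Flip angle maximizing the spoiled-GRE signal, cos aE = e^{-TR/T1}."""
    return float(np.rad2deg(np.arccos(np.exp(-TR / T1))))


# ---------------------------------------------------------------------------
# Configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionSpec:
    sequence: str                       # IR_SE | SE | SPGR_VFA | GRE3D
    TR: float                           # ms
    TE: float = 0.0                     # ms
    TI_list: tuple = ()                 # ms, IR series
    flip_list: tuple = ()               # degrees, VFA series
    flip: float = 90.0                  # degrees, single-volume modes
    voxel: tuple = (1.0, 1.0, 1.0)      # mm
    matrix: tuple = (64, 64, 64)
    slice_thickness: float | None = None  # mm, 2D modes

    def __post_init__(self):
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        for f in tuple(self.flip_list) + (self.flip,):
            if not (0.0 < f <= 180.0):
                raise ValueError("flip angles must lie in (0, 180] degrees")


@dataclass
class RegionProperties:
    """Per-region tissue surrogate: PD (fraction of water), T1 and T2 in ms."""

    PD: float
    T1: float
    T2: float

    def __post_init__(self):
        if not (0.0 <= self.PD <= 1.0):
            raise ValueError("PD must lie in [0, 1]")
        if self.T2 <= 0 or self.T1 < self.T2:
            raise ValueError("need T1 >= T2 > 0")


@dataclass
class DistortionField:
    """Similarity part (rotation/translation/scale) plus a smooth polynomial
    displacement.  ``poly`` maps exponent triples (i, j, k) to 3-vectors of
    mm displacement per (r/100 mm)^(i+j+k); the zero field is the identity."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0
    poly: dict = field(default_factory=dict)
    norm_mm: float = 100.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = self.scale * (pts @ np.asarray(self.rotation).T) + self.translation
        if self.poly:
            u = pts / self.norm_mm
            for (i, j, k), vec in self.poly.items():
                term = (u[:, 0] ** i) * (u[:, 1] ** j) * (u[:, 2] ** k)
                out = out + np.outer(term, np.asarray(vec, dtype=float))
        return out

    def nonlinear_displacement(self, pts: np.ndarray) -> np.ndarray:
        """Only the polynomial (non-similarity) part, evaluated at ``pts``."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.zeros_like(pts)
        u = pts / self.norm_mm
        for (i, j, k), vec in self.poly.items():
            term = (u[:, 0] ** i) * (u[:, 1] ** j) * (u[:, 2] ** k)
            out = out + np.outer(term, np.asarray(vec, dtype=float))
        return out


@dataclass
class BiasField:
    """Smooth multiplicative receive-sensitivity field.

    Polynomial in normalized coordinates u = r / 100 mm; ``coeffs`` maps
    exponent triples to scalars.  An empty dict is the uniform field 1."""

    coeffs: dict = field(default_factory=dict)
    norm_mm: float = 100.0

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.ones(len(pts))
        u = pts / self.norm_mm
        for (i, j, k), c in self.coeffs.items():
            out = out + c * (u[:, 0] ** i) * (u[:, 1] ** j) * (u[:, 2] ** k)
        return out

    def evaluate_grid(self, xs, ys, zs) -> np.ndarray:
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        return self.evaluate(pts).reshape(gx.shape)


@dataclass
class NoiseModel:
    """Rician magnitude noise (Gaussian on two quadrature channels then
    magnitude); ``gaussian`` and ``none`` retained for oracle tests."""

    sigma: float = 0.0
    kind: str = "rician"                # rician | gaussian | none
    seed: int = 0

    def apply(self, data: np.ndarray, rng=None) -> np.ndarray:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "none" or self.sigma == 0.0:
            return data
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        if self.kind == "gaussian":
            return data + rng.normal(0.0, self.sigma, data.shape)
        if self.kind == "rician":
            re = data + rng.normal(0.0, self.sigma, data.shape)
            im = rng.normal(0.0, self.sigma, data.shape)
            return np.hypot(re, im)
        raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class SimulationConfig:
    layout: PhantomLayout
    acquisition: AcquisitionSpec
    regions: dict = field(default_factory=dict)       # name -> RegionProperties
    distortion: DistortionField = field(default_factory=DistortionField)
    bias: BiasField = field(default_factory=BiasField)
    noise: NoiseModel = field(default_factory=NoiseModel)
    origin: tuple = (-110.0, -110.0, -110.0)          # mm, voxel (0,0,0)
    include: tuple = ("fiducials",)                   # fiducials and/or array kinds
    background: str = "water"                         # region name of the fill
    delta: float = 0.85                               # inversion efficiency
    signal_scale: float = 100.0                       # amplitude of PD=1 water
    oversample: int = 3                               # per-axis supersampling


def default_regions() -> dict:
    """Region properties from the bundled reference table."""
    t = load_reference_table()
    regions = {
        "water": RegionProperties(1.0, t["water"]["T1_ms"], t["water"]["T2_ms"]),
        "fiducial": RegionProperties(0.9, t["fiducial"]["T1_ms"], t["fiducial"]["T2_ms"]),
    }
    for kind in ("NiCl2", "MnCl2"):
        for i, (t1, t2) in enumerate(zip(t[kind]["T1_ms"], t[kind]["T2_ms"])):
            regions[f"{kind}_{i + 1}"] = RegionProperties(1.0, t1, t2)
    for i, pd in enumerate(t["PD"]["PD_percent"]):
        regions[f"PD_{i + 1}"] = RegionProperties(
            pd / 100.0, t["PD"]["T1_ms"][i], t["PD"]["T2_ms"][i])
    return regions


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def sphere_occupancy(center, radius, origin, spacing, shape, oversample=3):
    """Partial-volume occupancy of a sphere on the voxel grid.

    Returns (index slices, occupancy array) for the sphere's bounding box.
    Each voxel is supersampled ``oversample`` times per axis and the inside
    fraction box-averaged.
    """
    center = np.asarray(center, dtype=float)
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    lo_idx = np.floor((center - radius) / spacing - origin / spacing - 1).astype(int)
    hi_idx = np.ceil((center + radius) / spacing - origin / spacing + 1).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.asarray(shape) - 1)
    if np.any(hi_idx < lo_idx):
        return None, None
    ax = [np.arange(lo_idx[d], hi_idx[d] + 1) for d in range(3)]
    # sub-voxel sample offsets, centered
    m = oversample
    sub = (np.arange(m) + 0.5) / m - 0.5
    frac = np.zeros(tuple(len(a) for a in ax))
    # separable accumulation over sub-offset triples
    coords = [origin[d] + spacing[d] * ax[d] - center[d] for d in range(3)]
    r2 = radius * radius
    for sx in sub:
        dx2 = (coords[0] + sx * spacing[0]) ** 2
        for sy in sub:
            dy2 = (coords[1] + sy * spacing[1]) ** 2
            dxy2 = dx2[:, None] + dy2[None, :]
            for sz in sub:
                dz2 = (coords[2] + sz * spacing[2]) ** 2
                frac += (dxy2[:, :, None] + dz2[None, None, :]) <= r2
    frac /= m ** 3
    sl = tuple(slice(lo_idx[d], hi_idx[d] + 1) for d in range(3))
    return sl, frac


def _region_signal(props: RegionProperties, acq: AcquisitionSpec, cfg,
                   TI=None, TE=None, flip=None):
    scale = cfg.signal_scale
    if acq.sequence == "IR_SE":
        return float(signal_ir(props.PD, props.T1, TI, cfg.delta, scale)
                     * np.exp(-(TE if TE else acq.TE) / props.T2))
    if acq.sequence == "SE":
        sat = 1.0 - np.exp(-acq.TR / props.T1)
        return float(signal_se(props.PD, props.T2, TE, scale) * sat)
    if acq.sequence in ("SPGR_VFA", "GRE3D"):
        f = flip if flip is not None else acq.flip
        return float(signal_vfa(props.PD, props.T1, acq.TR, f, scale)
                     * np.exp(-acq.TE / props.T2))
    raise ValueError(f"unknown sequence {acq.sequence!r}")


def _spheres_to_render(cfg: SimulationConfig):
    out = []
    for item in cfg.include:
        if item == "fiducials":
            for s in cfg.layout.fiducials:
                out.append((s, "fiducial"))
        elif item in cfg.layout.arrays:
            for s in cfg.layout.arrays[item]:
                out.append((s, f"{item}_{s.id}"))
        else:
            raise ValueError(f"unknown include item {item!r}")
    return out


def render_volume(cfg: SimulationConfig, TI=None, TE=None, flip=None,
                  rng=None) -> ImageVolume:
    """Rasterize one volume of the configured phantom.

    Sphere centers are displaced by the distortion field, intensities are
    multiplied by the bias field, and Rician noise is applied last.
    """
    acq = cfg.acquisition
    spacing = np.asarray(acq.voxel, dtype=float)
    if np.any(spacing >= 10.0):
        raise ValueError("voxel size >= sphere diameter: unresolvable geometry")
    shape = tuple(int(n) for n in acq.matrix)
    regions = cfg.regions or default_regions()
    bg = regions[cfg.background]
    data = np.full(shape, _region_signal(bg, acq, cfg, TI, TE, flip))
    for sphere, region_name in _spheres_to_render(cfg):
        props = regions[region_name]
        sig = _region_signal(props, acq, cfg, TI, TE, flip)
        center = cfg.distortion.apply(sphere.center)[0]
        sl, frac = sphere_occupancy(center, sphere.radius, cfg.origin, spacing,
                                    shape, cfg.oversample)
        if sl is None:
            continue
        data[sl] = data[sl] * (1.0 - frac) + sig * frac
    if cfg.bias.coeffs:
        xs = cfg.origin[0] + spacing[0] * np.arange(shape[0])
        ys = cfg.origin[1] + spacing[1] * np.arange(shape[1])
        zs = cfg.origin[2] + spacing[2] * np.arange(shape[2])
        data = data * cfg.bias.evaluate_grid(xs, ys, zs)
    data = cfg.noise.apply(data, rng)
    meta = {"TR": acq.TR, "TE": TE if TE is not None else acq.TE,
            "TI": TI, "flip": flip if flip is not None else acq.flip,
            "series": acq.sequence}
    return ImageVolume(data, tuple(spacing), cfg.origin, np.eye(3), meta)


def render_series(cfg: SimulationConfig, repeats: int = 1) -> list[ImageVolume]:
    """One volume per TI / TE-step / flip angle (or ``repeats`` identical
    geometry volumes with independent noise draws for SNR measurement)."""
    acq = cfg.acquisition
    rng = np.random.default_rng(cfg.noise.seed)
    vols = []
    if acq.sequence == "IR_SE":
        if not acq.TI_list:
            raise ValueError("IR series needs a nonempty TI list")
        for ti in acq.TI_list:
            vols.append(render_volume(cfg, TI=float(ti), rng=rng))
    elif acq.sequence == "SE":
        te_list = acq.TI_list or None
        tes = [float(t) for t in (te_list or np.arange(10.0, 321.0, 10.0))]
        if acq.TE and not te_list:
            tes = [acq.TE]
        for te in tes:
            vols.append(render_volume(cfg, TE=te, rng=rng))
    elif acq.sequence == "SPGR_VFA":
        if not acq.flip_list:
            raise ValueError("VFA series needs a nonempty flip list")
        for f in acq.flip_list:
            vols.append(render_volume(cfg, flip=float(f), rng=rng))
    elif acq.sequence == "GRE3D":
        for rep in range(max(1, repeats)):
            v = render_volume(cfg, rng=rng)
            v.meta["repeat"] = rep + 1
            vols.append(v)
    else:
        raise ValueError(f"unknown sequence {acq.sequence!r}")
    if not vols:
        raise ValueError("empty series")
    return vols


# ---------------------------------------------------------------------------
# Acquisition presets (modeled on the recommended protocol series)
# ---------------------------------------------------------------------------

#: 10 inversion times from 50 ms to 3000 ms (log-spaced within the stated
#: range), TR = 4500 ms.
IR_TI_LIST = (50.0, 79.0, 125.0, 197.0, 311.0, 491.0, 776.0, 1225.0, 1935.0, 3000.0)

PRESETS = {
    "T1-IR": AcquisitionSpec("IR_SE", TR=4500.0, TE=10.0, TI_list=IR_TI_LIST,
                             voxel=(1.0, 1.0, 6.0), matrix=(128, 128, 1)),
    "T1-VFA": AcquisitionSpec("SPGR_VFA", TR=5.37, TE=1.49,
                              flip_list=(2, 3, 5, 7, 9, 11, 14, 18, 24, 30),
                              voxel=(1.0, 1.0, 1.0), matrix=(128, 128, 1)),
    "T2-SE": AcquisitionSpec("SE", TR=5000.0, voxel=(1.0, 1.0, 6.0),
                             matrix=(128, 128, 1)),
    "fiducial-GRE3D": AcquisitionSpec("GRE3D", TR=6.3, TE=1.89, flip=10.0,
                                      voxel=(1.0, 1.0, 1.0),
                                      matrix=(220, 220, 220)),
}


# ---------------------------------------------------------------------------
# Wedge (slice profile) rendering — 2D slice through the paired wedges
# ---------------------------------------------------------------------------

def wedge_erf(x, ramp_start, slope, thickness, profile="boxcar"):
    """Edge response of a slice of given thickness crossing a wedge ramp.

    ``slope`` = tan(effective wedge angle); for a boxcar slice-sensitivity
    profile the response rises linearly from 0 to ``thickness`` over the
    projected width thickness/slope; a Gaussian profile (FWHM = thickness)
    gives a smoothed ramp.
    """
    h = (np.asarray(x, dtype=float) - ramp_start) * slope
    if profile == "boxcar":
        return np.clip(h, 0.0, thickness)
    if profile == "gaussian":
        from scipy.stats import norm
        sigma = thickness / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        # integral of the Gaussian profile over material below height h
        hh = h - thickness / 2.0
        return thickness * norm.cdf(hh / sigma)
    raise ValueError(f"unknown profile {profile!r}")


def render_wedge_slice(thickness_mm, theta_deg=0.0, pixel_mm=0.25,
                       wedge: WedgeSpec | None = None, profile="boxcar",
                       noise: NoiseModel | None = None, signal_scale=100.0):
    """2D image of the two opposed 10-degree wedges seen by one slice.

    A slice-plane tilt ``theta`` makes the effective angles 10 + theta and
    10 - theta for the positive and negative wedge.  Returns the image and
    the two rectangular ROIs (index slices) matching the 4 mm x 50 mm
    analysis rectangles.
    """
    wedge = wedge or WedgeSpec()
    if thickness_mm > wedge.height_mm:
        raise ValueError("slice thickness exceeds the wedge height")
    nx = int(round(60.0 / pixel_mm))
    ny = int(round(16.0 / pixel_mm))
    x = (np.arange(nx) + 0.5) * pixel_mm
    img = np.zeros((nx, ny))
    rois = {}
    bands = {+1: (2.0, 6.0), -1: (10.0, 14.0)}
    for orient in wedge.orientations:
        alpha = np.deg2rad(wedge.wedge_angle_deg + orient * theta_deg)
        slope = np.tan(alpha)
        # ramp begins 13 mm into the image so that smooth (Gaussian)
        # profiles keep their tails inside the 50 mm analysis rectangle
        if orient > 0:
            erf = wedge_erf(x, 13.0, slope, thickness_mm, profile)
        else:
            erf = wedge_erf(55.0 - x, 13.0, slope, thickness_mm, profile)
        y0, y1 = bands[orient]
        j0, j1 = int(round(y0 / pixel_mm)), int(round(y1 / pixel_mm))
        img[:, j0:j1] = np.maximum(img[:, j0:j1], erf[:, None])
        i0 = int(round(5.0 / pixel_mm))
        i1 = i0 + int(round(wedge.roi_length_mm / pixel_mm))
        rois[orient] = (slice(max(0, i0 - 1), min(nx, i1 + 1)), slice(j0, j1))
    img *= signal_scale / thickness_mm
    if noise is not None:
        img = noise.apply(img)
    return img, rois


# ---------------------------------------------------------------------------
# Disk rasterization oracle (shared by resolution tests)
# ---------------------------------------------------------------------------

def rasterize_disks(holes, voxel_mm, extent, oversample=8, signal=1.0):
    """Direct high-resolution rasterization of a hole (disk) pattern,
    box-downsampled to the acquisition grid.  ``extent`` is
    ((x0, x1), (y0, y1)) in mm; returns the 2D image."""
    (x0, x1), (y0, y1) = extent
    nx = int(round((x1 - x0) / voxel_mm))
    ny = int(round((y1 - y0) / voxel_mm))
    m = oversample
    fx = x0 + (np.arange(nx * m) + 0.5) * voxel_mm / m
    fy = y0 + (np.arange(ny * m) + 0.5) * voxel_mm / m
    hi = np.zeros((nx * m, ny * m))
    for (cx, cy), d, _ang in holes:
        r = d / 2.0
        ix = np.nonzero(np.abs(fx - cx) <= r)[0]
        iy = np.nonzero(np.abs(fy - cy) <= r)[0]
        if len(ix) == 0 or len(iy) == 0:
            continue
        dx2 = (fx[ix] - cx) ** 2
        dy2 = (fy[iy] - cy) ** 2
        mask = dx2[:, None] + dy2[None, :] <= r * r
        hi[np.ix_(ix, iy)] = np.where(mask, signal, hi[np.ix_(ix, iy)])
    return hi.reshape(nx, m, ny, m).mean(axis=(1, 3))
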