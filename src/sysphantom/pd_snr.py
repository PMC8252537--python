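"""Proton-density quantification and SNR from replicate images.

Proton density (PD) is measured on the PD-array spin-echo image by
normalizing each sphere's ROI mean to the *local* background — the mean of
four small spherical samples taken 3 mm outside the sphere wall along the
in-plate directions (+/-x, +/-z) — and then scaling all ratios so the 100%
water sphere reads 100.  The local normalization removes the smooth receive
bias that makes raw signal nonlinear in PD.

SNR uses the two-acquisition difference method: with replicate images S1,
S2 and their difference dS = S2 - S1,

    S_av = (S1_av + S2_av) / 2,   N = SD(dS within ROI) / sqrt(2),
    SNR = S_av / N.

The within-ROI mean/SD ("spatial") ratio is also reported; it mixes noise
with structural nonuniformity and is kept separate from SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PhantomLayout
from .io import ImageVolume


def _spherical_roi_mean(volume: ImageVolume, center_mm, radius_mm):
    spacing = np.asarray(volume.spacing, dtype=float)
    idx_c = volume.world_to_index(center_mm)[0]
    half = np.ceil(radius_mm / spacing).astype(int) + 1
    lo = np.maximum(np.round(idx_c).astype(int) - half, 0)
    hi = np.minimum(np.round(idx_c).astype(int) + half,
                    np.array(volume.data.shape) - 1)
    ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    dist2 = np.zeros([len(a) for a in ax])
    for d, a in enumerate(ax):
        if spacing[d] <= 2 * radius_mm:
            sh = [1, 1, 1]
            sh[d] = len(a)
            dist2 = dist2 + (((a - idx_c[d]) * spacing[d]) ** 2).reshape(sh)
    m = dist2 <= radius_mm ** 2
    box = volume.data[tuple(slice(l, h + 1) for l, h in zip(lo, hi))]
    return box[m]


@dataclass
class PDResult:
    table: pd.DataFrame    # id, prescribed %, raw mean, background, measured %, error pp


def measure_pd(volume: ImageVolume, layout: PhantomLayout, prescribed_pd=None,
               transform=None, roi_diameter_mm=10.0, background_offset_mm=3.0,
               background_radius_vox=3.0) -> PDResult:
    """Measure the 14 PD-array spheres on a short-TE spin-echo image.

    ``transform`` (phantom -> scanner similarity) maps nominal centers into
    the image frame; identity when the phantom is already aligned.  If a
    background sample lands inside a neighboring sphere (detected as a
    sample deviating > 50% from the median of the four), it is re-sampled at
    offsets rotated 45 degrees in-plane and the sphere flagged.
    """
    spheres = layout.arrays["PD"]
    centers = np.array([s.center for s in spheres])
    if transform is not None:
        centers = transform.apply(centers)
    spacing = np.asarray(volume.spacing, dtype=float)
    bg_r = background_radius_vox * float(np.min(spacing))
    rows = []
    for s, c in zip(spheres, centers):
        roi = _spherical_roi_mean(volume, c, roi_diameter_mm / 2.0)
        raw = float(roi.mean())
        off = s.radius + background_offset_mm + bg_r
        offsets = np.array([[off, 0, 0], [-off, 0, 0], [0, 0, off], [0, 0, -off]])
        flag = False
        samples = np.array([
            _spherical_roi_mean(volume, c + o, bg_r).mean() for o in offsets])
        med = np.median(samples)
        bad = np.abs(samples - med) > 0.5 * abs(med)
        if np.any(bad):
            flag = True
            rot = np.array([[off, 0, off], [-off, 0, off],
                            [off, 0, -off], [-off, 0, -off]]) / np.sqrt(2)
            for i in np.nonzero(bad)[0]:
                samples[i] = _spherical_roi_mean(volume, c + rot[i], bg_r).mean()
        bg = float(samples.mean())
        rows.append((s.id, raw, bg, raw / bg, flag))
    tab = pd.DataFrame(rows, columns=["id", "raw_mean", "background",
                                      "ratio", "flag"])
    if prescribed_pd is None:
        from .simulate import load_reference_table
        prescribed_pd = load_reference_table()["PD"]["PD_percent"]
    prescribed_pd = np.asarray(prescribed_pd, dtype=float)
    tab["prescribed_pd"] = prescribed_pd
    i100 = int(np.argmax(prescribed_pd))
    tab["measured_pd"] = 100.0 * tab["ratio"] / tab["ratio"].iloc[i100]
    tab["error_pp"] = tab["measured_pd"] - tab["prescribed_pd"]
    return PDResult(tab)


@dataclass
class SNRResult:
    table: pd.DataFrame    # roi id, S_av, noise, SNR, spatial ratio, flag


def estimate_snr(volume1: ImageVolume, volume2: ImageVolume, rois,
                 roi_diameter_mm=10.0) -> SNRResult:
    """Difference-method SNR for each ROI center (scanner frame, mm).

    ``rois`` is an (n, 3) array of ROI centers.  Identical replicate images
    (N = 0) are flagged and SNR reported as NaN.  No drift correction is
    applied; the method assumes temporally stable replicates.
    """
    if volume1.data.shape != volume2.data.shape:
        raise ValueError("replicate volumes must share geometry")
    rows = []
    r = roi_diameter_mm / 2.0
    for k, c in enumerate(np.atleast_2d(np.asarray(rois, dtype=float)), start=1):
        a = _spherical_roi_mean(volume1, c, r)
        b = _spherical_roi_mean(volume2, c, r)
        s_av = 0.5 * (a.mean() + b.mean())
        d = b - a
        sd = float(d.std(ddof=1))
        noise = sd / np.sqrt(2.0)
        flag = noise == 0.0
        snr = np.nan if flag else float(s_av / noise)
        spatial = float(a.mean() / a.std(ddof=1)) if a.std(ddof=1) > 0 else np.nan
        rows.append((k, float(s_av), noise, snr, spatial, flag))
    return SNRResult(pd.DataFrame(
        rows, columns=["roi", "S_av", "noise", "SNR", "spatial_ratio", "flag"]))
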