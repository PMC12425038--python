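"""fBIRN/ABCD phantom quality-assurance battery for 4D fMRI time series.

Metrics follow the fBIRN stability conventions: per-voxel 2nd-order
Legendre detrending; SFNR as the ROI mean of (temporal mean / residual
SD); SNR from the odd/even volume-sum difference image; the Weisskoff
plot F(N) (temporal CV of the mean over N x N ROIs) and its radius of
decorrelation RDC = F(1)/F(Nmax); per-axis spatial FWHM from the lag-1
autocorrelation of the detrended residuals (Gaussian-equivalent,
AFNI-style); and the EPI ghost-to-signal ratio from ROIs displaced by
FOV/2 along the phase-encode axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .recon import ImageTimeSeries

#: Sentinel SFNR cap for (near-)constant series instead of infinity.
SFNR_CAP = 1e6


@dataclass
class ROISpec:
    """ROI conventions of the QA battery (fBIRN defaults)."""

    center: Optional[Tuple[int, int]] = None  # in-plane voxel; None = center of mass
    slice_index: Optional[int] = None  # None = center slice
    signal_roi: int = 21  # square signal ROI side
    weisskoff_widths: Tuple[int, ...] = tuple(range(1, 22))
    ghost_roi: int = 8  # background/ghost corner ROI side
    pe_axis: int = 1  # phase-encode axis of the in-plane image


@dataclass
class QAReport:
    """The fBIRN/ABCD metric set."""

    mean_signal: float
    snr: float
    sfnr: float
    rms_residual_percent: float
    drift_percent: float
    rdc: float
    rdc_flag: str
    fwhm_x_mm: float
    fwhm_y_mm: float
    fwhm_z_mm: float
    fwhm_flags: Tuple[str, str, str]
    ghost_to_signal: float
    sfnr_flag: str
    weisskoff_widths: List[int]
    weisskoff_f: List[float]
    protocol: Dict[str, object]

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"mean signal        {self.mean_signal:.2f}",
            f"SNR                {self.snr:.2f}",
            f"SFNR               {self.sfnr:.2f}",
            f"RMS residual [%]   {self.rms_residual_percent:.4f}",
            f"drift [%]          {self.drift_percent:.4f}",
            f"RDC                {self.rdc:.2f} {self.rdc_flag}",
            f"FWHM x/y/z [mm]    {self.fwhm_x_mm:.2f} / {self.fwhm_y_mm:.2f} / "
            f"{self.fwhm_z_mm:.2f}",
            f"ghost/signal       {self.ghost_to_signal:.5f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def legendre_detrend(ts: np.ndarray, order: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Remove a Legendre polynomial trend along the last axis.

    Returns (residuals, fitted_trend)."""
    nt = ts.shape[-1]
    x = np.linspace(-1.0, 1.0, nt)
    basis = np.stack([np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)], axis=1)
    flat = ts.reshape(-1, nt).T  # (nt, nvox)
    coef, *_ = np.linalg.lstsq(basis, flat, rcond=None)
    trend = (basis @ coef).T.reshape(ts.shape)
    return ts - trend, trend


# ---------------------------------------------------------------------------
# ROI helpers
# ---------------------------------------------------------------------------

def _center_slice(ts: ImageTimeSeries, roi: ROISpec) -> Tuple[np.ndarray, int]:
    z = roi.slice_index if roi.slice_index is not None else ts.data.shape[2] // 2
    return ts.data[:, :, z, :], z


def _roi_center(img: np.ndarray, roi: ROISpec) -> Tuple[int, int]:
    if roi.center is not None:
        return roi.center
    w = img.astype(float)
    tot = w.sum()
    if tot <= 0:
        return img.shape[0] // 2, img.shape[1] // 2
    cx = int(round((w.sum(axis=1) * np.arange(img.shape[0])).sum() / tot))
    cy = int(round((w.sum(axis=0) * np.arange(img.shape[1])).sum() / tot))
    return cx, cy


def _square(data: np.ndarray, cx: int, cy: int, width: int) -> np.ndarray:
    x0 = cx - width // 2
    y0 = cy - width // 2
    x0 = max(0, min(x0, data.shape[0] - width))
    y0 = max(0, min(y0, data.shape[1] - width))
    return data[x0 : x0 + width, y0 : y0 + width]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_signal_sfnr_snr(
    ts: ImageTimeSeries, roi: Optional[ROISpec] = None
) -> Tuple[float, float, float, Dict[str, float]]:
    """Mean signal, SFNR and SNR on the center-slice signal ROI.

    SFNR: ROI mean of (temporal mean / SD of 2nd-order-detrended
    residuals).  SNR (fBIRN): ROI mean signal divided by the SD of the
    odd-even volume-sum difference image in the ROI over sqrt(nt).
    """
    roi = roi or ROISpec()
    slab, _z = _center_slice(ts, roi)
    nt = slab.shape[-1]
    if nt < 4 or nt % 2:
        raise ValueError("compute_signal_sfnr_snr: need nt >= 4 and even")
    mean_img = slab.mean(axis=-1)
    cx, cy = _roi_center(mean_img, roi)
    resid, trend = legendre_detrend(slab)
    sd = resid.std(axis=-1, ddof=1)
    mean_roi = _square(mean_img, cx, cy, roi.signal_roi)
    sd_roi = _square(sd, cx, cy, roi.signal_roi)
    mean_signal = float(mean_roi.mean())
    flag = ""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd_roi > 0, mean_roi / sd_roi, SFNR_CAP)
    if np.any(sd_roi == 0):
        flag = "constant-series: SFNR capped"
    sfnr = float(np.minimum(ratio, SFNR_CAP).mean())
    odd = slab[..., 1::2].sum(axis=-1)
    even = slab[..., 0::2].sum(axis=-1)
    diff_roi = _square(odd - even, cx, cy, roi.signal_roi)
    noise_sd = float(diff_roi.std(ddof=1)) / np.sqrt(nt)
    snr = mean_signal / noise_sd if noise_sd > 0 else SFNR_CAP
    # fluctuation and drift of the ROI-mean time course (fBIRN style)
    roi_tc = np.array([
        _square(slab[..., t], cx, cy, roi.signal_roi).mean() for t in range(nt)
    ])
    tc_resid, tc_trend = legendre_detrend(roi_tc[None, :])
    rms_residual = float(
        100.0 * np.sqrt(np.mean(tc_resid[0] ** 2)) / max(roi_tc.mean(), 1e-30)
    )
    drift = float(
        100.0 * (tc_trend[0].max() - tc_trend[0].min()) / max(roi_tc.mean(), 1e-30)
    )
    extras = {"rms_residual_percent": rms_residual, "drift_percent": drift,
              "sfnr_flag": flag}
    return mean_signal, sfnr, float(snr), extras


def weisskoff_rdc(
    ts: ImageTimeSeries, roi: Optional[ROISpec] = None
) -> Tuple[float, np.ndarray, np.ndarray, str]:
    """Weisskoff stability analysis.

    F(N) is the temporal coefficient of variation of the mean signal over
    an N x N ROI after detrending; RDC = F(1)/F(Nmax).  For spatially
    independent noise F(N) = F(1)/N, so RDC approaches Nmax; fully
    correlated fluctuations give RDC near 1.  The returned RDC is clipped
    to [1, Nmax] with a flag when it hits a bound.
    """
    roi = roi or ROISpec()
    widths = np.asarray(roi.weisskoff_widths)
    if widths.size < 2:
        raise ValueError("weisskoff_rdc: need at least two ROI widths")
    slab, _z = _center_slice(ts, roi)
    mean_img = slab.mean(axis=-1)
    cx, cy = _roi_center(mean_img, roi)
    f = np.zeros(widths.size)
    for i, w in enumerate(widths):
        tc = _square(slab, cx, cy, int(w)).mean(axis=(0, 1))
        resid, _ = legendre_detrend(tc[None, :])
        m = tc.mean()
        f[i] = resid[0].std(ddof=1) / m if m > 0 else 0.0
    nmax = float(widths.max())
    rdc = f[0] / f[-1] if f[-1] > 0 else nmax
    flag = ""
    if rdc < 1.0:
        rdc, flag = 1.0, "clipped-low"
    elif rdc > nmax:
        rdc, flag = nmax, "clipped-high"
    return float(rdc), widths, f, flag


def spatial_fwhm(
    ts: ImageTimeSeries,
    mask: Optional[np.ndarray] = None,
) -> Tuple[Tuple[float, float, float], Tuple[str, str, str]]:
    """Gaussian-equivalent spatial smoothness of the noise, per axis.

    Estimated from the lag-1 spatial autocorrelation r1 of the detrended
    residuals: FWHM = dx * sqrt(-2 ln 2 / ln r1) for 0 < r1 < 1.  Values
    with r1 <= 0 are reported as a sub-voxel floor with a flag.
    """
    data = ts.data
    if mask is None:
        mean_img = data.mean(axis=-1)
        mask = mean_img > 0.2 * mean_img.max()
    resid, _ = legendre_detrend(data)
    fwhm: List[float] = []
    flags: List[str] = []
    for axis in range(3):
        if data.shape[axis] < 8:
            fwhm.append(float("nan"))
            flags.append("axis-too-short")
            continue
        a = np.moveaxis(resid, axis, 0)
        m = np.moveaxis(mask, axis, 0)
        pair = m[:-1] & m[1:]
        x0 = a[:-1][pair]
        x1 = a[1:][pair]
        denom = np.sqrt((x0**2).mean() * (x1**2).mean())
        r1 = float((x0 * x1).mean() / denom) if denom > 0 else 0.0
        dx = ts.voxel_size[axis] * 1e3  # mm
        if r1 <= 0:
            fwhm.append(dx * 0.5)
            flags.append("r1<=0: sub-voxel floor")
        elif r1 >= 1:
            fwhm.append(float("inf"))
            flags.append("r1>=1")
        else:
            fwhm.append(dx * np.sqrt(-2.0 * np.log(2.0) / np.log(r1)))
            flags.append("")
    return (fwhm[0], fwhm[1], fwhm[2]), (flags[0], flags[1], flags[2])


def ghost_signal_ratio(
    volume: np.ndarray, roi: Optional[ROISpec] = None
) -> float:
    """EPI N/2 ghost-to-signal ratio of one 2D image.

    GSR = (mean ghost ROI - mean background ROI) / mean signal ROI; the
    ghost ROI is the signal ROI translated by FOV/2 along the phase-encode
    axis; the background is the average of the four corner ROIs.
    """
    roi = roi or ROISpec()
    img = np.asarray(volume, dtype=float)
    if img.ndim != 2:
        raise ValueError("ghost_signal_ratio: expects a 2D image")
    if roi.pe_axis == 0:
        from dataclasses import replace as _rep

        center = (roi.center[1], roi.center[0]) if roi.center else None
        return ghost_signal_ratio(img.T, _rep(roi, pe_axis=1, center=center))
    cx, cy = _roi_center(img, roi)
    n_pe = img.shape[1]
    w = roi.signal_roi
    wg = roi.ghost_roi  # ghost/background ROIs are the small boxes; a QA
    # ball larger than half the PE FOV leaves no room for a full-size one
    signal = _square(img, cx, cy, w).mean()
    gx, gy = cx, (cy + n_pe // 2) % n_pe
    # overlap guard: ghost ROI must not intersect the signal ROI
    dpe = (gy - cy) % n_pe
    dpe = min(dpe, n_pe - dpe)
    if dpe < (w + wg) / 2:
        raise ValueError("ghost_signal_ratio: ghost and signal ROIs overlap")
    # ghost region: the object mask translated by FOV/2 along PE, minus a
    # 1-voxel-dilated copy of the object itself.  With a QA ball wider
    # than half the PE FOV, a fixed box would clip the object edge; the
    # mask form measures the ghost where it actually lands.
    from scipy.ndimage import binary_dilation

    support = img > 0.3 * img.max()
    dilated = binary_dilation(support, iterations=2)
    ghost_mask = np.roll(support, n_pe // 2, axis=1) & ~dilated
    if ghost_mask.sum() >= 4:
        ghost = float(img[ghost_mask].mean())
    else:
        xs = (np.arange(gx - wg // 2, gx - wg // 2 + wg)) % img.shape[0]
        ys = (np.arange(gy - wg // 2, gy - wg // 2 + wg)) % img.shape[1]
        ghost = float(img[np.ix_(xs, ys)].mean())
    b = roi.ghost_roi
    avoid = dilated | np.roll(dilated, n_pe // 2, axis=1)
    while b > 2:
        boxes = [avoid[:b, :b], avoid[:b, -b:], avoid[-b:, :b],
                 avoid[-b:, -b:]]
        if not any(bx.any() for bx in boxes):
            break
        b -= 1
    corners = [img[:b, :b], img[:b, -b:], img[-b:, :b], img[-b:, -b:]]
    background = float(np.mean([c.mean() for c in corners]))
    if signal <= 0:
        return 0.0
    return float((ghost - background) / signal)


def run_qa(
    ts: ImageTimeSeries,
    roi: Optional[ROISpec] = None,
    protocol_info: Optional[Dict[str, object]] = None,
) -> QAReport:
    """Aggregate the full metric battery into a QAReport."""
    from . import __version__

    roi = roi or ROISpec()
    mean_signal, sfnr, snr, extras = compute_signal_sfnr_snr(ts, roi)
    rdc, widths, f, rdc_flag = weisskoff_rdc(ts, roi)
    (fx, fy, fz), fflags = spatial_fwhm(ts)
    slab, _z = _center_slice(ts, roi)
    gsr = ghost_signal_ratio(slab.mean(axis=-1), roi)
    info = dict(protocol_info or {})
    info.update(
        {
            "tr_s": ts.tr,
            "matrix": list(ts.data.shape[:3]),
            "n_volumes": int(ts.data.shape[3]),
            "voxel_size_mm": [v * 1e3 for v in ts.voxel_size],
            "software_version": __version__,
            "roi_conventions": "fBIRN: 21x21 center-slice signal ROI, "
            "Weisskoff widths 1-21, 8x8 corner background ROIs",
        }
    )
    return QAReport(
        mean_signal=mean_signal,
        snr=snr,
        sfnr=sfnr,
        rms_residual_percent=extras["rms_residual_percent"],
        drift_percent=extras["drift_percent"],
        rdc=rdc,
        rdc_flag=rdc_flag,
        fwhm_x_mm=fx,
        fwhm_y_mm=fy,
        fwhm_z_mm=fz,
        fwhm_flags=fflags,
        ghost_to_signal=gsr,
        sfnr_flag=extras["sfnr_flag"],
        weisskoff_widths=[int(w) for w in widths],
        weisskoff_f=[float(v) for v in f],
        protocol=info,
    )
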