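"""Harmonized SMS-EPI reconstruction chain.

Fixed deterministic order per volume: odd/even phase correction (estimated
once from the single-band reference segment's navigators), least-squares
regridding of ramp samples onto the Cartesian kx grid, SMS unaliasing
(slice GRAPPA in k-space, or SENSE in the image domain), zero-filled
partial Fourier, unitary inverse FFT, and root-sum-of-squares coil
combination.  Dummy volumes are dropped; the result is written as a 4D
NIfTI with the protocol voxel size and TR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .protocol import (
    ProtocolParams,
    caipi_band_const,
    caipi_band_shift_voxels,
)
from .simulator import RawKSpace


class ReconError(ValueError):
    pass


# ---------------------------------------------------------------------------
# odd/even (Nyquist ghost) phase correction
# ---------------------------------------------------------------------------

@dataclass
class PhaseCorrection:
    """Constant and per-sample linear phase of negative-polarity echoes."""

    theta0: float  # rad
    theta1: float  # rad per acquisition sample

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta0) and np.isfinite(self.theta1)):
            raise ValueError("PhaseCorrection: parameters must be finite")
        if abs(self.theta1) >= np.pi / 2:
            raise ValueError("PhaseCorrection: |theta1| must be < pi/2 per sample")


def estimate_phase_correction(raw: RawKSpace) -> PhaseCorrection:
    """Estimate the odd/even phase from navigator echoes.

    Negative-polarity navigators are sample-reversed onto the positive
    readout direction; the phase of the magnitude-weighted cross-
    correlation with the positive navigators is fit linearly in the
    acquisition sample index.
    """
    nav = raw.nav
    if nav.size == 0 or not np.any(np.abs(nav) > 0):
        raise ReconError("estimate_phase_correction: all-zero navigators")
    pol = raw.nav_polarity
    pos = np.nonzero(pol == 1)[0]
    neg = np.nonzero(pol == -1)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ReconError(
            "estimate_phase_correction: need navigators of both polarities"
        )
    # average navs over volumes/shots per polarity
    nav_pos = nav[:, :, pos].mean(axis=(0, 1, 2))  # (nc, nsamp)
    nav_neg = nav[:, :, neg].mean(axis=(0, 1, 2))
    nsamp = nav_pos.shape[-1]
    # align polarities by kx position: negative-polarity sample j sits at
    # -kx[j]; pair it with the positive sample measuring the same kx (the
    # grids need not be mirror-symmetric)
    kx = np.asarray(raw.kx, dtype=float)
    dk = np.median(np.abs(np.diff(kx))) if nsamp > 1 else 1.0
    match = np.searchsorted(kx, -kx)
    match = np.clip(match, 0, nsamp - 1)
    prev = np.clip(match - 1, 0, nsamp - 1)
    pick_prev = np.abs(kx[prev] + kx) < np.abs(kx[match] + kx)
    match = np.where(pick_prev, prev, match)
    ok = np.abs(kx[match] + kx) < dk / 4
    j = np.nonzero(ok)[0]
    xcorr = (nav_neg[:, j] * np.conj(nav_pos[:, match[j]])).sum(axis=0)
    w = np.abs(xcorr)
    good = w > 0.05 * w.max()
    phase = np.unwrap(np.angle(xcorr))
    # phase(j) = theta0 + theta1 * j in acquisition sample order
    A = np.stack([np.ones(j.size), j.astype(float)], axis=1)
    Wd = w * good
    AtW = A.T * Wd
    coef = np.linalg.solve(AtW @ A, AtW @ phase)
    theta0 = float(np.mod(coef[0] + np.pi, 2 * np.pi) - np.pi)
    return PhaseCorrection(theta0=theta0, theta1=float(coef[1]))


def apply_phase_correction(
    data: np.ndarray, polarity: np.ndarray, pc: PhaseCorrection
) -> np.ndarray:
    """Remove the odd/even phase: multiply negative-polarity echoes by
    exp(-i (theta0 + theta1 n)) in acquisition sample order.

    `data` has echoes on axis -3 and samples on axis -1.
    """
    nsamp = data.shape[-1]
    corr = np.exp(-1j * (pc.theta0 + pc.theta1 * np.arange(nsamp)))
    out = data.copy()
    neg = np.asarray(polarity) == -1
    out[..., neg, :, :] = out[..., neg, :, :] * corr
    return out


# ---------------------------------------------------------------------------
# ramp-sampling regridding
# ---------------------------------------------------------------------------

class RampRegridder:
    """Least-squares interpolation of (possibly ramp-sampled) readout
    samples onto the uniform Cartesian kx grid.

    The sampled signal is modeled as the DFT of an nx-voxel object row
    evaluated at the measured kx positions; the Cartesian line is the DFT
    of the least-squares object estimate.  When the samples already lie on
    the Cartesian grid this reduces to the identity.
    """

    def __init__(self, kx: np.ndarray, nx: int, fov_x: float):
        kx = np.asarray(kx, dtype=float)
        dk = 1.0 / fov_x
        grid = (np.arange(nx) - nx // 2) * dk
        if grid.max() > kx.max() + dk / 2 + 1e-9 or grid.min() < kx.min() - dk / 2 - 1e-9:
            raise ReconError(
                "RampRegridder: target grid bandwidth exceeds the sampled extent"
            )
        vx = fov_x / nx
        xpos = (np.arange(nx) - nx // 2) * vx
        scale = 1.0 / np.sqrt(nx)
        E_pos = np.exp(-2j * np.pi * np.outer(kx, xpos)) * scale
        E_neg = np.exp(-2j * np.pi * np.outer(-kx, xpos)) * scale
        F = np.exp(-2j * np.pi * np.outer(grid, xpos)) * scale
        self.R_pos = F @ np.linalg.pinv(E_pos, rcond=1e-10)
        self.R_neg = F @ np.linalg.pinv(E_neg, rcond=1e-10)
        self.nx = nx

    def apply(self, data: np.ndarray, polarity: np.ndarray) -> np.ndarray:
        """Regrid (..., n_echoes, ncoils, nsamp) -> (..., n_echoes, ncoils, nx)."""
        pol = np.asarray(polarity)
        out_shape = data.shape[:-1] + (self.nx,)
        out = np.empty(out_shape, dtype=complex)
        pos = pol == 1
        neg = pol == -1
        out[..., pos, :, :] = np.tensordot(
            data[..., pos, :, :], self.R_pos, axes=([-1], [1])
        )
        out[..., neg, :, :] = np.tensordot(
            data[..., neg, :, :], self.R_neg, axes=([-1], [1])
        )
        return out


def regrid_ramp_samples(
    samples: np.ndarray,
    kx: np.ndarray,
    nx: int,
    fov_x: float,
    polarity: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Convenience wrapper: regrid echoes of shape (..., n_echoes, nc, nsamp)."""
    rg = RampRegridder(kx, nx, fov_x)
    if polarity is None:
        polarity = np.ones(samples.shape[-3], dtype=int)
    return rg.apply(samples, polarity)


# ---------------------------------------------------------------------------
# slice GRAPPA
# ---------------------------------------------------------------------------

#: Weight of the (partly synthetic) zero-padded border rows in the kernel fit.
BORDER_WEIGHT = 0.25


@dataclass
class SliceGrappaKernels:
    """Per-(shot-group, band) unaliasing kernels.

    kernels[g][b]: (kx_k * ky_k * nc, nc) complex weight matrix mapping a
    collapsed-k-space patch to the center sample of band b (in its
    CAIPI-shifted frame); `residual[g][b]` is the relative calibration
    residual.
    """

    kernel_size: Tuple[int, int]
    kernels: List[List[np.ndarray]]
    residual: List[List[float]]
    band_slices: np.ndarray  # (ngroups, nbands)
    caipi_phase: np.ndarray  # (ne, nbands)


def _patches(k: np.ndarray, kk: Tuple[int, int]) -> np.ndarray:
    """im2col: (nx, ne, nc) -> (n_valid, kx_k*ky_k*nc) sliding patches."""
    nx, ne, nc = k.shape
    kx_k, ky_k = kk
    vx = nx - kx_k + 1
    vy = ne - ky_k + 1
    if vx <= 0 or vy <= 0:
        raise ReconError("slice GRAPPA: calibration smaller than the kernel")
    s = np.lib.stride_tricks.sliding_window_view(k, (kx_k, ky_k), axis=(0, 1))
    # (vx, vy, nc, kx_k, ky_k) -> (vx*vy, kx_k*ky_k*nc)
    return s.transpose(0, 1, 3, 4, 2).reshape(vx * vy, kx_k * ky_k * nc)


def calibrate_slice_grappa(
    cal_k: np.ndarray,
    band_slices: np.ndarray,
    caipi_phase: np.ndarray,
    kernel_size: Tuple[int, int] = (7, 7),
) -> SliceGrappaKernels:
    """Fit slice-GRAPPA kernels from single-band calibration k-space.

    cal_k: (n_slices, nx, ne, nc) Cartesian calibration data (already
    phase-corrected and regridded).  For every shot group the collapsed
    calibration is synthesized as the CAIPI-phase-weighted sum of its
    bands; per band a kernel is fit by least squares to map collapsed
    patches to the band's (phase-weighted) center samples.
    """
    if kernel_size[0] % 2 == 0 or kernel_size[1] % 2 == 0:
        raise ValueError("calibrate_slice_grappa: kernel dims must be odd")
    ngroups, nbands = band_slices.shape
    ne, nb_tab = caipi_phase.shape
    if nb_tab != nbands:
        raise ReconError("calibrate_slice_grappa: CAIPI table/band mismatch")
    kernels: List[List[np.ndarray]] = []
    residuals: List[List[float]] = []
    cx, cy = kernel_size[0] // 2, kernel_size[1] // 2
    for g in range(ngroups):
        bands = band_slices[g]
        nxc, nec, nc = cal_k[bands[0]].shape
        collapsed = np.zeros_like(cal_k[bands[0]])
        for b, z in enumerate(bands):
            collapsed += caipi_phase[None, :, b, None] * cal_k[z]
        # fit on zero-padded patches: identical geometry to the application
        # step, so k-space border behavior is part of the fit; border rows
        # (partly synthetic zeros) are down-weighted so the physical
        # interior dominates the solution
        padded = np.zeros((nxc + 2 * cx, nec + 2 * cy, nc), dtype=complex)
        padded[cx : cx + nxc, cy : cy + nec] = collapsed
        A = _patches(padded, kernel_size)
        if A.shape[0] < A.shape[1]:
            raise ReconError(
                "calibrate_slice_grappa: underdetermined fit -- "
                f"{A.shape[0]} patches for {A.shape[1]} unknowns"
            )
        interior = np.zeros((nxc, nec), dtype=bool)
        interior[cx : nxc - cx, cy : nec - cy] = True
        interior = interior.ravel()
        wrow = np.where(interior, 1.0, BORDER_WEIGHT)
        Aw = A * wrow[:, None]
        AtA = Aw.conj().T @ Aw
        AtA.flat[:: AtA.shape[0] + 1] += 1e-9 * np.trace(AtA).real / AtA.shape[0]
        gk: List[np.ndarray] = []
        gr: List[float] = []
        for b, z in enumerate(bands):
            target_full = caipi_phase[None, :, b, None] * cal_k[z]
            T = target_full.reshape(A.shape[0], -1)
            W = np.linalg.solve(AtA, Aw.conj().T @ (T * wrow[:, None]))
            pred = A @ W
            denom = np.linalg.norm(T[interior])
            gr.append(
                float(np.linalg.norm((pred - T)[interior]) / denom)
                if denom > 0 else 0.0
            )
            gk.append(W)
        kernels.append(gk)
        residuals.append(gr)
    return SliceGrappaKernels(
        kernel_size=kernel_size,
        kernels=kernels,
        residual=residuals,
        band_slices=np.asarray(band_slices),
        caipi_phase=np.asarray(caipi_phase),
    )


def apply_slice_grappa(
    sms_k: np.ndarray, kern: SliceGrappaKernels, group: int
) -> np.ndarray:
    """Separate collapsed k-space (nx, ne, nc) into per-band k-space
    (nbands, nx, ne, nc); the CAIPI phase is removed afterwards so each
    band sits in its own unshifted frame.  Border samples outside the
    valid convolution region are synthesized from zero-padded patches."""
    nx, ne, nc = sms_k.shape
    kx_k, ky_k = kern.kernel_size
    cx, cy = kx_k // 2, ky_k // 2
    padded = np.zeros((nx + 2 * cx, ne + 2 * cy, nc), dtype=complex)
    padded[cx : cx + nx, cy : cy + ne] = sms_k
    A = _patches(padded, kern.kernel_size)  # (nx*ne, taps)
    bands = kern.band_slices[group]
    out = np.zeros((len(bands), nx, ne, nc), dtype=complex)
    for b in range(len(bands)):
        W = kern.kernels[group][b]
        est = (A @ W).reshape(nx, ne, nc)
        out[b] = est / kern.caipi_phase[None, :, b, None]
    return out


# ---------------------------------------------------------------------------
# SENSE
# ---------------------------------------------------------------------------

def sense_unalias(
    coil_images: np.ndarray,
    maps: np.ndarray,
    band_slices: np.ndarray,
    shifts: np.ndarray,
    consts: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Image-domain SMS unaliasing for one shot group.

    coil_images: (nx, ny, nc) collapsed complex images; maps: coil
    sensitivities (nc, nx, ny, nz); band_slices: slice index per band;
    shifts: CAIPI in-plane shift (voxels along y) per band; consts: known
    per-band constant encoding phase.  Solves the (nc x nbands) system at
    every in-plane voxel by least squares.  Returns (band_images, gfactor)
    of shapes (nbands, nx, ny) and (nbands, nx, ny); rank-deficient voxels
    are zero-filled.
    """
    nx, ny, nc = coil_images.shape
    nb = len(band_slices)
    shifts_int = np.round(shifts).astype(int)
    if not np.allclose(shifts, shifts_int, atol=1e-9):
        raise ReconError(
            "sense_unalias: CAIPI band shifts must be integer voxel counts "
            "(matrix size divisible by caipi_shift)"
        )
    A = np.zeros((nx, ny, nc, nb), dtype=complex)
    for b, z in enumerate(band_slices):
        # the encoding ramp exp(+2 pi i ky s_b / ny) displaces band b by
        # -s_b voxels in the collapsed frame
        shifted = np.roll(maps[:, :, :, z], -shifts_int[b], axis=2)  # (nc,nx,ny)
        A[..., b] = consts[b] * np.moveaxis(shifted, 0, -1)
    Aflat = A.reshape(-1, nc, nb)
    y = coil_images.reshape(-1, nc)
    nv = Aflat.shape[0]
    out = np.zeros((nv, nb), dtype=complex)
    gfac = np.ones((nv, nb))
    # bands with zero sensitivity at a voxel contribute nothing there;
    # solve the reduced normal equations over the active bands only,
    # grouped by support pattern for vectorization
    colnorm = np.linalg.norm(Aflat, axis=1)
    active = colnorm > 1e-8 * max(colnorm.max(), 1e-300)
    patterns = active @ (1 << np.arange(nb))
    for pat in np.unique(patterns):
        if pat == 0:
            continue  # flagged voxel set: nothing resolvable, left zero
        cols = np.nonzero((pat >> np.arange(nb)) & 1)[0]
        vox = np.nonzero(patterns == pat)[0]
        Ar = Aflat[np.ix_(vox, np.arange(nc), cols)]
        AhA = np.einsum("vcb,vcd->vbd", Ar.conj(), Ar)
        Ahy = np.einsum("vcb,vc->vb", Ar.conj(), y[vox])
        # voxels where the reduced system is singular stay zero (flagged)
        dets_ok = np.abs(np.linalg.det(AhA)) > 1e-20
        good = vox[dets_ok]
        if good.size == 0:
            continue
        inv = np.linalg.inv(AhA[dets_ok])
        sol = np.einsum("vbd,vd->vb", inv, Ahy[dets_ok])
        out[np.ix_(good, cols)] = sol
        diag_inv = np.einsum("vbb->vb", inv).real
        diag_aha = np.einsum("vbb->vb", AhA[dets_ok]).real
        gfac[np.ix_(good, cols)] = np.sqrt(np.maximum(diag_inv * diag_aha, 1.0))
    u = out.reshape(nx, ny, nb)
    g = gfac.reshape(nx, ny, nb)
    band_images = np.zeros((nb, nx, ny), dtype=complex)
    gfactor = np.zeros((nb, nx, ny))
    for b in range(nb):
        band_images[b] = np.roll(u[:, :, b], shifts_int[b], axis=1)
        gfactor[b] = np.roll(g[:, :, b], shifts_int[b], axis=1)
    return band_images, gfactor


# ---------------------------------------------------------------------------
# partial Fourier, FFT, coil combination
# ---------------------------------------------------------------------------

def pf_zerofill(lines: np.ndarray, ky_index: np.ndarray, ny: int) -> np.ndarray:
    """Place acquired ky lines into the full grid, zero-filling the missing
    early lines (explicit zero-fill; no phase estimation).

    lines: (..., n_echoes, nc, nx) with echoes ordered as `ky_index`.
    Returns (..., ny, nc, nx).
    """
    ky_index = np.asarray(ky_index)
    out_shape = lines.shape[:-3] + (ny,) + lines.shape[-2:]
    out = np.zeros(out_shape, dtype=complex)
    cols = ky_index + ny // 2
    out[..., cols, :, :] = lines
    return out


def ifft2_centered(kspace: np.ndarray, axes: Tuple[int, int]) -> np.ndarray:
    """Unitary centered 2D inverse FFT (inverse of the simulator's
    encoding convention: ky/kx = 0 at index n//2, x/y = 0 at index n//2)."""
    shifted = np.fft.ifftshift(kspace, axes=axes)
    img = np.fft.ifftn(shifted, axes=axes, norm="ortho")
    return np.fft.fftshift(img, axes=axes)


def coil_combine_rss(coil_images: np.ndarray, axis: int = -1) -> np.ndarray:
    """Root-sum-of-squares combination over the coil axis (nonnegative)."""
    return np.sqrt((np.abs(coil_images) ** 2).sum(axis=axis))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass
class ImageTimeSeries:
    """4D magnitude time series with voxel geometry."""

    data: np.ndarray  # (nx, ny, nz, nt)
    voxel_size: Tuple[float, float, float]  # m
    tr: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("ImageTimeSeries: data must be 4D")
        if np.any(self.data < 0):
            raise ValueError("ImageTimeSeries: magnitude data must be nonnegative")

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        vx, vy, vz = (v * 1e3 for v in self.voxel_size)  # mm
        affine = np.diag([vx, vy, vz, 1.0])
        affine[:3, 3] = -np.array(
            [vx * self.data.shape[0] / 2, vy * self.data.shape[1] / 2,
             vz * self.data.shape[2] / 2]
        )
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((vx, vy, vz, self.tr))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path)

    @staticmethod
    def from_nifti(path: str) -> "ImageTimeSeries":
        import nibabel as nib

        img = nib.load(path)
        zooms = img.header.get_zooms()
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        return ImageTimeSeries(
            data=np.abs(data),
            voxel_size=tuple(z * 1e-3 for z in zooms[:3]),
            tr=float(zooms[3]) if len(zooms) > 3 else 1.0,
        )


def _grid_calibration(
    cal: RawKSpace, pc: PhaseCorrection, rg: RampRegridder
) -> np.ndarray:
    """Calibration -> per-slice Cartesian k-space (n_slices, nx, ne, nc)."""
    data = apply_phase_correction(cal.data[0], cal.polarity, pc)
    gridded = rg.apply(data, cal.polarity)  # (nslices, ne, nc, nx)
    return np.moveaxis(gridded, -1, 1)  # (nslices, nx, ne, nc)


def coil_maps_from_calibration(
    cal_k: np.ndarray, ky_index: np.ndarray, ny: int, rel_thresh: float = 0.1
) -> np.ndarray:
    """Direct ratio-to-RSS coil maps from single-band calibration images.

    Returns (nc, nx, ny, nz) complex maps, zero outside the support mask.
    """
    nz, nx, ne, nc = cal_k.shape
    # pf_zerofill expects (..., ne, nc, nx)
    k = np.moveaxis(cal_k, 1, -1)  # (nz, ne, nc, nx)
    kfull = pf_zerofill(k, ky_index, ny)  # (nz, ny, nc, nx)
    imgs = ifft2_centered(kfull, axes=(-1, -3))  # x and ky axes
    imgs = np.moveaxis(imgs, -1, 1)  # (nz, nx, ny, nc)
    rss = coil_combine_rss(imgs, axis=-1)
    mask = rss > rel_thresh * rss.max()
    maps = np.zeros((nc, nx, ny, nz), dtype=complex)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = imgs / rss[..., None]
    ratio[~mask] = 0.0
    maps = np.moveaxis(ratio, (0, 3), (3, 0))  # (nc, nx, ny, nz)
    return maps


def reconstruct_timeseries(
    raw: RawKSpace,
    calibration: Optional[RawKSpace],
    method: str = "slice_grappa",
    maps: Optional[np.ndarray] = None,
    kernel_size: Tuple[int, int] = (7, 7),
    phase_correction: Optional[PhaseCorrection] = None,
) -> ImageTimeSeries:
    """Run the full chain on a RawKSpace container.

    `calibration` (single-band reference) is required for slice GRAPPA and
    is also the default source of SENSE coil maps; `maps` can override.
    """
    method = method.lower()
    if method not in ("slice_grappa", "sense"):
        raise ValueError(f"reconstruct_timeseries: unknown method {method!r}")
    if method == "slice_grappa" and calibration is None:
        raise ReconError(
            "reconstruct_timeseries: slice_grappa requires single-band "
            "calibration data"
        )
    if method == "sense" and calibration is None and maps is None:
        raise ReconError(
            "reconstruct_timeseries: sense requires coil maps or single-band "
            "calibration data to derive them"
        )
    nx, ny = raw.matrix
    nz = raw.n_slices
    fov_x = raw.fov[0]
    rg = RampRegridder(raw.kx, nx, fov_x)
    if phase_correction is not None:
        pc = phase_correction
    else:
        source = calibration if calibration is not None else raw
        pc = estimate_phase_correction(source)

    # reconstruct a pseudo protocol-param view for CAIPI bookkeeping
    nbands = raw.band_slices.shape[1]
    shifts = _shifts_from_phase(raw.caipi_phase, ny)
    consts = _consts_from_phase(raw.caipi_phase, raw.ky_index, shifts, ny)

    cal_k = None
    kern = None
    if calibration is not None:
        cal_k = _grid_calibration(calibration, pc, rg)
    if method == "slice_grappa":
        kern = calibrate_slice_grappa(
            cal_k, raw.band_slices, raw.caipi_phase, kernel_size
        )
    if method == "sense" and maps is None:
        maps = coil_maps_from_calibration(cal_k, raw.ky_index, ny)

    nvol_total, nshots = raw.data.shape[:2]
    nt = nvol_total - raw.n_dummy
    out = np.zeros((nx, ny, nz, nt), dtype=float)
    for v in range(raw.n_dummy, nvol_total):
        vol = np.zeros((nx, ny, nz))
        for s in range(nshots):
            data = apply_phase_correction(raw.data[v, s], raw.polarity, pc)
            gridded = rg.apply(data, raw.polarity)  # (ne, nc, nx)
            if method == "slice_grappa":
                sms_k = np.moveaxis(gridded, -1, 0)  # (nx, ne, nc)
                bands_k = apply_slice_grappa(sms_k, kern, s)
                bk = np.moveaxis(bands_k, 1, -1)  # (nb, ne, nc, nx)
                kfull = pf_zerofill(bk, raw.ky_index, ny)  # (nb, ny, nc, nx)
                imgs = ifft2_centered(kfull, axes=(-1, -3))
                slice_imgs = coil_combine_rss(
                    np.moveaxis(imgs, -1, 1), axis=-1
                )  # (nb, nx, ny)
            else:
                kfull = pf_zerofill(gridded, raw.ky_index, ny)  # (ny, nc, nx)
                coil_imgs = np.moveaxis(ifft2_centered(kfull, axes=(-1, -3)), -1, 0)
                # now (nx, ny, nc)
                band_imgs, _g = sense_unalias(
                    coil_imgs, maps, raw.band_slices[s], shifts, consts
                )
                slice_imgs = np.abs(band_imgs)
            for b, z in enumerate(raw.band_slices[s]):
                vol[:, :, z] = slice_imgs[b]
        out[..., v - raw.n_dummy] = vol
    voxel = (raw.fov[0] / nx, raw.fov[1] / ny, raw.fov[2] / nz)
    return ImageTimeSeries(out, voxel, raw.tr)


def _shifts_from_phase(caipi_phase: np.ndarray, ny: int) -> np.ndarray:
    """Recover per-band in-plane shifts (voxels) from the encoding table."""
    ne, nb = caipi_phase.shape
    if nb == 1 or ne < 2:
        return np.zeros(nb)
    # the table is exp(2 pi i b cyc_e / S); successive distinct phases give
    # the slope per ky line for band 1
    shifts = np.zeros(nb)
    dphi = np.angle(caipi_phase[1, 1] / caipi_phase[0, 1]) / (2 * np.pi)
    # dphi = d(cyc)/S per line; within a cycle cyc steps by +1
    S = round(1.0 / dphi) if dphi != 0 else 1
    for b in range(nb):
        shifts[b] = b * ny / S if S > 1 else 0.0
    return shifts


def _consts_from_phase(
    caipi_phase: np.ndarray, ky_index: np.ndarray, shifts: np.ndarray, ny: int
) -> np.ndarray:
    """Per-band constant phase after absorbing the pure ky ramp."""
    ne, nb = caipi_phase.shape
    consts = np.zeros(nb, dtype=complex)
    for b in range(nb):
        if shifts[b] == 0:
            consts[b] = caipi_phase[0, b]
        else:
            ramp0 = np.exp(2j * np.pi * shifts[b] * ky_index[0] / ny)
            consts[b] = caipi_phase[0, b] / ramp0
    return consts
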