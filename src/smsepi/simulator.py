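"""Synthetic-data generation: digital phantoms, coil maps, and forward
simulation of the SMS-EPI acquisition.

The forward model is a discrete-voxel DFT evaluated at the exact ADC
sample positions of the designed readout (including ramp samples):

    s(shot, e, c, k) = sum_b phi(e, b) sum_r rho(r, z_b) S_c(r, z_b)
                       exp(-2 pi i k(e, k) . r) + noise

with phi(e, b) the CAIPI encoding phase of band b at echo e.  Within an
echo ky is constant and lies on the Cartesian grid, so the y/x sums factor
into an FFT along y and a small dense DFT along x at the (possibly
nonuniform) kx sample positions.  This makes the noiseless reconstruction
oracle exact: inverting the same discrete model recovers the phantom to
numerical precision in the degenerate single-band, full-Fourier case.

Odd/even echo inconsistency is modeled as a constant + linear phase applied
to negative-polarity echoes in acquisition sample order; slow scanner
drift as a per-volume multiplicative scale; thermal noise as i.i.d.
complex Gaussian per coil, all seeded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import h5py
import numpy as np

from .protocol import (
    EPIReadout,
    ProtocolParams,
    caipi_phase_table,
    design_epi_readout,
)
from .events import SystemLimits


@dataclass
class DigitalPhantom:
    """3D intensity grid matching the protocol geometry."""

    data: np.ndarray  # (nx, ny, nz), nonnegative
    voxel_size: Tuple[float, float, float]  # m

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("DigitalPhantom: data must be 3D")
        if np.any(self.data < 0):
            raise ValueError("DigitalPhantom: intensities must be nonnegative")


@dataclass
class CoilMaps:
    """Complex coil sensitivities, unit root-sum-of-squares inside the mask."""

    maps: np.ndarray  # (ncoils, nx, ny, nz)
    mask: np.ndarray  # (nx, ny, nz) bool

    @property
    def ncoils(self) -> int:
        return self.maps.shape[0]


@dataclass
class AcqNoiseModel:
    """Acquisition imperfections; `seed` fixes all randomness."""

    sigma: float = 0.0  # complex Gaussian SD per coil, k-space units
    theta0: float = 0.0  # rad, constant odd-echo phase error
    theta1: float = 0.0  # rad per kx sample, linear odd-echo phase error
    drift: float = 0.0  # total multiplicative drift over the run (fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("AcqNoiseModel: sigma must be >= 0")


@dataclass
class RawKSpace:
    """Multi-coil k-space container.

    data: (n_volumes, n_shots, n_echoes, n_coils, n_samples)
    nav:  (n_volumes, n_shots, n_nav, n_coils, n_samples)
    """

    data: np.ndarray
    nav: np.ndarray
    ky_index: np.ndarray  # (n_echoes,)
    polarity: np.ndarray  # (n_echoes,) +-1, gradient sign during the echo
    nav_polarity: np.ndarray  # (n_nav,)
    band_slices: np.ndarray  # (n_shots, n_bands) slice index per band
    caipi_phase: np.ndarray  # (n_echoes, n_bands)
    kx: np.ndarray  # (n_samples,) kx at samples of a +polarity echo, 1/m
    dwell: float
    fov: Tuple[float, float, float]
    matrix: Tuple[int, int]
    n_slices: int
    tr: float
    n_dummy: int = 0

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# phantom and coil maps
# ---------------------------------------------------------------------------

def make_ball_phantom(
    p: ProtocolParams, radius: Optional[float] = None, intensity: float = 100.0
) -> DigitalPhantom:
    """Uniform ball phantom (the digital stand-in for an fBIRN/EZfMRI
    gel ball) with an anti-aliased boundary.

    Default radius is 40% of the in-plane FOV, matching the proportions of
    a 17 cm QA ball in a 21.6 cm FOV.  The ball may extend beyond the
    excited slab along z (slices are selectively excited, so there is no
    aliasing along the slice axis), but must fit the in-plane FOV.
    """
    if radius is None:
        radius = 0.4 * min(p.fov[0], p.fov[1])
    if radius >= min(p.fov[0], p.fov[1]) / 2:
        raise ValueError("make_ball_phantom: radius must be < min in-plane fov/2")
    nx, ny = p.matrix
    nz = p.n_slices
    vx, vy, vz = p.fov[0] / nx, p.fov[1] / ny, p.slice_thickness
    if radius <= 0:
        return DigitalPhantom(np.zeros((nx, ny, nz)), (vx, vy, vz))
    x = (np.arange(nx) - nx / 2) * vx
    y = (np.arange(ny) - ny / 2) * vy
    z = (np.arange(nz) - (nz - 1) / 2) * vz
    r = np.sqrt(
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    )
    # anti-aliased edge over one in-plane voxel
    edge = max(vx, vy)
    data = intensity * np.clip((radius - r) / edge + 0.5, 0.0, 1.0)
    return DigitalPhantom(data, (vx, vy, vz))


def make_coil_maps(
    p: ProtocolParams,
    ncoils: int,
    seed: int = 0,
    phantom: Optional[DigitalPhantom] = None,
) -> CoilMaps:
    """Smooth synthetic coil sensitivities: one Gaussian lobe per coil on a
    ring around the object, with a random low-order polynomial phase,
    normalized to unit root-sum-of-squares inside the object mask."""
    if ncoils < 1:
        raise ValueError("make_coil_maps: ncoils must be >= 1")
    rng = np.random.default_rng(seed)
    nx, ny = p.matrix
    nz = p.n_slices
    x = np.linspace(-1, 1, nx)
    y = np.linspace(-1, 1, ny)
    z = np.linspace(-1, 1, nz) if nz > 1 else np.zeros(1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    maps = np.zeros((ncoils, nx, ny, nz), dtype=complex)
    for c in range(ncoils):
        ang = 2 * np.pi * c / ncoils + rng.uniform(-0.2, 0.2)
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        cz = rng.uniform(-0.5, 0.5)
        width = 1.1 + rng.uniform(-0.1, 0.1)
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2 + 0.3 * (Z - cz) ** 2) / width**2)
        a, b, cc = rng.uniform(-1.5, 1.5, 3)
        phase = a * X + b * Y + cc * Z + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    if phantom is not None:
        mask = phantom.data > 0.05 * phantom.data.max()
    else:
        mask = np.ones((nx, ny, nz), dtype=bool)
    if ncoils == 1:
        maps = np.ones_like(maps)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    rss[rss == 0] = 1.0
    maps = maps / rss[None]
    return CoilMaps(maps, mask)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _encoding_matrices(
    p: ProtocolParams, readout: EPIReadout
) -> Tuple[np.ndarray, np.ndarray]:
    """Dense DFT matrices (nsamp, nx) for +/- polarity echoes."""
    nx = p.matrix[0]
    vx = p.fov[0] / nx
    xpos = (np.arange(nx) - nx / 2) * vx
    kx = readout.kx_of_sample
    scale = 1.0 / np.sqrt(nx)
    Epos = np.exp(-2j * np.pi * np.outer(kx, xpos)) * scale
    Eneg = np.exp(-2j * np.pi * np.outer(-kx, xpos)) * scale
    return Epos, Eneg


def _hybrid_kspace(slab: np.ndarray, axis: int) -> np.ndarray:
    """Centered DFT along `axis`: H[m] = sum_j a_j exp(-2 pi i m (j - n/2)/n)
    with the output indexed by m + n/2 (ky = 0 at the center column)."""
    shifted = np.fft.fft(np.fft.ifftshift(slab, axes=axis), axis=axis, norm="ortho")
    return np.fft.fftshift(shifted, axes=axis)


def simulate_acquisition(
    phantom: DigitalPhantom,
    maps: CoilMaps,
    p: ProtocolParams,
    readout: Optional[EPIReadout] = None,
    noise: Optional[AcqNoiseModel] = None,
    limits: Optional[SystemLimits] = None,
) -> Tuple[RawKSpace, RawKSpace]:
    """Forward-simulate the SMS time series and the single-band reference.

    Returns ``(sms_raw, calibration_raw)``.  The calibration container has
    one "volume", one shot per slice, one band per shot, unit CAIPI
    phases, and no drift; it shares the noise model's sigma and odd-echo
    phase errors (they are properties of the receive chain, not of the
    multiband encoding).
    """
    noise = noise or AcqNoiseModel()
    limits = limits or SystemLimits()
    if readout is None:
        readout = design_epi_readout(p, limits)
    nx, ny = p.matrix
    nz = p.n_slices
    if phantom.data.shape != (nx, ny, nz):
        raise ValueError(
            f"simulate_acquisition: phantom shape {phantom.data.shape} does not "
            f"match protocol geometry {(nx, ny, nz)}"
        )
    if maps.maps.shape[1:] != (nx, ny, nz):
        raise ValueError("simulate_acquisition: coil map geometry mismatch")
    nc = maps.ncoils
    ne = p.n_echoes
    nsamp = readout.adc.num_samples
    nnav = p.n_navigators
    nshots = p.n_shots_per_volume
    nvol_total = p.n_dummy + p.n_volumes
    kyi = p.ky_indices()
    phase_tab = caipi_phase_table(p)

    Epos, Eneg = _encoding_matrices(p, readout)
    # per-slice hybrid signal at every (sample, ky, coil) for both polarities
    weighted = phantom.data[None] * maps.maps  # (nc, nx, ny, nz)
    ky_cols = kyi + ny // 2  # indices into the fftshifted ky axis

    pos_lines = np.zeros((nz, ne, nc, nsamp), dtype=complex)
    neg_lines = np.zeros((nz, ne, nc, nsamp), dtype=complex)
    nav_pos = np.zeros((nz, nc, nsamp), dtype=complex)
    nav_neg = np.zeros((nz, nc, nsamp), dtype=complex)
    zero_col = ny // 2
    for z in range(nz):
        hyb = _hybrid_kspace(weighted[:, :, :, z], axis=2)  # (nc, nx, ny)
        sel = hyb[:, :, ky_cols]  # (nc, nx, ne)
        pos_lines[z] = np.einsum("sx,cxe->ecs", Epos, sel)
        neg_lines[z] = np.einsum("sx,cxe->ecs", Eneg, sel)
        nav_pos[z] = (Epos @ hyb[:, :, zero_col].T).T
        nav_neg[z] = (Eneg @ hyb[:, :, zero_col].T).T

    # echo polarity bookkeeping: navigators alternate starting +, the EPI
    # train starts with the polarity following the last navigator
    nav_polarity = np.array([1 if i % 2 == 0 else -1 for i in range(nnav)])
    start = 1 if nnav % 2 == 0 else -1
    polarity = np.array([start * (1 if e % 2 == 0 else -1) for e in range(ne)])

    # odd-echo (negative-polarity) phase error in acquisition sample order
    n_idx = np.arange(nsamp)
    err = np.exp(1j * (noise.theta0 + noise.theta1 * n_idx))

    def assemble(band_slices: np.ndarray, use_caipi: bool) -> Tuple[np.ndarray, np.ndarray]:
        """(ne, nc, nsamp) echo data + (nnav, nc, nsamp) navs for one shot."""
        echoes = np.zeros((ne, nc, nsamp), dtype=complex)
        navs = np.zeros((nnav, nc, nsamp), dtype=complex)
        for b, z in enumerate(band_slices):
            ph = phase_tab[:, b] if use_caipi else np.ones(ne)
            lines = np.where(
                (polarity == 1)[:, None, None], pos_lines[z], neg_lines[z]
            )
            echoes += ph[:, None, None] * lines
            navs += np.where(
                (nav_polarity == 1)[:, None, None],
                nav_pos[z][None],
                nav_neg[z][None],
            )
        echoes = np.where((polarity == -1)[:, None, None], echoes * err, echoes)
        navs = np.where((nav_polarity == -1)[:, None, None], navs * err, navs)
        return echoes, navs

    rng = np.random.default_rng(noise.seed)

    def noisy(shape):
        if noise.sigma == 0:
            return 0.0
        return noise.sigma * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        ) / np.sqrt(2)

    # SMS time series
    sms_data = np.zeros((nvol_total, nshots, ne, nc, nsamp), dtype=complex)
    sms_nav = np.zeros((nvol_total, nshots, nnav, nc, nsamp), dtype=complex)
    band_table = np.stack([p.slices_of_shot(s) for s in range(nshots)])
    shot_signal = {}
    for s in range(nshots):
        shot_signal[s] = assemble(band_table[s], use_caipi=True)
    for v in range(nvol_total):
        scale = 1.0 + noise.drift * (v / max(nvol_total - 1, 1))
        for s in range(nshots):
            e_sig, n_sig = shot_signal[s]
            sms_data[v, s] = scale * e_sig + noisy((ne, nc, nsamp))
            sms_nav[v, s] = scale * n_sig + noisy((nnav, nc, nsamp))
    sms = RawKSpace(
        data=sms_data,
        nav=sms_nav,
        ky_index=kyi,
        polarity=polarity,
        nav_polarity=nav_polarity,
        band_slices=band_table,
        caipi_phase=phase_tab,
        kx=readout.kx_of_sample,
        dwell=readout.adc.dwell,
        fov=tuple(p.fov),
        matrix=tuple(p.matrix),
        n_slices=nz,
        tr=p.tr,
        n_dummy=p.n_dummy,
    )

    # single-band calibration: one shot per slice, no CAIPI, no drift
    cal_data = np.zeros((1, nz, ne, nc, nsamp), dtype=complex)
    cal_nav = np.zeros((1, nz, nnav, nc, nsamp), dtype=complex)
    for z in range(nz):
        e_sig, n_sig = assemble(np.array([z]), use_caipi=False)
        cal_data[0, z] = e_sig + noisy((ne, nc, nsamp))
        cal_nav[0, z] = n_sig + noisy((nnav, nc, nsamp))
    cal = RawKSpace(
        data=cal_data,
        nav=cal_nav,
        ky_index=kyi,
        polarity=polarity,
        nav_polarity=nav_polarity,
        band_slices=np.arange(nz)[:, None],
        caipi_phase=np.ones((ne, 1), dtype=complex),
        kx=readout.kx_of_sample,
        dwell=readout.adc.dwell,
        fov=tuple(p.fov),
        matrix=tuple(p.matrix),
        n_slices=nz,
        tr=p.tr,
        n_dummy=0,
    )
    return sms, cal


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def save_raw(raw: RawKSpace, path: str) -> None:
    """Write a RawKSpace container to HDF5 (data + per-readout headers)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data.astype(np.complex64))
        f.create_dataset("nav", data=raw.nav.astype(np.complex64))
        for name in ("ky_index", "polarity", "nav_polarity", "band_slices", "kx"):
            f.create_dataset(name, data=getattr(raw, name))
        f.create_dataset("caipi_phase", data=raw.caipi_phase.astype(np.complex128))
        f.attrs["dwell"] = raw.dwell
        f.attrs["fov"] = raw.fov
        f.attrs["matrix"] = raw.matrix
        f.attrs["n_slices"] = raw.n_slices
        f.attrs["tr"] = raw.tr
        f.attrs["n_dummy"] = raw.n_dummy


def load_raw(path: str) -> RawKSpace:
    with h5py.File(path, "r") as f:
        return RawKSpace(
            data=f["data"][()].astype(complex),
            nav=f["nav"][()].astype(complex),
            ky_index=f["ky_index"][()],
            polarity=f["polarity"][()],
            nav_polarity=f["nav_polarity"][()],
            band_slices=f["band_slices"][()],
            caipi_phase=f["caipi_phase"][()],
            kx=f["kx"][()],
            dwell=float(f.attrs["dwell"]),
            fov=tuple(f.attrs["fov"]),
            matrix=tuple(int(v) for v in f.attrs["matrix"]),
            n_slices=int(f.attrs["n_slices"]),
            tr=float(f.attrs["tr"]),
            n_dummy=int(f.attrs["n_dummy"]),
        )
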