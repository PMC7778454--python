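"""Analytic forward models for the spherical phantom.

EEG: scalp potentials of a current dipole inside a four-shell concentric
sphere, computed by a truncated Legendre series.  For each harmonic order n
the radial boundary-value problem across the shells is solved exactly
(continuity of potential and radial current at each interface, vanishing
normal current at the scalp), so the only approximation is the series
truncation.

DOT: continuous-wave Rytov sensitivity from diffusion-approximation Green's
functions of a semi-infinite homogeneous medium tangent to the optode patch.
Per-voxel sensitivity is G(rs, r) G(r, rd) / G(rs, rd) scaled by a nominal
voxel volume; chromophore columns are scaled by hemoglobin extinction
coefficients per wavelength, so the Jacobian maps [dHbO; dHb] directly to
optical-density changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .phantom import (
    ElectrodeArray,
    GeometryError,
    HeadModel,
    OptodeArray,
    SourceSpace,
)

__all__ = [
    "EEGLeadfield",
    "DOTJacobian",
    "PhysicsError",
    "compute_eeg_leadfield",
    "compute_dot_jacobian",
    "multishell_dipole_potential",
    "shell_series_coefficients",
    "load_extinction_coefficients",
    "semi_infinite_green",
]


class PhysicsError(ValueError):
    """Raised for physically invalid optical/electrical parameters."""


@dataclass(frozen=True)
class EEGLeadfield:
    """E x V gain matrix for unit radial dipoles, average-referenced."""

    matrix: np.ndarray
    n_terms: int
    truncation_tol: float  # magnitude ratio of last to largest series term

    @property
    def shape(self):
        return self.matrix.shape


@dataclass(frozen=True)
class DOTJacobian:
    """(C*W) x (2V) sensitivity matrix mapping [dHbO; dHb] to dOD.

    Rows are wavelength-major: all channels at the first wavelength, then
    all channels at the second.  Columns are chromophore-major: HbO for all
    voxels, then Hb.
    """

    matrix: np.ndarray
    wavelengths: tuple
    n_channels: int
    extinction_coeffs: dict  # {wavelength: {"HbO": e, "Hb": e}}

    @property
    def shape(self):
        return self.matrix.shape

    def wavelength_block(self, wl) -> np.ndarray:
        i = self.wavelengths.index(wl)
        C = self.n_channels
        return self.matrix[i * C : (i + 1) * C]


# ---------------------------------------------------------------------------
# EEG: four-shell sphere Legendre series
# ---------------------------------------------------------------------------


def shell_series_coefficients(head: HeadModel, n_terms: int) -> np.ndarray:
    """Per-order surface coefficients F_n of the multishell radial problem.

    With radii normalised by the scalp radius, the potential in the source
    shell is r^-(n+1) + A1 r^n (unit source coefficient) and A_k r^n +
    B_k r^-(n+1) in the outer shells.  F_n is the radial factor of the
    potential evaluated at the scalp surface.  In the homogeneous limit
    F_n = (2n+1)/n.
    """
    radii = np.asarray(head.shell_radii, float) / head.scalp_radius
    sig = np.asarray(head.conductivities, float)
    L = len(radii)
    out = np.empty(n_terms)
    for idx, n in enumerate(range(1, n_terms + 1)):
        # unknowns: A1, A2, B2, ..., A_L, B_L  -> 2L-1
        m = 2 * L - 1
        M = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_A(k):  # shell k (0-based), coefficient of r^n
            return 0 if k == 0 else 2 * k - 1

        def col_B(k):  # shell k>0, coefficient of r^-(n+1)
            return 2 * k

        row = 0
        for k in range(L - 1):  # interface between shell k and k+1
            R = radii[k]
            # potential continuity
            M[row, col_A(k)] = R**n
            if k > 0:
                M[row, col_B(k)] = R ** -(n + 1)
            M[row, col_A(k + 1)] = -(R**n)
            M[row, col_B(k + 1)] = -(R ** -(n + 1))
            rhs[row] = 0.0 if k > 0 else -(R ** -(n + 1))
            row += 1
            # radial current continuity
            M[row, col_A(k)] = sig[k] * n * R ** (n - 1)
            if k > 0:
                M[row, col_B(k)] = -sig[k] * (n + 1) * R ** -(n + 2)
            M[row, col_A(k + 1)] = -sig[k + 1] * n * R ** (n - 1)
            M[row, col_B(k + 1)] = sig[k + 1] * (n + 1) * R ** -(n + 2)
            rhs[row] = sig[k] * (n + 1) * R ** -(n + 2) if k == 0 else 0.0
            row += 1
        # outer boundary: zero normal current at scalp (radius 1)
        M[row, col_A(L - 1)] = n
        M[row, col_B(L - 1)] = -(n + 1)
        coef = np.linalg.solve(M, rhs)
        out[idx] = coef[col_A(L - 1)] + coef[col_B(L - 1)]
    return out


def multishell_dipole_potential(
    head: HeadModel,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_pos: np.ndarray,
    n_terms: int = 60,
    average_reference: bool = False,
) -> np.ndarray:
    """Scalp potential of an arbitrary dipole inside the innermost shell.

    ``dipole_pos`` in mm (strictly inside the brain shell), ``dipole_moment``
    an arbitrary 3-vector, ``electrode_pos`` (E, 3) on the scalp surface.
    """
    p0 = np.asarray(dipole_pos, float)
    m = np.asarray(dipole_moment, float)
    elec = np.atleast_2d(np.asarray(electrode_pos, float))
    b = np.linalg.norm(p0)
    R = head.scalp_radius
    if b >= head.shell_radii[0]:
        raise GeometryError("dipole must lie strictly inside the brain shell")

    F = shell_series_coefficients(head, n_terms)
    f = b / R
    if b < 1e-12:
        rhat = np.array([0.0, 0.0, 1.0])
    else:
        rhat = p0 / b
    ehat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    cosg = np.clip(ehat @ rhat, -1.0, 1.0)
    # tangential unit vector in the dipole-electrode plane
    t = ehat - cosg[:, None] * rhat
    tn = np.linalg.norm(t, axis=1)
    that = np.where(tn[:, None] > 1e-12, t / np.maximum(tn, 1e-300)[:, None], 0.0)
    m_r = float(m @ rhat)
    m_t = that @ m

    # Legendre recurrences for P_n(c) and P_n^1(c) (no Condon-Shortley)
    V = np.zeros(elec.shape[0])
    sig1 = head.conductivities[0]
    c = cosg
    s = np.sqrt(np.maximum(0.0, 1.0 - c * c))
    Pnm1, Pn = np.ones_like(c), c.copy()          # P_0, P_1
    P1nm1, P1n = np.zeros_like(c), s.copy()       # P_0^1, P_1^1
    scale = 1.0 / (4.0 * np.pi * sig1 * R**2)
    for i, n in enumerate(range(1, n_terms + 1)):
        term = f ** (n - 1) * F[i] * (n * m_r * Pn + m_t * P1n)
        V += term
        # advance recurrences to order n+1
        Pnp1 = ((2 * n + 1) * c * Pn - n * Pnm1) / (n + 1)
        P1np1 = ((2 * n + 1) * c * P1n - (n + 1) * P1nm1) / n
        Pnm1, Pn = Pn, Pnp1
        P1nm1, P1n = P1n, P1np1
    V *= scale
    if average_reference:
        V = V - V.mean()
    return V


def compute_eeg_leadfield(
    head: HeadModel,
    electrodes: ElectrodeArray,
    sources: SourceSpace,
    n_terms: int = 60,
) -> EEGLeadfield:
    """Leadfield for unit radial (normal-constrained) dipoles.

    Each column is the average-referenced scalp potential pattern of a unit
    dipole along the cortical-surface normal.  All sources share the
    cortical radius, so the series reduces to a single P_n accumulation
    over electrode-source angle cosines.
    """
    pos = sources.positions
    b = np.linalg.norm(pos, axis=1)
    # the cortical shell sits exactly at the brain radius; allow equality
    if np.any(b > head.shell_radii[0] + 1e-9):
        raise GeometryError("all sources must lie on or inside the brain shell")
    R = head.scalp_radius
    sig1 = head.conductivities[0]
    F = shell_series_coefficients(head, n_terms)

    ehat = electrodes.positions / np.linalg.norm(
        electrodes.positions, axis=1, keepdims=True
    )
    shat = pos / b[:, None]
    c = np.clip(ehat @ shat.T, -1.0, 1.0)  # (E, V)
    f = (b / R)[None, :]

    G = np.zeros_like(c)
    Pnm1, Pn = np.ones_like(c), c.copy()
    fpow = np.ones_like(f)  # f^(n-1)
    last_mag = 0.0
    max_mag = 0.0
    for i, n in enumerate(range(1, n_terms + 1)):
        term = fpow * F[i] * n * Pn
        G += term
        last_mag = float(np.max(np.abs(term)))
        max_mag = max(max_mag, last_mag)
        Pnp1 = ((2 * n + 1) * c * Pn - n * Pnm1) / (n + 1)
        Pnm1, Pn = Pn, Pnp1
        fpow = fpow * f
    G *= 1.0 / (4.0 * np.pi * sig1 * R**2)
    G = G - G.mean(axis=0, keepdims=True)  # average reference
    tol = last_mag / max_mag if max_mag > 0 else 0.0
    return EEGLeadfield(matrix=G, n_terms=n_terms, truncation_tol=tol)


# ---------------------------------------------------------------------------
# DOT: semi-infinite diffusion Green's functions
# ---------------------------------------------------------------------------


def load_extinction_coefficients() -> dict:
    """Hemoglobin extinction coefficients from the packaged data table.

    Returns {wavelength_nm: {"HbO": eps, "Hb": eps}} in cm^-1 / (mol/L),
    decadic.
    """
    with resources.files("eegdot.data").joinpath("hemoglobin_extinction.yaml").open() as fh:
        table = yaml.safe_load(fh)
    return {float(wl): dict(v) for wl, v in table["extinction"].items()}


def semi_infinite_green(pts_a: np.ndarray, pts_b: np.ndarray, mua: float, musp: float) -> np.ndarray:
    """CW diffusion Green's function between interior points of a
    semi-infinite medium occupying depth > 0.

    Points are (N, 3) local patch coordinates (u, v, depth).  An
    extrapolated zero boundary at depth -zb (zb = 2D) is enforced with an
    image across that plane; the resulting kernel is exactly symmetric in
    its two arguments (reciprocity).
    """
    if musp <= 0:
        raise PhysicsError("reduced scattering coefficient must be positive")
    if mua <= 0:
        raise PhysicsError("absorption coefficient must be positive")
    D = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(mua / D)
    zb = 2.0 * D
    a = np.atleast_2d(pts_a)
    bpts = np.atleast_2d(pts_b)
    diff = a[:, None, :] - bpts[None, :, :]
    r1 = np.sqrt((diff[..., 0] ** 2) + (diff[..., 1] ** 2) + (diff[..., 2] ** 2))
    zsum = a[:, None, 2] + bpts[None, :, 2] + 2.0 * zb
    r2 = np.sqrt((diff[..., 0] ** 2) + (diff[..., 1] ** 2) + zsum**2)
    r1 = np.maximum(r1, 1e-9)
    r2 = np.maximum(r2, 1e-9)
    return (np.exp(-mueff * r1) / r1 - np.exp(-mueff * r2) / r2) / (4.0 * np.pi * D)


def compute_dot_jacobian(
    head: HeadModel,
    optodes: OptodeArray,
    sources: SourceSpace,
    extinction=None,
    voxel_thickness: float = 4.0,
) -> DOTJacobian:
    """Rytov sensitivity of each channel to [dHbO; dHb] at each voxel.

    The scalp patch is flattened: every point keeps its azimuthal-
    equidistant tangent coordinates and its radial depth below the scalp
    sphere, and the medium below the patch is treated as semi-infinite and
    homogeneous.  Both optode terminals are modelled as isotropic points at
    depth 1/musp', which makes source-detector reciprocity exact.
    """
    extinction = extinction or load_extinction_coefficients()
    R = head.scalp_radius
    frame = optodes.frame
    src_loc = frame.local_coords(optodes.source_positions, R)
    det_loc = frame.local_coords(optodes.detector_positions, R)
    vox_loc = frame.local_coords(sources.positions, R)
    if np.max(np.abs(src_loc[:, 2])) > 1.0 or np.max(np.abs(det_loc[:, 2])) > 1.0:
        raise GeometryError("optodes must lie on the scalp surface")

    V = sources.n_voxels
    voxel_volume = (4.0 * np.pi * head.cortex_radius**2 / V) * voxel_thickness
    si = np.array([c[0] for c in optodes.channels])
    di = np.array([c[1] for c in optodes.channels])

    wavelengths = head.wavelengths
    blocks = []
    for wl in wavelengths:
        props = head.optical_props[wl]
        mua, musp = props["mua"], props["musp"]
        z0 = 1.0 / musp
        spts = src_loc.copy()
        spts[:, 2] = z0
        dpts = det_loc.copy()
        dpts[:, 2] = z0
        Gsv = semi_infinite_green(spts, vox_loc, mua, musp)  # (S, V)
        Gvd = semi_infinite_green(vox_loc, dpts, mua, musp)  # (V, D)
        Gsd = semi_infinite_green(spts, dpts, mua, musp)     # (S, D)
        # channel-wise absorption sensitivity, units mm (path-length like)
        J_abs = (Gsv[si, :] * Gvd[:, di].T) / Gsd[si, di][:, None] * voxel_volume
        try:
            eps = extinction[float(wl)]
        except KeyError as err:
            raise PhysicsError(f"no extinction coefficients for {wl} nm") from err
        # decadic OD change per unit concentration change
        blocks.append(np.hstack([J_abs * eps["HbO"], J_abs * eps["Hb"]]))
    return DOTJacobian(
        matrix=np.vstack(blocks),
        wavelengths=tuple(wavelengths),
        n_channels=len(optodes.channels),
        extinction_coeffs={wl: dict(extinction[float(wl)]) for wl in wavelengths},
    )
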