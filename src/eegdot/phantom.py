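"""Layered spherical head phantom: geometry, source space, sensor layouts.

The phantom replaces a realistic FEM head model with a four-shell concentric
sphere (brain, CSF, skull, scalp).  Neuronal sources live on the outer brain
surface ("cortical shell") with radially oriented dipoles; EEG electrodes sit
on the scalp shell at standard 10-20 angular positions; DOT optodes form a
rectangular patch over the right hemisphere.

Coordinates are right-handed RAS-like (x right, y anterior, z superior),
head centre at the origin, millimetres throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeadModel",
    "SourceSpace",
    "ElectrodeArray",
    "OptodeArray",
    "PatchFrame",
    "GeometryError",
    "ConfigurationError",
    "DEFAULT_OPTICAL_PROPS",
    "build_spherical_head",
    "place_sensors",
    "fibonacci_shell",
]


class GeometryError(ValueError):
    """Raised for inconsistent head geometry (e.g. non-increasing radii)."""


class ConfigurationError(ValueError):
    """Raised for unknown layouts or invalid sensor configuration."""


#: Homogeneous brain-like optical properties per wavelength (mm^-1).
#: mua = absorption, musp = reduced scattering; literature-typical values.
DEFAULT_OPTICAL_PROPS = {
    750.0: {"mua": 0.0178, "musp": 1.25},
    850.0: {"mua": 0.0186, "musp": 1.10},
}

#: Relative conductivities brain : CSF : skull : scalp.  The skull is 80x
#: more resistive than scalp/brain and CSF 5x more conductive.
DEFAULT_CONDUCTIVITIES = (1.0, 5.0, 1.0 / 80.0, 1.0)

#: Outer radii of the brain, CSF, skull and scalp shells (mm).
DEFAULT_SHELL_RADII = (80.0, 82.0, 87.0, 92.0)


@dataclass(frozen=True)
class HeadModel:
    """Four-shell spherical head.

    Parameters
    ----------
    shell_radii : tuple of float
        Outer radii (mm) of the brain, CSF, skull and scalp shells,
        strictly increasing.
    conductivities : tuple of float
        Relative electrical conductivities of the four shells
        (brain, CSF, skull, scalp).
    optical_props : dict
        ``{wavelength_nm: {"mua": float, "musp": float}}`` in mm^-1.
    """

    shell_radii: tuple = DEFAULT_SHELL_RADII
    conductivities: tuple = DEFAULT_CONDUCTIVITIES
    optical_props: dict = field(default_factory=lambda: dict(DEFAULT_OPTICAL_PROPS))

    def __post_init__(self):
        radii = np.asarray(self.shell_radii, float)
        if radii.size != 4 or np.any(np.diff(radii) <= 0):
            raise GeometryError(
                f"shell radii must be 4 strictly increasing values, got {self.shell_radii}"
            )
        if len(self.conductivities) != 4 or any(s <= 0 for s in self.conductivities):
            raise GeometryError("need 4 positive conductivities")
        for wl, props in self.optical_props.items():
            if props["mua"] <= 0 or props["musp"] <= 0:
                raise GeometryError(f"optical properties at {wl} nm must be positive")

    @property
    def cortex_radius(self) -> float:
        return float(self.shell_radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.shell_radii[3])

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted(self.optical_props))


@dataclass(frozen=True)
class SourceSpace:
    """Quasi-uniform source grid on the cortical shell with radial normals."""

    positions: np.ndarray  # (V, 3) mm
    normals: np.ndarray    # (V, 3) unit radial
    voxel_ids: np.ndarray  # (V,) int labels

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def nominal_spacing(self) -> float:
        """Median nearest-neighbour distance (mm), a resolution scale."""
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        return float(np.median(d[:, 1]))


@dataclass(frozen=True)
class ElectrodeArray:
    positions: np.ndarray  # (E, 3) mm on the scalp shell
    labels: tuple          # 10-20 names

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class PatchFrame:
    """Local tangent frame of the optode patch.

    ``centre_dir`` is the unit outward direction of the patch centre;
    ``e1``/``e2`` span the tangent plane.  Points at local tangent
    coordinates (u, v) are mapped to a shell of radius R with the
    azimuthal-equidistant (exponential) map, which preserves arc length
    from the patch centre.
    """

    centre_dir: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def to_shell(self, uv: np.ndarray, radius: float) -> np.ndarray:
        """Map local (u, v) mm coordinates onto a sphere of ``radius``."""
        uv = np.atleast_2d(np.asarray(uv, float))
        rho = np.hypot(uv[:, 0], uv[:, 1])
        ang = rho / radius
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(rho[:, None] > 0, uv / np.maximum(rho, 1e-300)[:, None], 0.0)
        tang = t[:, 0:1] * self.e1 + t[:, 1:2] * self.e2
        pts = radius * (np.cos(ang)[:, None] * self.centre_dir + np.sin(ang)[:, None] * tang)
        return pts

    def local_coords(self, points: np.ndarray, surface_radius: float) -> np.ndarray:
        """Inverse map: (u, v, depth) of 3-D points relative to the patch.

        ``u``/``v`` are azimuthal-equidistant tangent coordinates at
        ``surface_radius``; ``depth`` is the radial distance below that
        surface (positive inward).
        """
        pts = np.atleast_2d(np.asarray(points, float))
        r = np.linalg.norm(pts, axis=1)
        d = pts / r[:, None]
        cosang = np.clip(d @ self.centre_dir, -1.0, 1.0)
        ang = np.arccos(cosang)
        tang = d - cosang[:, None] * self.centre_dir
        tnorm = np.linalg.norm(tang, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            that = np.where(tnorm[:, None] > 1e-12, tang / np.maximum(tnorm, 1e-300)[:, None], 0.0)
        rho = surface_radius * ang
        u = rho * (that @ self.e1)
        v = rho * (that @ self.e2)
        depth = surface_radius - r
        return np.column_stack([u, v, depth])


@dataclass(frozen=True)
class OptodeArray:
    """DOT source/detector layout with source-detector channel pairs."""

    source_positions: np.ndarray    # (S, 3) mm on the scalp shell
    detector_positions: np.ndarray  # (D, 3) mm
    channels: tuple                 # ((source_idx, detector_idx), ...)
    density: str                    # "regular" | "high"
    frame: PatchFrame

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_distances(self) -> np.ndarray:
        si = np.array([c[0] for c in self.channels])
        di = np.array([c[1] for c in self.channels])
        return np.linalg.norm(
            self.source_positions[si] - self.detector_positions[di], axis=1
        )

    def channel_midpoints(self) -> np.ndarray:
        si = np.array([c[0] for c in self.channels])
        di = np.array([c[1] for c in self.channels])
        return 0.5 * (self.source_positions[si] + self.detector_positions[di])


def fibonacci_shell(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice of ``n`` points on a sphere."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def build_spherical_head(
    shell_radii=DEFAULT_SHELL_RADII,
    conductivities=DEFAULT_CONDUCTIVITIES,
    optical_props=None,
    resolution: int = 1000,
):
    """Build the layered head and its cortical source space.

    Parameters
    ----------
    resolution : int
        Number of source voxels placed quasi-uniformly (Fibonacci lattice)
        on the cortical shell.  Must be >= 500 so that the activation-spot
        and metric machinery has a meaningful grid to work with.

    Returns
    -------
    head : HeadModel
    sources : SourceSpace
    """
    if resolution < 500:
        raise ConfigurationError(f"resolution must be >= 500, got {resolution}")
    head = HeadModel(
        shell_radii=tuple(float(r) for r in shell_radii),
        conductivities=tuple(float(s) for s in conductivities),
        optical_props=dict(optical_props) if optical_props else dict(DEFAULT_OPTICAL_PROPS),
    )
    pos = fibonacci_shell(resolution, head.cortex_radius)
    normals = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    sources = SourceSpace(
        positions=pos, normals=normals, voxel_ids=np.arange(resolution)
    )
    return head, sources


# ---------------------------------------------------------------------------
# Sensor layouts
# ---------------------------------------------------------------------------

_EEG32_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
)

_EEG64_LABELS = _EEG32_LABELS + (
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)


def _standard_1020_positions(labels):
    """10-20/10-10 angular positions from MNE's bundled montage, sphere-fit
    and radially projected.  Returns unit direction vectors."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import mne

        montage = mne.channels.make_standard_montage("standard_1020")
    chpos = montage.get_positions()["ch_pos"]
    all_pos = np.array([chpos[name] for name in montage.ch_names])
    # least-squares sphere fit: centre c minimising |(|p-c|^2 - r^2)| spread
    A = np.column_stack([2 * all_pos, np.ones(len(all_pos))])
    b = (all_pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    missing = [lab for lab in labels if lab not in chpos]
    if missing:
        raise ConfigurationError(f"labels missing from 10-20 template: {missing}")
    pos = np.array([chpos[lab] for lab in labels]) - centre
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def default_patch_frame() -> PatchFrame:
    """Patch over the right hemisphere, centred at 45 deg elevation
    (right motor/somatosensory analogue)."""
    c = np.array([np.cos(np.pi / 4), 0.0, np.sin(np.pi / 4)])
    e1 = np.array([0.0, 1.0, 0.0])  # anterior
    e2 = np.cross(c, e1)
    e2 /= np.linalg.norm(e2)
    return PatchFrame(centre_dir=c, e1=e1, e2=e2)


#: lattice constant of the regular optode grid (mm); nearest source-detector
#: separation, within the 17-27 mm regular-grid range.
_REGULAR_PITCH = 21.0
_HIGH_DENSITY_PITCH = 10.5


def _checkerboard_grid(nx, ny, pitch):
    """(u,v) lattice with alternating source/detector roles."""
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    src_uv, det_uv, role = [], [], {}
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            if (i + j) % 2 == 0:
                role[(i, j)] = ("S", len(src_uv))
                src_uv.append((x, y))
            else:
                role[(i, j)] = ("D", len(det_uv))
                det_uv.append((x, y))
    return np.array(src_uv), np.array(det_uv), role, xs, ys


def _pair_channels(src_uv, det_uv, dmin, dmax):
    """All source-detector pairs with planar separation in [dmin, dmax]."""
    channels = []
    for si, s in enumerate(src_uv):
        for di, d in enumerate(det_uv):
            dist = float(np.hypot(*(s - d)))
            if dmin <= dist <= dmax:
                channels.append((si, di))
    return tuple(channels)


def _optode_array(head, src_uv, det_uv, channels, density, frame):
    R = head.scalp_radius
    return OptodeArray(
        source_positions=frame.to_shell(src_uv, R),
        detector_positions=frame.to_shell(det_uv, R),
        channels=channels,
        density=density,
        frame=frame,
    )


def place_sensors(head: HeadModel, layout: str, frame: PatchFrame | None = None):
    """Place EEG electrodes or DOT optodes on the scalp shell.

    Layouts
    -------
    ``eeg32`` / ``eeg64``
        Standard 10-20 (extended 10-10) positions, radially projected onto
        the scalp sphere.
    ``dot_regular``
        4x4 checkerboard of 8 sources and 8 detectors at 21 mm pitch over
        the right-lateral patch; the 24 nearest-neighbour pairs form the
        channels (separations all within 17-27 mm).
    ``dot_regular_plus_detector``
        Same grid plus one extra detector beyond the +u edge, adding two
        channels (26 total).
    ``dot_high_density``
        7x7 checkerboard at 10.5 mm pitch; all pairs with separation in
        [7.5, 29] mm are channels (overlapping, high-density style).
    """
    frame = frame or default_patch_frame()
    if layout in ("eeg32", "eeg64"):
        labels = _EEG32_LABELS if layout == "eeg32" else _EEG64_LABELS
        dirs = _standard_1020_positions(labels)
        return ElectrodeArray(positions=head.scalp_radius * dirs, labels=labels)

    if layout == "dot_regular" or layout == "dot_regular_plus_detector":
        src_uv, det_uv, role, xs, ys = _checkerboard_grid(4, 4, _REGULAR_PITCH)
        channels = _pair_channels(src_uv, det_uv, 17.0, 27.0)
        if layout == "dot_regular_plus_detector":
            # extra detector just beyond the +u edge, between the two edge
            # sources of the outer column -> exactly two extra channels
            # (as far out as the regular channel-distance range allows)
            extra = np.array([[xs[-1] + 16.5, ys[2]]])
            det_uv = np.vstack([det_uv, extra])
            channels = _pair_channels(src_uv, det_uv, 17.0, 27.0)
        arr = _optode_array(head, src_uv, det_uv, channels, "regular", frame)
        return arr

    if layout == "dot_high_density":
        src_uv, det_uv, *_ = _checkerboard_grid(7, 7, _HIGH_DENSITY_PITCH)
        channels = _pair_channels(src_uv, det_uv, 7.5, 29.0)
        return _optode_array(head, src_uv, det_uv, channels, "high", frame)

    raise ConfigurationError(f"unknown layout {layout!r}")
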