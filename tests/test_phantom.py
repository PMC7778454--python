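"""Geometry, sensor layouts, and the analytic forward models."""

import numpy as np
import pytest

import eegdot as ed
from eegdot.forward import (
    multishell_dipole_potential,
    semi_infinite_green,
    shell_series_coefficients,
)
from eegdot.phantom import ConfigurationError, GeometryError


# ---------------------------------------------------------------------------
# head + source space construction
# ---------------------------------------------------------------------------


def test_source_space_on_cortical_shell(head_sources):
    head, sources = head_sources
    r = np.linalg.norm(sources.positions, axis=1)
    assert np.allclose(r, 80.0, atol=1e-6)
    norms = np.linalg.norm(sources.normals, axis=1)
    assert np.allclose(norms, 1.0, atol=1e-12)


def test_source_space_resolution_and_spacing():
    head, sources = ed.build_spherical_head(resolution=1000)
    assert sources.n_voxels == 1000
    from scipy.spatial.distance import pdist

    assert pdist(sources.positions).min() > 0


def test_build_deterministic():
    h1, s1 = ed.build_spherical_head()
    h2, s2 = ed.build_spherical_head()
    assert np.array_equal(s1.positions, s2.positions)
    assert h1.shell_radii == h2.shell_radii


def test_geometry_errors():
    with pytest.raises(GeometryError):
        ed.build_spherical_head(shell_radii=(80, 78, 87, 92))
    with pytest.raises(ConfigurationError):
        ed.build_spherical_head(resolution=100)


# ---------------------------------------------------------------------------
# sensor layouts
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("layout,count", [("eeg32", 32), ("eeg64", 64)])
def test_eeg_layouts_on_scalp(head_sources, layout, count):
    head, _ = head_sources
    arr = ed.place_sensors(head, layout)
    assert arr.n_channels == count
    assert np.allclose(np.linalg.norm(arr.positions, axis=1), head.scalp_radius)


def test_regular_grid_channel_count_and_distances(head_sources):
    head, _ = head_sources
    opt = ed.place_sensors(head, "dot_regular")
    assert opt.n_channels == 24
    d = opt.channel_distances()
    assert d.min() >= 17.0 and d.max() <= 27.0


def test_extra_detector_adds_two_channels(head_sources):
    head, _ = head_sources
    opt = ed.place_sensors(head, "dot_regular_plus_detector")
    assert opt.n_channels == 26
    d = opt.channel_distances()
    assert d.min() >= 17.0 and d.max() <= 27.0


def test_high_density_distances(head_sources):
    head, _ = head_sources
    opt = ed.place_sensors(head, "dot_high_density")
    d = opt.channel_distances()
    assert d.min() >= 7.5 and d.max() <= 29.0
    assert opt.n_channels > 24  # overlapping, denser than the regular grid


def test_unknown_layout(head_sources):
    head, _ = head_sources
    with pytest.raises(ConfigurationError):
        ed.place_sensors(head, "meg")


# ---------------------------------------------------------------------------
# EEG leadfield
# ---------------------------------------------------------------------------


def _closed_form_single_sphere(head, p0, m, elec_pos):
    """Frank-type closed-form surface potential of a dipole inside a
    homogeneous conducting sphere (independent oracle, derived by summing
    the Legendre series in closed form)."""
    sig = head.conductivities[0]
    R = head.scalp_radius
    b = np.linalg.norm(p0)
    f = b / R
    rhat = p0 / b
    ehat = elec_pos / np.linalg.norm(elec_pos, axis=1, keepdims=True)
    c = np.clip(ehat @ rhat, -1.0, 1.0)
    s = np.sqrt(np.maximum(0.0, 1.0 - c * c))
    t = ehat - c[:, None] * rhat
    tn = np.linalg.norm(t, axis=1)
    that = np.where(tn[:, None] > 1e-12, t / np.maximum(tn, 1e-300)[:, None], 0.0)
    mr = m @ rhat
    mt = that @ m
    d = np.sqrt(1 + f * f - 2 * f * c)
    radial = 2 * (c - f) / d**3 + (1 / f) * (1 / d - 1)
    tangential = s * (2 / d**3 + (d + 1) / (d * (1 - f * c + d)))
    return (mr * radial + mt * tangential) / (4 * np.pi * sig * R**2)


def test_series_coefficients_homogeneous_limit():
    head, _ = ed.build_spherical_head(conductivities=(1, 1, 1, 1))
    n = np.arange(1, 41)
    F = shell_series_coefficients(head, 40)
    assert np.allclose(F, (2 * n + 1) / n, rtol=1e-12)


def test_homogeneous_sphere_matches_closed_form(head_sources):
    head_hom, _ = ed.build_spherical_head(conductivities=(2.5, 2.5, 2.5, 2.5))
    elec = ed.place_sensors(head_hom, "eeg32")
    rng = np.random.default_rng(7)
    for _ in range(3):
        p0 = rng.normal(size=3)
        p0 *= rng.uniform(30, 55) / np.linalg.norm(p0)  # deep enough to converge
        m = rng.normal(size=3)
        V = multishell_dipole_potential(head_hom, p0, m, elec.positions, n_terms=150)
        V_cf = _closed_form_single_sphere(head_hom, p0, m, elec.positions)
        assert np.max(np.abs(V - V_cf)) / np.max(np.abs(V_cf)) < 1e-6


def test_leadfield_average_reference(assets):
    col_sums = assets.leadfield.matrix.sum(axis=0)
    scale = np.abs(assets.leadfield.matrix).max()
    assert np.max(np.abs(col_sums)) < 1e-10 * scale * 32


def test_radial_dipole_peaks_beneath_electrode(head_sources):
    """A radial dipole directly beneath an electrode produces its largest
    (pre-reference) potential at that electrode."""
    head, _ = head_sources
    elec = ed.place_sensors(head, "eeg32")
    for e in (0, 13, 25):
        direction = elec.positions[e] / np.linalg.norm(elec.positions[e])
        p0 = 75.0 * direction
        V = multishell_dipole_potential(head, p0, direction, elec.positions)
        assert np.argmax(np.abs(V)) == e


def test_dipole_potential_linearity(head_sources):
    head, _ = head_sources
    elec = ed.place_sensors(head, "eeg32")
    rng = np.random.default_rng(3)
    p0 = np.array([10.0, 20.0, 60.0])
    m1, m2 = rng.normal(size=3), rng.normal(size=3)
    V12 = multishell_dipole_potential(head, p0, m1 + m2, elec.positions)
    V1 = multishell_dipole_potential(head, p0, m1, elec.positions)
    V2 = multishell_dipole_potential(head, p0, m2, elec.positions)
    assert np.allclose(V12, V1 + V2, rtol=1e-12, atol=1e-300)


def test_eeg_sensitivity_decays_with_depth(head_sources):
    head, _ = head_sources
    elec = ed.place_sensors(head, "eeg32")
    direction = elec.positions[13] / np.linalg.norm(elec.positions[13])
    mags = []
    for radius in (78.0, 70.0, 60.0, 45.0):
        V = multishell_dipole_potential(head, radius * direction, direction,
                                        elec.positions, average_reference=True)
        mags.append(np.abs(V).max())
    assert np.all(np.diff(mags) < 0)


def test_leadfield_domain_error(head_sources):
    head, _ = head_sources
    elec = ed.place_sensors(head, "eeg32")
    with pytest.raises(GeometryError):
        multishell_dipole_potential(head, np.array([0, 0, 95.0]),
                                    np.array([0, 0, 1.0]), elec.positions)


# ---------------------------------------------------------------------------
# DOT Jacobian
# ---------------------------------------------------------------------------


def test_jacobian_zero_concentration_zero_od(assets):
    dod = assets.jacobian.matrix @ np.zeros(assets.jacobian.matrix.shape[1])
    assert np.all(dod == 0)


def test_jacobian_reciprocity(assets):
    """Swapping every channel's source and detector leaves the sensitivity
    rows unchanged (Green's function reciprocity)."""
    head = assets.head
    opt = assets.optodes
    swapped = ed.OptodeArray(
        source_positions=opt.detector_positions,
        detector_positions=opt.source_positions,
        channels=tuple((d, s) for s, d in opt.channels),
        density=opt.density,
        frame=opt.frame,
    )
    J2 = ed.compute_dot_jacobian(head, swapped, assets.sources)
    assert np.max(np.abs(assets.jacobian.matrix - J2.matrix)) < 1e-10 * np.abs(
        assets.jacobian.matrix
    ).max()


def test_midpoint_sensitivity_exceeds_lateral(assets):
    """Per channel, the cortical voxel nearest the source-detector midpoint
    is sensed more strongly than any voxel >= 20 mm laterally offset at the
    same depth (banana-shaped sensitivity)."""
    J = assets.jacobian
    sources = assets.sources
    block = np.abs(J.wavelength_block(J.wavelengths[0])[:, : sources.n_voxels])
    mids = assets.optodes.channel_midpoints()
    mids_cortex = mids / np.linalg.norm(mids, axis=1, keepdims=True) * 80.0
    from scipy.spatial.distance import cdist

    d_mid = cdist(mids_cortex, sources.positions)
    for ch in range(0, J.n_channels, 5):
        vmid = int(np.argmin(d_mid[ch]))
        lateral = np.flatnonzero(d_mid[ch] >= 20.0)
        assert block[ch, vmid] > block[ch, lateral].max()


def test_optical_sensitivity_decays_with_depth(assets):
    mua, musp = 0.0178, 1.25
    src = np.array([[0.0, 0.0, 1.0 / musp]])
    det = np.array([[21.0, 0.0, 1.0 / musp]])
    depths = np.array([8.0, 12.0, 20.0, 30.0])
    vox = np.column_stack([np.full(4, 10.5), np.zeros(4), depths])
    s = (
        semi_infinite_green(src, vox, mua, musp)[0]
        * semi_infinite_green(vox, det, mua, musp)[:, 0]
    )
    assert np.all(np.diff(s) < 0)


def test_jacobian_wavelength_blocks_identical_when_props_match(head_sources):
    """With the same optical properties and extinction coefficients the two
    wavelength blocks coincide: they differ only through physics inputs."""
    _, sources = head_sources
    props = {"mua": 0.018, "musp": 1.2}
    head, _ = ed.build_spherical_head(
        optical_props={750.0: dict(props), 850.0: dict(props)}
    )
    opt = ed.place_sensors(head, "dot_regular")
    eps = {750.0: {"HbO": 600.0, "Hb": 1000.0}, 850.0: {"HbO": 600.0, "Hb": 1000.0}}
    J = ed.compute_dot_jacobian(head, opt, sources, extinction=eps)
    C = J.n_channels
    assert np.allclose(J.matrix[:C], J.matrix[C:], rtol=1e-12)


def test_zero_scattering_is_physics_error(assets):
    from eegdot.forward import PhysicsError

    with pytest.raises(PhysicsError):
        semi_infinite_green(np.zeros((1, 3)), np.ones((1, 3)), 0.02, 0.0)
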