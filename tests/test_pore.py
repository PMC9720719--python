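import numpy as np
import pytest

from tetragate import synthetic
from tetragate.pore import (GateCall, PoreProfile, call_state, compute_profile,
                            gate_anchored_profile, locate_gate,
                            normalize_profile)
from tetragate.structure_io import StructureModel


def _ring_stack(center_radius=6.0, n_rings=20, n_per_ring=48, dz=1.0,
                constrict_at=None, constrict_radius=3.0):
    """Ideal cylinder of atom rings; optionally one tightened ring."""
    rows = []
    serial = 1
    for i in range(n_rings):
        z = i * dz
        r = constrict_radius if i == constrict_at else center_radius
        for k in range(n_per_ring):
            th = 2 * np.pi * k / n_per_ring
            rows.append((serial, r * np.cos(th), r * np.sin(th), z, i + 1))
            serial += 1
    serials, xs, ys, zs, res = zip(*rows)
    n = len(serials)
    return StructureModel.from_arrays(
        serial=serials, name=["X1"] * n, element=["C"] * n,
        residue_number=res, residue_name=["SYN"] * n,
        subunit=[1] * n, coords=np.stack([xs, ys, zs], axis=1),
        numbering_scheme="canonical")


VDW = {"C": 1.5}


def brute_force_slab_radius(model, z, grid=0.05, extent=3.5):
    """Oracle: exhaustive grid maximization of the probe radius over the
    pore interior (the extent stays inside the channel wall, since the
    mathematical maximum over the unbounded plane lies in free space
    outside the structure)."""
    coords = model.coords
    g = np.arange(-extent, extent + 1e-9, grid)
    gx, gy = np.meshgrid(g, g)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    d = np.sqrt(((coords[None, :, :2] - pts[:, None, :]) ** 2).sum(axis=2)
                + (coords[None, :, 2] - z) ** 2) - 1.5
    return max(float(d.min(axis=1).max()), 0.0)


def test_ideal_cylinder_profile_is_analytic():
    model = _ring_stack()
    prof = compute_profile(model, radius_table=VDW, cutoff_radius=10.0,
                           z_min=2.0, z_max=17.0)
    assert np.all(np.abs(prof.radius - 4.5) < 0.1)
    assert np.all(np.diff(prof.z) > 0)


def test_constricted_ring_minimum_matches_oracle():
    model = _ring_stack(constrict_at=10, constrict_radius=3.0)
    prof = compute_profile(model, radius_table=VDW, z_min=4.0, z_max=16.0)
    i = int(np.argmin(prof.radius))
    assert prof.z[i] == pytest.approx(10.0, abs=0.26)
    assert prof.radius[i] == pytest.approx(1.5, abs=0.1)
    for z in (6.0, 8.0, 10.0, 12.0):
        oracle = brute_force_slab_radius(model, z)
        assert prof.radius_at(z) == pytest.approx(oracle, abs=0.1)


def test_random_constricted_channels_match_bruteforce_oracle(rng):
    for _ in range(3):
        cr = rng.uniform(2.5, 4.5)
        model = _ring_stack(center_radius=rng.uniform(5.0, 7.0),
                            constrict_at=int(rng.integers(5, 15)),
                            constrict_radius=cr)
        prof = compute_profile(model, radius_table=VDW, z_min=3.0, z_max=16.0)
        for z in rng.choice(prof.z, size=5, replace=False):
            assert prof.radius_at(z) == pytest.approx(
                brute_force_slab_radius(model, float(z)), abs=0.1)


def test_profile_terminates_at_cutoff(open_tetramer):
    prof = gate_anchored_profile(open_tetramer, cutoff_radius=10.0)
    assert np.all(prof.radius <= 10.0)
    # beyond the channel mouth the radius exceeds the cutoff, so the
    # profile support is finite even though space is unbounded
    assert prof.z[0] > -100 and prof.z[-1] < 100
    wider = gate_anchored_profile(open_tetramer, cutoff_radius=12.0,
                                  window=25.0)
    assert np.all(wider.radius <= 12.0)
    assert wider.z[-1] >= prof.z[-1]


def test_vdw_inflation_shrinks_profile_uniformly():
    model = _ring_stack()
    a = compute_profile(model, radius_table={"C": 1.5}, z_min=5.0, z_max=14.0)
    b = compute_profile(model, radius_table={"C": 1.8}, z_min=5.0, z_max=14.0)
    common = np.intersect1d(a.z, b.z)
    ra = np.array([a.radius_at(z) for z in common])
    rb = np.array([b.radius_at(z) for z in common])
    assert np.allclose(ra - rb, 0.3, atol=0.02)


def test_gate_location_and_equivariance(closed_tetramer):
    gz = locate_gate(closed_tetramer)
    assert gz == pytest.approx(12.0, abs=0.1)
    shifted = closed_tetramer.with_coords(closed_tetramer.coords + [0, 0, 5.0])
    assert locate_gate(shifted) == pytest.approx(gz + 5.0, abs=1e-9)
    with pytest.raises(ValueError, match="gate residue"):
        locate_gate(closed_tetramer, gate_residue=99)


def test_normalize_shifts_gate_to_zero_and_flips():
    prof = PoreProfile(z=np.array([10.0, 11.0, 12.0, 13.0]),
                       radius=np.array([3.0, 2.0, 1.0, 2.5]),
                       cutoff_radius=10.0, step=1.0)
    norm = normalize_profile(prof, 12.0, +1)
    assert norm.radius_at(0.0) == 1.0
    assert norm.z[0] == -2.0
    flipped = normalize_profile(prof, 12.0, -1)
    assert np.allclose(flipped.z, -norm.z[::-1])
    assert np.allclose(flipped.radius, norm.radius[::-1])
    ident = normalize_profile(norm, 0.0, +1)
    assert np.allclose(ident.z, norm.z)


def test_profile_invariant_under_axial_translation(closed_tetramer):
    a = gate_anchored_profile(closed_tetramer, window=3.0)
    moved = closed_tetramer.with_coords(closed_tetramer.coords + [0, 0, 7.0])
    b = gate_anchored_profile(moved, window=3.0)
    common = np.intersect1d(np.round(a.z, 6), np.round(b.z, 6))
    assert len(common) >= 10
    for z in common:
        assert a.radius_at(z) == pytest.approx(b.radius_at(z), abs=0.05)


def test_profile_invariant_under_c4_rotation(closed_tetramer):
    theta = np.pi / 2
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    rotated = closed_tetramer.with_coords(closed_tetramer.coords @ R.T)
    a = gate_anchored_profile(closed_tetramer, window=3.0)
    b = gate_anchored_profile(rotated, window=3.0)
    assert np.allclose(a.radius, b.radius, atol=0.05)


def test_minimum_bounded_by_gate_radius(closed_tetramer, open_tetramer):
    for m in (closed_tetramer, open_tetramer):
        call = call_state(gate_anchored_profile(m, window=4.0))
        assert call.min_radius <= call.gate_radius + 1e-9
        assert call.gate_local_min <= call.gate_radius + 1e-9


@pytest.mark.parametrize("gate_radius,expected", [(0.74, "closed"),
                                                  (3.4, "open"),
                                                  (1.5, "open")])
def test_state_threshold_convention(gate_radius, expected):
    prof = PoreProfile(z=np.array([-1.0, 0.0, 1.0]),
                       radius=np.array([gate_radius + 0.5, gate_radius,
                                        gate_radius + 0.5]),
                       cutoff_radius=10.0, step=1.0)
    assert call_state(prof).state == expected


def test_state_call_outside_support_raises():
    prof = PoreProfile(z=np.array([5.0, 6.0]), radius=np.array([1.0, 2.0]),
                       cutoff_radius=10.0, step=1.0)
    with pytest.raises(ValueError, match="outside the profile support"):
        call_state(prof)


def test_synthetic_presets_reproduce_gate_radius_clusters(closed_tetramer,
                                                          open_tetramer):
    closed_call = call_state(gate_anchored_profile(closed_tetramer, window=2.0))
    open_call = call_state(gate_anchored_profile(open_tetramer, window=2.0))
    assert closed_call.gate_radius == pytest.approx(0.74, abs=0.1)
    assert closed_call.state == "closed"
    assert open_call.gate_radius == pytest.approx(3.4, abs=0.1)
    assert open_call.state == "open"
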