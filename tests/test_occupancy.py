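import numpy as np
import pytest

from tetragate import synthetic
from tetragate.occupancy import (DEFAULT_POOLS, OccupancyRecord, ResidueKey,
                                 compare_summaries, filter_high_occupancy,
                                 frame_contacts, frame_to_records,
                                 interface_sites, occupancy_table,
                                 records_to_frame, summarize_counts)
from tetragate.regions import ResidueRegion
from tetragate.structure_io import StructureModel
from tetragate.trajstats import TrajectoryEnsemble


def _two_residue_model(distance, with_hydrogen=False, hydrogen_distance=1.0):
    """Two single-atom residues on different subunits, a set distance apart."""
    rows = [
        (1, "C1", "C", 100, 1, (0.0, 0.0, 0.0)),
        (2, "C1", "C", 200, 2, (distance, 0.0, 0.0)),
    ]
    if with_hydrogen:
        rows.append((3, "H1", "H", 100, 1, (hydrogen_distance / 2, 0.0, 0.0)))
        rows.append((4, "H2", "H", 200, 2, (hydrogen_distance / 2 + 0.01, 0.0, 0.0)))
    serial, name, el, res, su, pos = zip(*rows)
    return StructureModel.from_arrays(
        serial=serial, name=name, element=el, residue_number=res,
        residue_name=["ALA"] * len(rows), subunit=su, coords=np.array(pos),
        numbering_scheme="canonical")


@pytest.mark.parametrize("distance,n_events", [(2.9, 1), (3.0, 1), (3.1, 0)])
def test_cutoff_boundary_is_inclusive(distance, n_events):
    events = frame_contacts(_two_residue_model(distance))
    assert len(events) == n_events
    if n_events:
        assert events[0].min_distance == pytest.approx(distance)
        assert events[0].a == ResidueKey(1, 100, "ALA")
        assert events[0].b == ResidueKey(2, 200, "ALA")


def test_hydrogen_contacts_are_ignored():
    # hydrogens 0.01 Å apart between the residues; heavies 4 Å apart
    events = frame_contacts(_two_residue_model(4.0, with_hydrogen=True))
    assert events == []


def test_sequence_adjacent_pairs_excluded():
    rows = [(i, "C1", "C", 100 + i, 1, (i * 2.0, 0.0, 0.0)) for i in range(4)]
    serial, name, el, res, su, pos = zip(*rows)
    m = StructureModel.from_arrays(
        serial=serial, name=name, element=el, residue_number=res,
        residue_name=["ALA"] * 4, subunit=su, coords=np.array(pos),
        numbering_scheme="canonical")
    events = frame_contacts(m, cutoff=2.5)  # neighbours are 2.0 Å apart
    assert events == []  # |Δresidue| <= 2 on one subunit is trivial contact
    events = frame_contacts(m, cutoff=2.5, min_sequence_separation=1)
    assert len(events) == 3


def test_random_frames_match_brute_force_oracle(rng):
    """KD-tree contact search equals the O(n^2) oracle, 100 random frames."""
    n = 500
    for trial in range(100):
        coords = rng.uniform(0, 30, (n, 3))
        m = StructureModel.from_arrays(
            serial=np.arange(1, n + 1),
            name=["C1"] * n, element=["C"] * n,
            residue_number=rng.integers(1, 120, n),
            residue_name=["ALA"] * n,
            subunit=rng.integers(1, 5, n), coords=coords,
            numbering_scheme="canonical")
        got = {(e.a.subunit, e.a.number, e.b.subunit, e.b.number):
               e.min_distance for e in frame_contacts(m, cutoff=3.0)}
        expected = _brute_force_contacts(m, cutoff=3.0)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)


def _brute_force_contacts(m, cutoff):
    d = np.linalg.norm(m.coords[:, None] - m.coords[None, :], axis=2)
    out = {}
    for i in range(m.n_atoms):
        for j in range(i + 1, m.n_atoms):
            if d[i, j] > cutoff:
                continue
            su_i, su_j = int(m.subunit[i]), int(m.subunit[j])
            r_i, r_j = int(m.residue_number[i]), int(m.residue_number[j])
            if (su_i, r_i) == (su_j, r_j):
                continue
            if su_i == su_j and abs(r_i - r_j) < 3:
                continue
            a, b = sorted([(su_i, r_i), (su_j, r_j)])
            key = (a[0], a[1], b[0], b[1])
            out[key] = min(out.get(key, np.inf), float(d[i, j]))
    return out


def test_occupancy_counts_frames_with_any_contact(tiny_tetramer):
    pair = ((1, 4866), (3, 4866))
    sched = synthetic.ContactSchedule(pair=pair, p=1.0)
    traj = synthetic.make_trajectory(
        tiny_tetramer, synthetic.TrajectorySpec(
            n_frames=10, jitter_sigma=0.0, contact_schedule=(sched,), seed=5))
    scope = ResidueRegion.single("a", 4866, 4866)
    records = occupancy_table(traj, scope=scope, system="toy")
    rec = _find(records, (1, 4866), (3, 4866))
    assert rec.occupancy == 1.0
    assert rec.locality == "inter"
    assert rec.n_frames == 10


def test_engineered_bernoulli_occupancy_recovered(tiny_tetramer):
    pair = ((1, 4866), (3, 4866))
    scope = ResidueRegion.single("a", 4866, 4866)
    estimates = []
    for seed in range(60):
        sched = synthetic.ContactSchedule(pair=pair, p=0.4)
        traj = synthetic.make_trajectory(
            tiny_tetramer, synthetic.TrajectorySpec(
                n_frames=100, jitter_sigma=0.05,
                contact_schedule=(sched,), seed=seed))
        records = occupancy_table(traj, frame_window=100, scope=scope)
        rec = _find(records, (1, 4866), (3, 4866))
        estimates.append(rec.occupancy if rec else 0.0)
    estimates = np.array(estimates)
    band = 4 * np.sqrt(0.4 * 0.6 / 100)
    assert np.mean(np.abs(estimates - 0.4) <= band) >= 0.99
    assert estimates.mean() == pytest.approx(0.4, abs=0.03)


def _find(records, a, b):
    for r in records:
        if ((r.a.subunit, r.a.number), (r.b.subunit, r.b.number)) == (a, b):
            return r
    return None


def test_high_occupancy_threshold_is_inclusive():
    def rec(occ):
        return OccupancyRecord(a=ResidueKey(1, 10, "ALA"),
                               b=ResidueKey(2, 20, "GLY"),
                               occupancy=occ, n_frames=100, locality="inter")
    kept = filter_high_occupancy([rec(0.30), rec(0.29), rec(0.95)])
    assert [r.occupancy for r in kept] == [0.30, 0.95]
    assert filter_high_occupancy([]) == []


def test_records_tsv_roundtrip():
    rec = OccupancyRecord(a=ResidueKey(1, 4763, "ASN"),
                          b=ResidueKey(2, 4874, "ARG"),
                          occupancy=0.62, n_frames=100, locality="inter",
                          system="4O", source_side="a")
    df = records_to_frame([rec])
    assert frame_to_records(df) == [rec]


def _mk(res_a, res_b, su_a=1, su_b=1, system="4C", source_side="a"):
    return OccupancyRecord(
        a=ResidueKey(su_a, res_a, "X"), b=ResidueKey(su_b, res_b, "Y"),
        occupancy=0.5, n_frames=100,
        locality="inter" if su_a != su_b else "intra",
        system=system, source_side=source_side)


def test_source_and_partner_modes_count_correct_side():
    records = [_mk(4763, 4868)]
    src = summarize_counts([("4C", records)], "closed-pool", "source-residue")
    assert src.counts == {4763: 1}
    par = summarize_counts([("4C", records)], "closed-pool", "partner-residue")
    assert par.counts == {4868: 1}


def test_pooling_across_subunits_and_systems():
    sets = [(sys_name, [_mk(4763, 4868, su_a=su, su_b=(su % 4) + 1,
                            system=sys_name) for su in (1, 2, 3, 4)])
            for sys_name in ("4C", "1C3O", "1C3O-HID")]
    summary = summarize_counts(sets, "closed-pool", "source-residue")
    assert summary.counts == {4763: 12}
    # sum over residues equals the number of records
    assert sum(summary.counts.values()) == 12


def test_interface_mode_excludes_intra_and_counts_both_sides():
    records = [_mk(4763, 4874, su_a=1, su_b=2), _mk(4759, 4869, su_a=1, su_b=1)]
    summary = summarize_counts([("4O", records)], "open-pool", "interface",
                               pools={"open-pool": ("4O",)})
    assert summary.counts == {4763: 1, 4874: 1}


def test_mixed_pools_in_one_call_raise():
    with pytest.raises(ValueError, match="mixed groupings"):
        summarize_counts([("4C", []), ("4O", [])], "closed-pool",
                         "source-residue")


def test_min_appearances_keeps_residues_passing_in_either_pool():
    closed = summarize_counts(
        [("4C", [_mk(4763, 4874, su_b=2)] * 2)], "closed-pool", "interface")
    open_ = summarize_counts(
        [("4O", [_mk(4763, 4874, su_b=2, system="4O")] * 3)],
        "open-pool", "interface")
    assert closed.counts == {4763: 2, 4874: 2}
    filtered = summarize_counts(
        [("4C", [_mk(4763, 4874, su_b=2)] * 2)], "closed-pool", "interface",
        min_appearances=3, companion_summaries=[open_])
    # closed count is 2 (<3) but the open pool reaches 3, so kept
    assert filtered.counts == {4763: 2, 4874: 2}
    alone = summarize_counts(
        [("4C", [_mk(4763, 4874, su_b=2)] * 2)], "closed-pool", "interface",
        min_appearances=3)
    assert alone.counts == {}
    df = compare_summaries([closed, open_], min_appearances=3)
    assert list(df.index) == [4763, 4874]
    assert df.loc[4763, "closed-pool"] == 2
    assert df.loc[4763, "open-pool"] == 3


def test_interface_sites_union_of_inter_partners():
    records = [_mk(4763, 4874, su_b=2), _mk(4759, 4869)]  # second is intra
    assert interface_sites(records) == {4763, 4874}
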