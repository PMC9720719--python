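"""Residue-pair contact occupancy over trajectory windows.

A residue pair is "in contact" in a frame when any heavy-atom (non-hydrogen)
pair between the two residues lies within the distance cutoff (3.0 Å by
default — close to the mean donor-acceptor distance of protein hydrogen
bonds).  The percent occupancy of a pair is the fraction of analysed frames
in which the contact appears; pairs at >= 30% are the "high percent
occupancy" interactions that the downstream summaries and the mutation
proximity analysis consume.

Contacts are classified intra-subunit vs inter-subunit, and summaries pool
records from all four subunits across the systems of a pool (e.g. the three
closed-state systems vs the three open-state systems).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .regions import ResidueRegion
from .structure_io import StructureModel
from .trajstats import TrajectoryEnsemble

DEFAULT_CUTOFF = 3.0
HIGH_OCCUPANCY_THRESHOLD = 0.30
#: same-subunit pairs within this sequence separation are trivial backbone
#: neighbours and excluded by default
MIN_SEQUENCE_SEPARATION = 3

RECORD_COLUMNS = ["system", "subunit_a", "res_a", "name_a",
                  "subunit_b", "res_b", "name_b",
                  "occupancy", "n_frames", "locality", "source_side"]


@dataclass(frozen=True)
class ResidueKey:
    subunit: int
    number: int
    name: str

    def sort_key(self) -> tuple[int, int]:
        return (self.subunit, self.number)


@dataclass(frozen=True)
class ContactEvent:
    frame: int
    a: ResidueKey
    b: ResidueKey
    min_distance: float


@dataclass(frozen=True)
class OccupancyRecord:
    a: ResidueKey
    b: ResidueKey
    occupancy: float
    n_frames: int
    locality: str          # 'intra' | 'inter'
    system: str = ""
    source_side: str = "a"  # which member matched the scope selection

    @property
    def source_subunit(self) -> int:
        return (self.a if self.source_side == "a" else self.b).subunit

    @property
    def source_residue(self) -> int:
        return (self.a if self.source_side == "a" else self.b).number

    @property
    def partner_residue(self) -> int:
        return (self.b if self.source_side == "a" else self.a).number


def _canonical_pair(a: ResidueKey, b: ResidueKey) -> tuple[ResidueKey, ResidueKey, bool]:
    """Order the pair (lower subunit, then lower residue first); report swap."""
    if b.sort_key() < a.sort_key():
        return b, a, True
    return a, b, False


def frame_contacts(model: StructureModel, *, coords: np.ndarray | None = None,
                   cutoff: float = DEFAULT_CUTOFF,
                   scope: ResidueRegion | None = None,
                   partner_scope: ResidueRegion | None = None,
                   min_sequence_separation: int = MIN_SEQUENCE_SEPARATION,
                   exclude_scope_scope_same_subunit: bool = True,
                   frame: int = 0) -> list[ContactEvent]:
    """Residue pairs with any heavy-atom pair within ``cutoff`` in one frame.

    One member of each pair must match ``scope`` and the other
    ``partner_scope`` (``None`` = everything).  Same-residue pairs and
    same-subunit pairs closer than ``min_sequence_separation`` in sequence
    are excluded.  When a proper ``scope`` is given, same-subunit pairs with
    *both* members inside the scope are excluded by default (a linker's
    self-contacts are not interface contacts; contacts between the same
    element on adjacent subunits still count); disable with
    ``exclude_scope_scope_same_subunit=False``.

    ``coords`` overrides the model's coordinates (for trajectory frames).
    The KD-tree search returns exactly the all-pairs result.
    """
    xyz = model.coords if coords is None else np.asarray(coords)
    heavy = model.heavy_mask()
    in_scope = heavy if scope is None else heavy & scope.mask(model.residue_number)
    in_partner = heavy if partner_scope is None else heavy & partner_scope.mask(model.residue_number)
    ia, ib = np.flatnonzero(in_scope), np.flatnonzero(in_partner)
    if len(ia) == 0 or len(ib) == 0:
        return []

    ta, tb = cKDTree(xyz[ia]), cKDTree(xyz[ib])
    sparse = ta.sparse_distance_matrix(tb, cutoff, output_type="coo_matrix")

    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    scope_side: dict[tuple[ResidueKey, ResidueKey], str] = {}
    for k in range(sparse.nnz):
        i = int(ia[sparse.row[k]])
        j = int(ib[sparse.col[k]])
        if i == j:
            continue
        su_i, su_j = int(model.subunit[i]), int(model.subunit[j])
        r_i, r_j = int(model.residue_number[i]), int(model.residue_number[j])
        if su_i == su_j:
            if abs(r_i - r_j) < min_sequence_separation:
                continue
            if (exclude_scope_scope_same_subunit and scope is not None
                    and r_i in scope and r_j in scope
                    and (partner_scope is None or
                         (r_i in partner_scope and r_j in partner_scope))):
                continue
        key_i = ResidueKey(su_i, r_i, str(model.residue_name[i]))
        key_j = ResidueKey(su_j, r_j, str(model.residue_name[j]))
        a, b, swapped = _canonical_pair(key_i, key_j)
        d = float(sparse.data[k])
        pair = (a, b)
        if d < best.get(pair, np.inf):
            best[pair] = d
        scope_side.setdefault(pair, "b" if swapped else "a")
    return [ContactEvent(frame=frame, a=a, b=b, min_distance=best[(a, b)])
            for a, b in sorted(best, key=lambda p: (p[0].sort_key(), p[1].sort_key()))]


def occupancy_table(traj: TrajectoryEnsemble, *, frame_window: int | None = None,
                    cutoff: float = DEFAULT_CUTOFF,
                    scope: ResidueRegion | None = None,
                    partner_scope: ResidueRegion | None = None,
                    min_sequence_separation: int = MIN_SEQUENCE_SEPARATION,
                    exclude_scope_scope_same_subunit: bool = True,
                    system: str = "") -> list[OccupancyRecord]:
    """Per-residue-pair occupancy over the last ``frame_window`` frames.

    Occupancy is the number of frames in which the pair shows at least one
    qualifying heavy-atom contact, divided by the window size.  Locality is
    'inter' when the two residues sit on different subunits.
    """
    n = traj.n_frames if frame_window is None else int(frame_window)
    if n < 1 or n > traj.n_frames:
        raise ValueError(f"frame_window={frame_window} outside 1..{traj.n_frames}")
    start = traj.n_frames - n
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    sides: dict[tuple[ResidueKey, ResidueKey], str] = {}
    for f in range(start, traj.n_frames):
        events = frame_contacts(
            traj.topology, coords=traj.frames[f], cutoff=cutoff, scope=scope,
            partner_scope=partner_scope,
            min_sequence_separation=min_sequence_separation,
            exclude_scope_scope_same_subunit=exclude_scope_scope_same_subunit,
            frame=f)
        for ev in events:
            pair = (ev.a, ev.b)
            counts[pair] = counts.get(pair, 0) + 1
            if pair not in sides:
                side = "a"
                if scope is not None and ev.a.number not in scope and ev.b.number in scope:
                    side = "b"
                sides[pair] = side
    records = []
    for (a, b), c in sorted(counts.items(),
                            key=lambda kv: (kv[0][0].sort_key(), kv[0][1].sort_key())):
        records.append(OccupancyRecord(
            a=a, b=b, occupancy=c / n, n_frames=n,
            locality="inter" if a.subunit != b.subunit else "intra",
            system=system, source_side=sides[(a, b)]))
    return records


def filter_high_occupancy(records: Iterable[OccupancyRecord],
                          threshold: float = HIGH_OCCUPANCY_THRESHOLD
                          ) -> list[OccupancyRecord]:
    """Keep records at or above the occupancy threshold (>= 30% by default)."""
    return [r for r in records if r.occupancy >= threshold]


def records_to_frame(records: Iterable[OccupancyRecord]) -> pd.DataFrame:
    rows = [(r.system, r.a.subunit, r.a.number, r.a.name,
             r.b.subunit, r.b.number, r.b.name,
             r.occupancy, r.n_frames, r.locality, r.source_side)
            for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[OccupancyRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(OccupancyRecord(
            a=ResidueKey(int(row.subunit_a), int(row.res_a), str(row.name_a)),
            b=ResidueKey(int(row.subunit_b), int(row.res_b), str(row.name_b)),
            occupancy=float(row.occupancy), n_frames=int(row.n_frames),
            locality=str(row.locality), system=str(row.system),
            source_side=str(row.source_side)))
    return out


# --------------------------------------------------------------------------
# Count summaries (per-residue interaction tallies, pooled across systems)

VALID_MODES = ("source-residue", "partner-residue", "interface")
VALID_GROUPINGS = ("closed-pool", "open-pool", "mutant-pool")

#: Standard pool membership for the eight-system study design.
DEFAULT_POOLS = {
    "closed-pool": ("4C", "1C3O", "1C3O-HID"),
    "open-pool": ("4O", "1C3O-open-S4S5L", "1C3O-open-S4S5L-HID"),
    "mutant-pool": ("1C3O-H4762P", "1C3O-open-S4S5L-H4762P"),
}


@dataclass
class CountSummary:
    """Per-residue interaction counts for one pool of systems."""

    counts: dict[int, int]
    grouping: str
    mode: str
    systems: tuple[str, ...] = ()

    def count(self, residue: int) -> int:
        return self.counts.get(residue, 0)


def summarize_counts(record_sets: Sequence[tuple[str, Iterable[OccupancyRecord]]],
                     grouping: str, mode: str, *, min_appearances: int = 0,
                     pools: dict[str, tuple[str, ...]] | None = None,
                     companion_summaries: Sequence[CountSummary] = ()
                     ) -> CountSummary:
    """Tally high-occupancy interactions per residue across pooled systems.

    ``mode`` decides which residue of each record is credited:
    'source-residue' increments the scope-side residue; 'partner-residue'
    the other side; 'interface' keeps only inter-subunit records and
    increments both residues.  All ``record_sets`` must belong to the stated
    ``grouping`` pool — mixing pools in one call is a hard error.

    ``min_appearances`` drops residues whose count fails the bound in this
    summary *and* in every ``companion_summaries`` entry (the "appear at
    least three times in either the closed or the open systems" rule).
    Records are expected pre-filtered to high occupancy.
    """
    if mode not in VALID_MODES:
        raise ValueError(f"mode must be one of {VALID_MODES}")
    if grouping not in VALID_GROUPINGS:
        raise ValueError(f"grouping must be one of {VALID_GROUPINGS}")
    pool_map = DEFAULT_POOLS if pools is None else pools
    allowed = set(pool_map.get(grouping, ()))
    counts: dict[int, int] = {}
    systems = []
    for system, records in record_sets:
        if allowed and system not in allowed:
            raise ValueError(
                f"system {system!r} does not belong to {grouping}; "
                "mixed groupings in one call are not allowed")
        systems.append(system)
        for r in records:
            if mode == "interface":
                if r.locality != "inter":
                    continue
                for res in (r.a.number, r.b.number):
                    counts[res] = counts.get(res, 0) + 1
            elif mode == "source-residue":
                counts[r.source_residue] = counts.get(r.source_residue, 0) + 1
            else:
                counts[r.partner_residue] = counts.get(r.partner_residue, 0) + 1
    if min_appearances > 0:
        keep = set()
        for res in set(counts):
            if counts[res] >= min_appearances or any(
                    c.count(res) >= min_appearances for c in companion_summaries):
                keep.add(res)
        for c in companion_summaries:
            for res, v in c.counts.items():
                if v >= min_appearances:
                    keep.add(res)
        counts = {res: v for res, v in counts.items() if res in keep}
    return CountSummary(counts=counts, grouping=grouping, mode=mode,
                        systems=tuple(systems))


def compare_summaries(summaries: Sequence[CountSummary],
                      min_appearances: int = 0) -> pd.DataFrame:
    """Side-by-side residue counts across pools.

    A residue row is retained when its count reaches ``min_appearances`` in
    at least one pool (with 3, the published interface-figure filter).
    """
    residues = sorted({r for s in summaries for r in s.counts})
    if min_appearances > 0:
        residues = [r for r in residues
                    if any(s.count(r) >= min_appearances for s in summaries)]
    data = {s.grouping: [s.count(r) for r in residues] for s in summaries}
    return pd.DataFrame(data, index=pd.Index(residues, name="residue"))


def interface_sites(records: Iterable[OccupancyRecord]) -> set[int]:
    """Union of both partner residue numbers of inter-subunit records."""
    out: set[int] = set()
    for r in records:
        if r.locality == "inter":
            out.add(r.a.number)
            out.add(r.b.number)
    return out
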