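"""Synthetic tetramer channels, trajectories and mutation catalogues.

The generators build toy four-fold-symmetric channels with analytically
known ground truth so every stage of the analysis stack — pore profiling,
state calling, superposition, occupancy statistics, proximity fractions —
can be validated without any external structure files.

Geometry: each subunit is a stack of residue "rings" occupying one
90-degree sector around the z axis; atoms sit on each ring at a uniform
arc spacing (cell-centred within the sector, so seam gaps between subunits
equal the in-arc spacing and no inter-residue pair comes closer than the
spacing target).  One residue per subunit is the gate residue, whose ring
is pulled in to ``gate_center_radius``; since the centre of a complete ring
is a local maximum of the inscribed-probe radius, the pore radius at the
gate is ``gate_center_radius - vdw`` regardless of ring density, while the
van der Waals spheres seal the inter-atom gaps.  Defaults mimic
the closed-state channel: gate atom centres at 2.44 Å with carbon vdW 1.70 Å
give the 0.74 Å gate radius of the closed cluster; the open preset uses
5.10 Å centres for a 3.4 Å gate.

The generated structures are geometric pseudo-helices, not chemically valid
polypeptides: the analysis stack consumes only coordinates, elements and
numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .proximity import MutationCatalogue
from .structure_io import StructureModel
from .trajstats import TrajectoryEnsemble

ResiduePair = tuple[tuple[int, int], tuple[int, int]]  # ((subunit, res), (subunit, res))


@dataclass(frozen=True)
class ChannelSpec:
    """Parameters of a toy C4-symmetric channel."""

    n_residues_per_subunit: int = 25
    gate_center_radius: float = 2.44   # Å from axis to gate atom centres
    lumen_center_radius: float = 8.0   # Å from axis to wall atom centres
    gate_residue_number: int = 4867
    atom_vdw: float = 1.70             # Å; matches carbon in the Bondi table
    axial_span: float = 24.0           # Å covered by the residue stack
    state_tag: str = "closed"
    seed: int = 0
    gate_z: float = 12.0               # axial position of the gate ring
    atom_spacing: float = 1.3          # target arc spacing between atoms, Å
    twist_per_ring: float = 4.5        # degrees of helical twist per residue

    def __post_init__(self) -> None:
        if self.gate_center_radius <= 0 or self.lumen_center_radius <= 0:
            raise ValueError("ring radii must be positive")
        if self.gate_center_radius > self.lumen_center_radius:
            raise ValueError("gate radius must not exceed lumen radius")
        if self.n_residues_per_subunit < 3:
            raise ValueError("need at least 3 residues per subunit")

    @property
    def expected_gate_radius(self) -> float:
        """Analytic pore radius at the gate ring."""
        return self.gate_center_radius - self.atom_vdw

    @property
    def expected_lumen_radius(self) -> float:
        return self.lumen_center_radius - self.atom_vdw


#: Preset mimicking the closed-state gate-radius cluster (~0.74 Å).
CLOSED_SPEC = ChannelSpec(state_tag="closed", gate_center_radius=2.44)
#: Preset mimicking the open-state gate-radius cluster (~3.4 Å).
OPEN_SPEC = ChannelSpec(state_tag="open", gate_center_radius=5.10)


def make_tetramer(spec: ChannelSpec, label: str | None = None) -> StructureModel:
    """Build a four-subunit channel with a gate ring of known radius.

    Residues are numbered consecutively with the gate residue at the centre
    of the stack; atoms are carbon ("C1".."Cn" names, non-backbone, so the
    gate ring counts as sidechain for gate location).  Output is exactly
    reproducible from the spec (the construction is deterministic).
    """
    n = spec.n_residues_per_subunit
    gate_idx = n // 2
    first_residue = spec.gate_residue_number - gate_idx
    dz = spec.axial_span / (n - 1)
    z_first = spec.gate_z - gate_idx * dz

    serial, names, elements, resnums, resnames, subunits, coords = \
        [], [], [], [], [], [], []
    serial_counter = 1
    for su in range(1, 5):
        sector0 = (su - 1) * 90.0
        for i in range(n):
            resnum = first_residue + i
            radius = (spec.gate_center_radius if resnum == spec.gate_residue_number
                      else spec.lumen_center_radius)
            z = z_first + i * dz
            # cell-centred arc: the seam gap between subunits equals the
            # in-arc spacing, so the full ring is uniform and every
            # inter-atom distance stays above the target spacing
            arc_len = 2.0 * np.pi * radius / 4.0
            n_arc = max(3, int(np.ceil(arc_len / spec.atom_spacing)))
            step_deg = 90.0 / n_arc
            twist = (spec.twist_per_ring * i) % step_deg
            for k in range(n_arc):
                theta = np.deg2rad(sector0 + (k + 0.5) * step_deg + twist)
                coords.append((radius * np.cos(theta), radius * np.sin(theta), z))
                serial.append(serial_counter)
                serial_counter += 1
                names.append(f"C{k + 1}")
                elements.append("C")
                resnums.append(resnum)
                resnames.append("GAT" if resnum == spec.gate_residue_number else "SYN")
                subunits.append(su)

    return StructureModel.from_arrays(
        serial=serial, name=names, element=elements, residue_number=resnums,
        residue_name=resnames, subunit=subunits, coords=np.array(coords),
        label=label or f"toy-{spec.state_tag}", state_tag=spec.state_tag,
        numbering_scheme="canonical")


@dataclass(frozen=True)
class ContactSchedule:
    """One engineered residue-pair contact with a Bernoulli appearance rate."""

    pair: ResiduePair
    p: float
    contact_distance: float = 2.8
    apart_distance: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("occupancy probability must be in [0, 1]")
        if self.contact_distance >= self.apart_distance:
            raise ValueError("contact distance must be below apart distance")


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int = 100
    jitter_sigma: float = 0.1          # Å, i.i.d. Gaussian per coordinate
    contact_schedule: tuple[ContactSchedule, ...] = ()
    seed: int = 0


def make_trajectory(model: StructureModel, spec: TrajectorySpec
                    ) -> TrajectoryEnsemble:
    """Jittered frames of a model with engineered Bernoulli contacts.

    Frame f is the model plus i.i.d. Gaussian coordinate noise.  For every
    scheduled pair, a designated atom of the second residue is placed at the
    contact distance from a designated atom of the first residue in a
    Bernoulli(p) subset of frames, and at the apart distance otherwise, so
    the pair's occupancy over many frames concentrates at p.  The same atom
    may not appear in two schedules.
    """
    rng = np.random.default_rng(spec.seed)
    designated: list[tuple[int, int, ContactSchedule]] = []
    used: set[int] = set()
    for sched in spec.contact_schedule:
        (su_a, res_a), (su_b, res_b) = sched.pair
        ia = _first_atom(model, su_a, res_a)
        ib = _first_atom(model, su_b, res_b)
        for idx in (ia, ib):
            if idx in used:
                raise ValueError(
                    f"atom {idx} appears in two contact schedules")
            used.add(idx)
        designated.append((ia, ib, sched))

    frames = np.empty((spec.n_frames, model.n_atoms, 3))
    for f in range(spec.n_frames):
        frame = model.coords.copy()
        if spec.jitter_sigma > 0:
            frame += rng.normal(0.0, spec.jitter_sigma, frame.shape)
        for ia, ib, sched in designated:
            d = (sched.contact_distance if rng.random() < sched.p
                 else sched.apart_distance)
            direction = model.coords[ib] - model.coords[ia]
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                direction, norm = np.array([1.0, 0.0, 0.0]), 1.0
            frame[ib] = frame[ia] + direction / norm * d
        frames[f] = frame
    return TrajectoryEnsemble(topology=model, frames=frames)


def _first_atom(model: StructureModel, subunit: int, resnum: int) -> int:
    hits = np.flatnonzero((model.subunit == subunit)
                          & (model.residue_number == resnum))
    if len(hits) == 0:
        raise ValueError(f"scheduled residue {resnum} (subunit {subunit}) "
                         "not present in the model")
    return int(hits[0])


def make_catalogue(sites: Sequence[int], hits: int, misses: int, k: int,
                   seed: int = 0, *, hit_distances: Sequence[int] | None = None,
                   number_range: tuple[int, int] | None = None
                   ) -> MutationCatalogue:
    """Catalogue with a known within-k fraction hits/(hits+misses).

    Exactly ``hits`` entries are placed within ``k`` residues of some site
    and ``misses`` entries strictly beyond ``k`` of every site.
    ``hit_distances`` pins the intended nearest-site distance of each hit
    (length must equal ``hits``); placements whose realised nearest-site
    distance differs from the intent are rejected and retried at another
    site, so mixed criteria (e.g. 32 entries within 3 *and* 36 within 5 out
    of 49) can be constructed exactly.
    """
    site_list = sorted(set(int(s) for s in sites))
    if not site_list:
        raise ValueError("sites must be non-empty")
    if hit_distances is not None and len(hit_distances) != hits:
        raise ValueError("hit_distances must have one entry per hit")
    rng = np.random.default_rng(seed)
    lo, hi = number_range or (max(1, min(site_list) - 400), max(site_list) + 400)

    def nearest(res: int) -> int:
        return min(abs(res - s) for s in site_list)

    chosen: set[int] = set()
    entries: list[tuple[int, str]] = []
    def try_place(want: int) -> bool:
        for si in rng.permutation(len(site_list)):
            for sign in (1, -1):
                res = site_list[si] + sign * want
                if res < lo or res > hi or res in chosen:
                    continue
                if nearest(res) != want:
                    continue
                chosen.add(res)
                entries.append((res, f"hit-d{want}"))
                return True
        return False

    for h in range(hits):
        if hit_distances is not None:
            want = int(hit_distances[h])
            if not try_place(want):
                raise ValueError(
                    f"could not place a hit at distance {want} from any site")
        else:
            # preferred random distance, falling back to any feasible one
            preferred = int(rng.integers(0, k + 1))
            candidates = [preferred] + [d for d in rng.permutation(k + 1)
                                        if d != preferred]
            if not any(try_place(int(d)) for d in candidates):
                raise ValueError(
                    f"could not place hit {h + 1}/{hits} within {k} of any site")
    candidates = [r for r in range(lo, hi + 1)
                  if nearest(r) > k and r not in chosen]
    if len(candidates) < misses:
        raise ValueError(
            f"only {len(candidates)} positions beyond distance {k} available "
            f"for {misses} misses")
    for res in rng.choice(candidates, size=misses, replace=False):
        entries.append((int(res), "miss"))
    return MutationCatalogue(entries, provenance=f"synthetic(seed={seed})")
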