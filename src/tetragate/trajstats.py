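"""Trajectory bookkeeping: RMSD time series, window-averaged structures,
and best-aligned-chain-pair substructure RMSD between systems.

A trajectory is an ordered stack of coordinate frames sharing one topology
(typically 1000 equally spaced snapshots at 1 frame/ns).  Equilibrated
single-structure analyses use the average over the last 100 frames after a
rigid fit of every frame to the first retained frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .chimera import _kabsch, superpose
from .regions import ResidueRegion
from .structure_io import StructureModel, extract_regions


@dataclass
class TrajectoryEnsemble:
    """Frames over a fixed topology; ``frames`` has shape (n_frames, n_atoms, 3)."""

    topology: StructureModel
    frames: np.ndarray
    frame_spacing: float = 1.0  # nominal time per frame (ns)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])


def _selection_mask(topology: StructureModel,
                    atom_selection: Iterable[str] | None) -> np.ndarray:
    if atom_selection is None:
        return np.ones(topology.n_atoms, dtype=bool)
    sel = set(atom_selection)
    mask = np.array([nm in sel for nm in topology.name], dtype=bool)
    if not mask.any():
        raise ValueError(f"atom selection {sorted(sel)} matches no atoms")
    return mask


def _fit_onto(mob: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigid-fit coordinates mob onto ref (same atom order); return fitted mob."""
    res = _kabsch(mob, ref)
    return res.apply(mob)


def rmsd_timeseries(traj: TrajectoryEnsemble,
                    atom_selection: Iterable[str] | None = ("CA",)
                    ) -> np.ndarray:
    """Per-frame RMSD versus the first frame, after rigid fitting.

    Each frame is least-squares fitted to frame 1 over the selection, and
    the RMSD is evaluated over the same selection; entry 0 is exactly 0.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSD time series needs at least two frames")
    mask = _selection_mask(traj.topology, atom_selection)
    ref = traj.frames[0][mask]
    out = np.empty(traj.n_frames)
    out[0] = 0.0
    for i in range(1, traj.n_frames):
        fitted = _fit_onto(traj.frames[i][mask], ref)
        out[i] = np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean())
    return out


def average_structure(traj: TrajectoryEnsemble, last_n: int) -> StructureModel:
    """Mean structure of the final ``last_n`` frames after rigid fitting.

    Every retained frame is fitted (all atoms) to the first retained frame
    to remove global translation and rotation, then coordinates are averaged
    arithmetically.  Flexible regions may look distorted in the average;
    that is accepted — the average serves well-ordered elements.
    """
    if last_n < 1:
        raise ValueError("last_n must be >= 1")
    if last_n > traj.n_frames:
        raise ValueError(f"last_n={last_n} exceeds frame count {traj.n_frames}")
    window = traj.frames[traj.n_frames - last_n:]
    ref = window[0]
    acc = ref.copy()
    for frame in window[1:]:
        acc += _fit_onto(frame, ref)
    out = traj.topology.with_coords(acc / last_n)
    out.label = f"{traj.topology.label}|avg-last{last_n}"
    return out


def substructure_rmsd(model: StructureModel, reference: StructureModel,
                      region: ResidueRegion, *,
                      atom_selection: Iterable[str] | None = ("CA",)
                      ) -> float:
    """Four-subunit RMSD of a residue region under the best-aligned-pair rule.

    The region is extracted from all four subunits of both models.  For each
    of the 4x4 (model subunit, reference subunit) pairings, that pair is
    superposed and the whole four-subunit RMSD evaluated under the resulting
    transform, with the remaining subunits corresponded by the same cyclic
    offset (the tetramer's four-fold arrangement); the minimum over the 16
    pairings is returned.  All four subunits enter every comparison because
    the gate geometry is defined only by the assembled tetramer.
    """
    sub_m = _region_subunits(model, region, atom_selection)
    sub_r = _region_subunits(reference, region, atom_selection)
    sus_m, sus_r = sorted(sub_m), sorted(sub_r)
    if len(sus_m) != 4 or len(sus_r) != 4:
        raise ValueError("substructure RMSD requires the region on all four "
                         "subunits of both models")
    best = np.inf
    for i in sus_m:
        for j in sus_r:
            pair_m, pair_r = _pair_by_key(sub_m[i], sub_r[j])
            if len(pair_m) < 3:
                continue
            fit = _kabsch(pair_m, pair_r)
            # full four-subunit correspondence under the cyclic offset i -> j
            tot_m, tot_r = [], []
            for s in sus_m:
                t = sus_r[(sus_m.index(s) + sus_r.index(j) - sus_m.index(i)) % 4]
                cm, cr = _pair_by_key(sub_m[s], sub_r[t])
                tot_m.append(cm)
                tot_r.append(cr)
            M = fit.apply(np.vstack(tot_m))
            R = np.vstack(tot_r)
            rmsd = float(np.sqrt(((M - R) ** 2).sum(axis=1).mean()))
            best = min(best, rmsd)
    if not np.isfinite(best):
        raise ValueError("no subunit pairing had >=3 shared atoms in the region")
    return best


def _region_subunits(model: StructureModel, region: ResidueRegion,
                     atom_selection: Iterable[str] | None):
    ext = extract_regions(model, region)
    mask = _selection_mask(ext, atom_selection)
    ext = ext.select(mask)
    return {su: ext.subunit_model(su) for su in ext.subunits}


def _pair_by_key(a: StructureModel, b: StructureModel
                 ) -> tuple[np.ndarray, np.ndarray]:
    ka = {(int(a.residue_number[i]), str(a.name[i])): i for i in range(a.n_atoms)}
    kb = {(int(b.residue_number[i]), str(b.name[i])): i for i in range(b.n_atoms)}
    keys = sorted(ka.keys() & kb.keys())
    return a.coords[[ka[k] for k in keys]], b.coords[[kb[k] for k in keys]]
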