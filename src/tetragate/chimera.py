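"""Chimera tetramer construction by rigid-body superposition and substitution.

A chimera system mixes subunits (or residue segments such as the S4-S5
linker) from a closed-state and an open-state tetramer: the donor subunit is
least-squares superposed onto the acceptor subunit it will replace, then the
in-scope atoms are excised from the acceptor and the transformed donor atoms
spliced in.  Splices are left geometrically unregularised — downstream
relaxation is assumed — so :func:`clash_check` and junction bond lengths are
the quality gates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .regions import ResidueRegion
from .structure_io import StructureModel

DEFAULT_ATOM_SELECTION = frozenset({"CA"})


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping mobile onto reference: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ChimeraRecipe:
    acceptor: StructureModel
    donor: StructureModel
    target_subunit: int
    scope: ResidueRegion | None = None  # None = whole subunit
    mutation_label: str = ""  # bookkeeping only; no atoms are built


def _paired_coords(mobile: StructureModel, reference: StructureModel,
                   atom_selection: Iterable[str] | None) -> tuple[np.ndarray, np.ndarray]:
    """Match atoms by (residue_number, atom name) over the intersection."""
    sel = set(atom_selection) if atom_selection is not None else None

    def index(m: StructureModel) -> dict[tuple[int, str], int]:
        out = {}
        for i in range(m.n_atoms):
            nm = str(m.name[i])
            if sel is not None and nm not in sel:
                continue
            out[(int(m.residue_number[i]), nm)] = i
        return out

    im, ir = index(mobile), index(reference)
    keys = sorted(im.keys() & ir.keys())
    if len(keys) < 3:
        raise ValueError(
            f"superposition needs >=3 paired atoms, found {len(keys)}")
    mob = mobile.coords[[im[k] for k in keys]]
    ref = reference.coords[[ir[k] for k in keys]]
    return mob, ref


def _kabsch(mob: np.ndarray, ref: np.ndarray) -> SuperpositionResult:
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(len(mob)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_matched=len(mob))


def superpose(mobile: StructureModel, reference: StructureModel, *,
              atom_selection: Iterable[str] | None = DEFAULT_ATOM_SELECTION,
              prune: bool = False, prune_sd: float = 2.0,
              max_prune_cycles: int = 5) -> SuperpositionResult:
    """Least-squares rigid fit (Kabsch) of one subunit onto another.

    Atoms are paired by canonical residue number and atom name over the
    intersection of the two models; the default selection is alpha-carbons.
    The mobile model is not mutated — the transform is returned.

    With ``prune=True``, pairs deviating more than ``prune_sd`` standard
    deviations above the mean post-fit deviation are dropped and the fit
    repeated (at most ``max_prune_cycles`` times).  This mimics aligners
    that iteratively discard far pairs and generally reports a lower RMSD
    over fewer atoms.
    """
    mob, ref = _paired_coords(mobile, reference, atom_selection)
    result = _kabsch(mob, ref)
    if not prune:
        return result
    for _ in range(max_prune_cycles):
        dev = np.linalg.norm(result.apply(mob) - ref, axis=1)
        keep = dev <= dev.mean() + prune_sd * dev.std()
        if keep.all() or keep.sum() < 3:
            break
        mob, ref = mob[keep], ref[keep]
        result = _kabsch(mob, ref)
    return result


def substitute(recipe: ChimeraRecipe, *,
               atom_selection: Iterable[str] | None = DEFAULT_ATOM_SELECTION) -> StructureModel:
    """Replace the scope of the acceptor's target subunit with donor atoms.

    The donor target subunit is first superposed (whole-subunit) onto the
    acceptor target subunit; the transformed donor atoms inside the scope
    then replace the acceptor's.  Atoms outside the scope are bit-identical
    to the acceptor.  Serials are renumbered in the output.
    """
    acc, don, su = recipe.acceptor, recipe.donor, recipe.target_subunit
    if su not in acc.subunits or su not in don.subunits:
        raise ValueError(f"target subunit {su} absent from acceptor or donor")
    acc_su = acc.subunit_model(su)
    don_su = don.subunit_model(su)
    fit = superpose(don_su, acc_su, atom_selection=atom_selection)

    if recipe.scope is None:
        scope_mask_acc = np.ones(acc_su.n_atoms, dtype=bool)
        scope_mask_don = np.ones(don_su.n_atoms, dtype=bool)
    else:
        scope_mask_acc = recipe.scope.mask(acc_su.residue_number)
        scope_mask_don = recipe.scope.mask(don_su.residue_number)
        missing = sorted(set(recipe.scope.residues())
                         & set(acc_su.residue_number.tolist())
                         - set(don_su.residue_number.tolist()))
        if missing:
            raise ValueError(
                f"scope residues absent from donor subunit {su}: {missing}")
        if not scope_mask_don.any():
            raise ValueError(f"scope {recipe.scope.name!r} selects no donor atoms")

    keep_acc = acc.copy()
    drop = (acc.subunit == su) & (
        np.ones(acc.n_atoms, dtype=bool) if recipe.scope is None
        else recipe.scope.mask(acc.residue_number))
    kept = keep_acc.select(~drop)

    incoming = don_su.select(scope_mask_don)
    incoming = incoming.with_coords(fit.apply(incoming.coords))

    out = StructureModel.from_arrays(
        serial=np.concatenate([kept.serial, incoming.serial + kept.serial.max()]),
        name=np.concatenate([kept.name, incoming.name]),
        element=np.concatenate([kept.element, incoming.element]),
        residue_number=np.concatenate([kept.residue_number, incoming.residue_number]),
        residue_name=np.concatenate([kept.residue_name, incoming.residue_name]),
        subunit=np.concatenate([kept.subunit, incoming.subunit]),
        coords=np.vstack([kept.coords, incoming.coords]),
        label=f"{acc.label}+{don.label}@su{su}"
              + (f"[{recipe.scope.name}]" if recipe.scope else ""),
        state_tag="unknown",
        numbering_scheme=acc.numbering_scheme,
    )
    return out.renumber_serials()


def clash_check(model: StructureModel, min_separation: float = 1.0
                ) -> list[tuple[int, int, float]]:
    """All heavy-atom pairs from different residues closer than the cutoff.

    Returns ``(atom_index_a, atom_index_b, distance)`` triples; an empty
    list means the splice produced no unphysical contacts.
    """
    heavy = np.flatnonzero(model.heavy_mask())
    coords = model.coords[heavy]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(min_separation, output_type="ndarray")
    out = []
    for i, j in pairs:
        ai, aj = int(heavy[i]), int(heavy[j])
        same_res = (model.subunit[ai] == model.subunit[aj]
                    and model.residue_number[ai] == model.residue_number[aj])
        if same_res:
            continue
        d = float(np.linalg.norm(model.coords[ai] - model.coords[aj]))
        if d < min_separation:  # strictly closer than the cutoff
            out.append((ai, aj, d))
    return sorted(out)


def junction_bond_lengths(model: StructureModel, scope: ResidueRegion,
                          subunit: int) -> dict[str, float]:
    """Backbone C-N distances across the splice boundaries of a segment swap."""
    out: dict[str, float] = {}
    for a, b in scope.intervals:
        for res_out, res_in, tag in ((a - 1, a, f"{a - 1}-{a}"),
                                     (b, b + 1, f"{b}-{b + 1}")):
            ci = _atom_index(model, subunit, res_out, "C")
            ni = _atom_index(model, subunit, res_in, "N")
            if ci is None or ni is None:
                continue
            out[tag] = float(np.linalg.norm(model.coords[ci] - model.coords[ni]))
    return out


def _atom_index(model: StructureModel, subunit: int, resnum: int,
                name: str) -> int | None:
    hits = np.flatnonzero((model.subunit == subunit)
                          & (model.residue_number == resnum)
                          & (model.name == name))
    return int(hits[0]) if len(hits) else None
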