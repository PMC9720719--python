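"""Sequence proximity of disease mutations to interface interaction sites.

Given a catalogue of disease-associated residue positions (e.g. CPVT1
mutations) and the set of residues participating in high-occupancy
inter-subunit interactions, this module scores each mutation by its sequence
distance (|Δresidue number|) to the nearest site and reports the fraction of
mutations within k residues of a site.  Distance is purely one-dimensional
sequence distance: the criterion under test is "within k residues", not
spatial adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .regions import ResidueRegion


@dataclass
class MutationCatalogue:
    """Disease-mutation positions; duplicates collapse with merged labels."""

    entries: list[tuple[int, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        merged: dict[int, list[str]] = {}
        for res, label in self.entries:
            res = int(res)
            if res <= 0:
                raise ValueError(f"residue numbers must be positive, got {res}")
            merged.setdefault(res, [])
            if label and label not in merged[res]:
                merged[res].append(label)
        self.entries = [(res, ";".join(labels)) for res, labels in
                        sorted(merged.items())]

    @property
    def residues(self) -> list[int]:
        return [res for res, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, text: str, provenance: str = "") -> "MutationCatalogue":
        entries = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            entries.append((int(parts[0]), parts[1] if len(parts) > 1 else ""))
        return cls(entries, provenance=provenance)

    def to_tsv(self) -> str:
        return "".join(f"{res}\t{label}\n" for res, label in self.entries)


@dataclass
class ProximityResult:
    """Per-mutation nearest-site distances and within-k fractions."""

    distances: dict[int, int]          # residue -> nearest-site distance
    fraction_within: dict[int, float]  # k -> fraction of entries at distance <= k
    n_in_model: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": list(self.distances),
             "nearest_site_distance": list(self.distances.values())})


def restrict_to_model(catalogue: MutationCatalogue,
                      model_regions: ResidueRegion) -> MutationCatalogue:
    """Keep catalogue entries that fall inside the modeled residue ranges."""
    if len(catalogue) == 0:
        raise ValueError("empty mutation catalogue")
    kept = [(res, label) for res, label in catalogue.entries
            if res in model_regions]
    return MutationCatalogue(kept, provenance=catalogue.provenance
                             + f" | restricted to {model_regions.name}")


def proximity_fractions(catalogue: MutationCatalogue, sites: Iterable[int],
                        ks: Sequence[int] = (3, 5)) -> ProximityResult:
    """Nearest-site sequence distances and the within-k fractions.

    ``fraction_within[k]`` is the share of catalogue entries whose distance
    to the nearest site is <= k (inclusive); it is nondecreasing in k.  Each
    mutation counts once however many sites are nearby.
    """
    site_list = sorted(set(int(s) for s in sites))
    if not site_list:
        raise ValueError("sites must be non-empty")
    distances = {res: min(abs(res - s) for s in site_list)
                 for res in catalogue.residues}
    n = len(distances)
    fw = {int(k): (sum(1 for d in distances.values() if d <= k) / n if n else 0.0)
          for k in ks}
    return ProximityResult(distances=distances, fraction_within=fw, n_in_model=n)


def annotate_missing_adjacent(catalogue: MutationCatalogue,
                              model_regions: ResidueRegion,
                              window: int = 5) -> dict[int, bool]:
    """Flag entries within ``window`` residues of a model gap boundary.

    A gap is a run of residues missing between two modeled intervals; its
    boundary residues are the first and last missing positions.  A mutation
    that sits close in sequence to such a gap may be undercounted by the
    proximity analysis (its true neighbours are absent from the model); the
    flag marks those entries.  ``window=0`` flags only the exact gap
    boundary residues themselves.
    """
    gap_bounds: list[int] = []
    ivs = model_regions.intervals
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        gap_bounds.extend((b1 + 1, a2 - 1))
    out = {}
    for res in catalogue.residues:
        out[res] = any(abs(res - g) <= window for g in gap_bounds)
    return out
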