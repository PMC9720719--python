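"""Named residue regions as unions of closed integer intervals.

Residue regions are the selection currency of the whole package: structural
elements (S4-S5 linker, S6 helix, U-motif), the modeled residue ranges of a
channel construct, and the gaps left by disordered segments are all expressed
as :class:`ResidueRegion` objects in canonical residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

Interval = tuple[int, int]


def _normalize(intervals: Iterable[Sequence[int]]) -> tuple[Interval, ...]:
    """Sort and merge overlapping/adjacent closed intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if a > b:
            raise ValueError(f"invalid interval [{a}, {b}]: start exceeds end")
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class ResidueRegion:
    """A named set of canonical residue numbers, stored as merged intervals."""

    name: str
    intervals: tuple[Interval, ...]

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[Sequence[int]]) -> "ResidueRegion":
        return cls(name, _normalize(intervals))

    @classmethod
    def single(cls, name: str, start: int, end: int) -> "ResidueRegion":
        return cls.from_intervals(name, [(start, end)])

    def __contains__(self, residue_number: int) -> bool:
        return any(a <= residue_number <= b for a, b in self.intervals)

    def __iter__(self) -> Iterator[int]:
        for a, b in self.intervals:
            yield from range(a, b + 1)

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)

    def residues(self) -> set[int]:
        return set(self)

    def mask(self, residue_numbers: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an array of residue numbers."""
        out = np.zeros(len(residue_numbers), dtype=bool)
        for a, b in self.intervals:
            out |= (residue_numbers >= a) & (residue_numbers <= b)
        return out

    def union(self, other: "ResidueRegion", name: str | None = None) -> "ResidueRegion":
        return ResidueRegion.from_intervals(
            name or f"{self.name}|{other.name}", self.intervals + other.intervals
        )

    def difference(self, other: "ResidueRegion", name: str | None = None) -> "ResidueRegion":
        kept = sorted(self.residues() - other.residues())
        return ResidueRegion.from_intervals(name or f"{self.name}-{other.name}", _runs(kept))

    def intersection(self, other: "ResidueRegion", name: str | None = None) -> "ResidueRegion":
        kept = sorted(self.residues() & other.residues())
        return ResidueRegion.from_intervals(name or f"{self.name}&{other.name}", _runs(kept))

    def boundaries(self) -> list[int]:
        """All interval endpoints — the residues that border a region edge."""
        return [x for a, b in self.intervals for x in (a, b)]


def _runs(sorted_values: Sequence[int]) -> list[Interval]:
    runs: list[list[int]] = []
    for v in sorted_values:
        if runs and v == runs[-1][1] + 1:
            runs[-1][1] = v
        else:
            runs.append([v, v])
    return [(a, b) for a, b in runs]


def load_regions(yaml_text: str) -> dict[str, ResidueRegion]:
    """Parse a regions config: ``{name: [[start, end], ...]}``."""
    raw = yaml.safe_load(yaml_text)
    if not isinstance(raw, dict):
        raise ValueError("regions config must be a mapping of name -> interval list")
    return {name: ResidueRegion.from_intervals(name, ivs) for name, ivs in raw.items()}


# --- Canonical RyR2 regions (human isoform-1 numbering) -------------------

#: U-motif of the cytosolic central domain.
U_MOTIF = ResidueRegion.single("U-motif", 4167, 4184)
#: S4-S5 linker, the helix-loop element whose conformation gates the channel.
S4S5L = ResidueRegion.single("S4S5L", 4746, 4766)
#: 51-residue window around the S4-S5 linker.
S4S5L_WIDE = ResidueRegion.single("S4S5L-wide", 4731, 4781)
#: Pore-lining S6 helix carrying the hydrophobic gate residue I4867.
S6_HELIX = ResidueRegion.single("S6", 4839, 4889)
#: 11-residue S6 window centred on the hydrophobic gate.
GATE_WINDOW = ResidueRegion.single("gate-window", 4859, 4869)

#: Residue ranges retained in the channel constructs: central-domain
#: portion (with the U-motif) plus the transmembrane/C-terminal block.
MODELED_RANGES = ResidueRegion.from_intervals("modeled", [(4099, 4206), (4485, 4963)])
#: Disordered transmembrane segments absent from the closed-state deposition.
CLOSED_MISSING = ResidueRegion.from_intervals("closed-missing", [(4524, 4556), (4672, 4694)])
#: The open-state deposition additionally lacks residue 4523.
OPEN_MISSING = CLOSED_MISSING.union(ResidueRegion.single("r4523", 4523, 4523), name="open-missing")

#: Per-subunit residue content of the closed- and open-state constructs.
CLOSED_MODEL = MODELED_RANGES.difference(CLOSED_MISSING, name="closed-model")
OPEN_MODEL = MODELED_RANGES.difference(OPEN_MISSING, name="open-model")
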