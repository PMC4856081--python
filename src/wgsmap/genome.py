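"""Genome coordinates, genetic maps, and ancestry-labelled haplotypes.

Physical coordinates are 1-based inclusive base pairs throughout. Genetic
positions are centimorgans measured from the left end of each chromosome.
The cM<->bp conversion is a piecewise-linear (Marey-map style) interpolation
between anchors; the default is a single linear segment per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MapStructureError

__all__ = [
    "ChromosomeMap",
    "GeneticMap",
    "Haplotype",
    "DiploidGenome",
    "splice",
]


@dataclass(frozen=True)
class ChromosomeMap:
    """One chromosome of a genetic map.

    Parameters
    ----------
    name : str
        Chromosome name (e.g. ``"I"`` or ``"chr1"``).
    length_bp : int
        Physical length in base pairs (positions run 1..length_bp).
    length_cm : float
        Genetic length in centimorgans.
    anchors_bp, anchors_cm : array-like, optional
        Strictly increasing anchor coordinates defining the piecewise-linear
        cM<->bp conversion. Defaults to a single linear segment spanning the
        chromosome.
    """

    name: str
    length_bp: int
    length_cm: float
    anchors_bp: np.ndarray = field(default=None)  # type: ignore[assignment]
    anchors_cm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.length_bp <= 0:
            raise MapStructureError(f"{self.name}: physical length must be > 0")
        if self.length_cm <= 0:
            raise MapStructureError(f"{self.name}: genetic length must be > 0")
        abp = self.anchors_bp
        acm = self.anchors_cm
        if abp is None or acm is None:
            abp = np.array([1.0, float(self.length_bp)])
            acm = np.array([0.0, float(self.length_cm)])
        abp = np.asarray(abp, dtype=float)
        acm = np.asarray(acm, dtype=float)
        if abp.shape != acm.shape or abp.ndim != 1 or abp.size < 2:
            raise MapStructureError(f"{self.name}: anchors must be two equal-length 1-d arrays")
        if not (np.all(np.diff(abp) > 0) and np.all(np.diff(acm) > 0)):
            raise MapStructureError(f"{self.name}: anchors must be strictly increasing")
        if abp[0] != 1 or abp[-1] != self.length_bp:
            raise MapStructureError(f"{self.name}: bp anchors must span [1, length_bp]")
        if acm[0] != 0 or acm[-1] != self.length_cm:
            raise MapStructureError(f"{self.name}: cM anchors must span [0, length_cm]")
        object.__setattr__(self, "anchors_bp", abp)
        object.__setattr__(self, "anchors_cm", acm)

    def bp_to_cm(self, bp):
        """Convert physical position(s) to genetic position(s)."""
        return np.interp(bp, self.anchors_bp, self.anchors_cm)

    def cm_to_bp(self, cm):
        """Convert genetic position(s) to physical position(s)."""
        return np.interp(cm, self.anchors_cm, self.anchors_bp)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of :class:`ChromosomeMap` objects."""

    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self):
        chroms = tuple(self.chromosomes)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise MapStructureError("duplicate chromosome names in genetic map")
        object.__setattr__(self, "chromosomes", chroms)

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)

    def __contains__(self, name: str):
        return any(c.name == name for c in self.chromosomes)

    def __getitem__(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def lengths_bp(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    def check_position(self, chromosome: str, position: int) -> None:
        c = self[chromosome]
        if not (1 <= position <= c.length_bp):
            raise MapStructureError(
                f"position {position} outside chromosome {chromosome} (1..{c.length_bp})"
            )

    @classmethod
    def worm_like(cls, n_chromosomes: int = 6, length_cm: float = 50.0,
                  lengths_bp: list[int] | None = None) -> "GeneticMap":
        """A default autosomal genome: 6 chromosomes of 15-21 Mbp, 50 cM each."""
        if lengths_bp is None:
            base = [15_000_000, 15_300_000, 13_800_000, 17_500_000, 20_900_000, 17_700_000]
            lengths_bp = [base[i % len(base)] for i in range(n_chromosomes)]
        names = ["I", "II", "III", "IV", "V", "X"]
        if n_chromosomes > len(names):
            names = [f"chr{i + 1}" for i in range(n_chromosomes)]
        return cls(tuple(
            ChromosomeMap(names[i], lengths_bp[i], length_cm) for i in range(n_chromosomes)
        ))


class Haplotype:
    """A chromosome as an ordered run of ancestry-labelled segments.

    Segments are encoded as ``ends`` (strictly increasing 1-based inclusive
    endpoints, the last equal to the chromosome length) and ``ancestry``
    (one strain label per segment; adjacent labels differ).
    """

    __slots__ = ("chromosome", "ends", "ancestry")

    def __init__(self, chromosome: str, ends, ancestry):
        ends = np.asarray(ends, dtype=np.int64)
        ancestry = tuple(ancestry)
        if ends.size == 0 or ends.size != len(ancestry):
            raise MapStructureError("haplotype needs one ancestry label per segment end")
        if ends.size > 1 and not np.all(np.diff(ends) > 0):
            raise MapStructureError("segment ends must be strictly increasing")
        if any(a == b for a, b in zip(ancestry, ancestry[1:])):
            raise MapStructureError("adjacent segments must differ in ancestry")
        self.chromosome = chromosome
        self.ends = ends
        self.ancestry = ancestry

    @classmethod
    def uniform(cls, chromosome: str, length_bp: int, label: str) -> "Haplotype":
        return cls(chromosome, [length_bp], [label])

    @property
    def length_bp(self) -> int:
        return int(self.ends[-1])

    def ancestry_at(self, position):
        """Strain label(s) at 1-based position(s)."""
        idx = np.searchsorted(self.ends, position, side="left")
        if np.ndim(position) == 0:
            return self.ancestry[int(idx)]
        labels = np.array(self.ancestry, dtype=object)
        return labels[idx]

    def n_breakpoints(self) -> int:
        return len(self.ancestry) - 1

    def __eq__(self, other):
        return (isinstance(other, Haplotype)
                and self.chromosome == other.chromosome
                and np.array_equal(self.ends, other.ends)
                and self.ancestry == other.ancestry)

    def __hash__(self):
        return hash((self.chromosome, self.ends.tobytes(), self.ancestry))

    def __repr__(self):
        segs = ", ".join(f"{a}<={e}" for e, a in zip(self.ends, self.ancestry))
        return f"Haplotype({self.chromosome}: {segs})"


def splice(left: Haplotype, right: Haplotype, breakpoint_bp: int) -> Haplotype:
    """Recombinant haplotype: ``left`` on [1, breakpoint], ``right`` after.

    Adjacent same-ancestry segments are merged so the invariant holds.
    """
    if left.chromosome != right.chromosome or left.length_bp != right.length_bp:
        raise MapStructureError("cannot splice haplotypes of different chromosomes")
    length = left.length_bp
    if not (1 <= breakpoint_bp < length):
        # A breakpoint at/after the last base transmits `left` unchanged.
        return left if breakpoint_bp >= length else right
    ends: list[int] = []
    labels: list[str] = []
    for e, a in zip(left.ends, left.ancestry):
        if e > breakpoint_bp:
            break
        ends.append(int(e))
        labels.append(a)
    # Left part of the segment containing the breakpoint.
    left_label = left.ancestry_at(breakpoint_bp)
    if not labels or labels[-1] != left_label:
        ends.append(breakpoint_bp)
        labels.append(left_label)
    else:
        ends[-1] = breakpoint_bp
    # Right-hand segments contribute positions > breakpoint only.
    start_idx = int(np.searchsorted(right.ends, breakpoint_bp, side="right"))
    for e, a in zip(right.ends[start_idx:], right.ancestry[start_idx:]):
        if labels and labels[-1] == a:
            ends[-1] = int(e)
        else:
            ends.append(int(e))
            labels.append(a)
    return Haplotype(left.chromosome, ends, labels)


class DiploidGenome:
    """A pair of haplotypes for every chromosome of a genetic map."""

    __slots__ = ("pairs",)

    def __init__(self, pairs: dict[str, tuple[Haplotype, Haplotype]]):
        for name, (m, p) in pairs.items():
            if m.chromosome != name or p.chromosome != name:
                raise MapStructureError(
                    f"haplotype pair under key {name!r} references another chromosome"
                )
        self.pairs = dict(pairs)

    @classmethod
    def homozygous(cls, gmap: GeneticMap, label: str) -> "DiploidGenome":
        return cls({
            c.name: (Haplotype.uniform(c.name, c.length_bp, label),
                     Haplotype.uniform(c.name, c.length_bp, label))
            for c in gmap
        })

    def genotype_at(self, chromosome: str, position: int) -> tuple[str, str]:
        m, p = self.pairs[chromosome]
        return (m.ancestry_at(position), p.ancestry_at(position))

    def dose_at(self, chromosome: str, position: int, label: str) -> int:
        """Number of haplotypes (0, 1 or 2) carrying ``label`` ancestry."""
        return sum(a == label for a in self.genotype_at(chromosome, position))

    def is_homozygous_at(self, chromosome: str, position: int, label: str) -> bool:
        return self.dose_at(chromosome, position, label) == 2

    def chromosomes(self) -> list[str]:
        return list(self.pairs)

    def __eq__(self, other):
        return isinstance(other, DiploidGenome) and self.pairs == other.pairs

    def __repr__(self):
        return f"DiploidGenome({list(self.pairs)})"
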