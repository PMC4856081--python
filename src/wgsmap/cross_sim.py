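"""Forward simulation of mutagenesis mapping crosses.

Models the genetics behind pooled-F2 mapping designs: meiosis with
crossover interference, Mendelian transmission through selfing,
phenotype assignment for recessive / dominant / semidominant and
two-locus synthetic mutations, phenotype- and marker-based F2 pool
selection (with optional segregation distortion), and F3 progeny
screening to resolve zygosity. The closed-form expectations those
designs rest on (locus allele frequencies, F3 misclassification rates,
recombinant screening effort) are provided as analytic helpers.

Conventions
-----------
* All chromosomes behave as autosomes; F2s arise by F1 selfing.
* Ancestry labels identify the two parental strains. By default the
  mutagenized laboratory background is ``"mut"`` and the polymorphic
  mapping strain (or the wild-type backcross parent in marked designs)
  is ``"map"``.
* Crossover interference ``"complete"`` places exactly one crossover
  per bivalent, uniformly on the genetic map, and transmits a
  recombinant chromatid with probability 1/2 — giving a recombinant
  fraction of d/100 for loci d cM apart. ``"none"`` draws a Poisson
  (genetic_length/100) number of crossovers on the transmitted product,
  which reproduces the Haldane map function.
* One root seed drives a run; per-individual child streams are derived
  with ``numpy.random.SeedSequence`` so pools are reproducible
  regardless of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Literal

import numpy as np

from .errors import (
    MapMismatchError,
    MapStructureError,
    PoolExhaustionError,
    UnsupportedDesignError,
)
from .genome import DiploidGenome, GeneticMap, Haplotype, splice

__all__ = [
    "MUTANT_LABEL",
    "MAPPING_LABEL",
    "MutationSpec",
    "MarkerSpec",
    "CrossDesign",
    "PoolSample",
    "DESIGN_TAGS",
    "make_gamete",
    "cross",
    "f2_generator",
    "phenotype_of",
    "select_f2_pool",
    "f3_homozygote_screen",
    "screen_pool_f3",
    "pool_genotype_table",
    "expected_locus_frequency",
    "het_misclassification_prob",
    "screening_effort",
    "marker_screen_reduction",
]

MUTANT_LABEL = "mut"
MAPPING_LABEL = "map"

Interference = Literal["complete", "none"]

DESIGN_TAGS = (
    "recessive_hawaiian",
    "dominant_reverse",
    "dominant_f3",
    "semidominant_f3",
    "two_gene_hawaiian",
    "marked_single",
    "marked_reciprocal",
)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class MutationSpec:
    """The mutation(s) under study.

    ``loci`` holds (chromosome, position) pairs; a single-locus spec has
    exactly one, a two-gene synthetic spec exactly two on distinct
    chromosomes. ``penetrance`` is the probability that a mutant
    genotype expresses the mutant phenotype.
    """

    loci: tuple[tuple[str, int], ...]
    dominance: Literal["recessive", "dominant", "semidominant"] = "recessive"
    interaction: Literal["single", "two_gene_synthetic"] = "single"
    penetrance: float = 1.0
    mutant_label: str = MUTANT_LABEL

    def __post_init__(self):
        loci = tuple((str(c), int(p)) for c, p in self.loci)
        object.__setattr__(self, "loci", loci)
        if self.interaction == "single" and len(loci) != 1:
            raise MapStructureError("single-locus spec requires exactly 1 locus")
        if self.interaction == "two_gene_synthetic":
            if len(loci) != 2:
                raise MapStructureError("two_gene_synthetic requires exactly 2 loci")
            if loci[0][0] == loci[1][0]:
                raise MapStructureError("two_gene_synthetic loci must be on distinct chromosomes")
        if not (0.0 <= self.penetrance <= 1.0):
            raise MapStructureError("penetrance must lie in [0, 1]")

    def validate_on(self, gmap: GeneticMap) -> None:
        for chrom, pos in self.loci:
            gmap.check_position(chrom, pos)


@dataclass(frozen=True)
class MarkerSpec:
    """Morphological marker loci flanking (or linked to) the mutation.

    Used only by the marked designs; each marker must sit on the same
    chromosome as the mutation locus it flanks.
    """

    markers: tuple[tuple[str, int, str], ...]  # (chromosome, position, side)

    def __post_init__(self):
        markers = tuple((str(c), int(p), str(s)) for c, p, s in self.markers)
        for _, _, side in markers:
            if side not in ("left", "right"):
                raise MapStructureError(f"marker side must be left|right, got {side!r}")
        object.__setattr__(self, "markers", markers)

    def validate_on(self, gmap: GeneticMap, spec: MutationSpec) -> None:
        mut_chroms = {c for c, _ in spec.loci}
        for chrom, pos, _ in self.markers:
            gmap.check_position(chrom, pos)
            if chrom not in mut_chroms:
                raise MapStructureError(
                    f"marker on {chrom} does not flank any mutation locus"
                )

    def side(self, which: str) -> "MarkerSpec":
        sel = tuple(m for m in self.markers if m[2] == which)
        if not sel:
            raise MapStructureError(f"no marker with side {which!r}")
        return MarkerSpec(sel)


@dataclass(frozen=True)
class CrossDesign:
    """Which mapping cross is being run and how the pool is assembled."""

    tag: str
    pool_size: int
    n_f3_per_f2: int | None = None
    distortion: tuple[str, int, float] | None = None  # (chrom, pos, viability)

    def __post_init__(self):
        if self.tag not in DESIGN_TAGS:
            raise MapStructureError(f"unknown design tag {self.tag!r}")
        if self.pool_size < 1:
            raise MapStructureError("pool_size must be >= 1")
        if self.tag.endswith("_f3"):
            if self.n_f3_per_f2 is None or self.n_f3_per_f2 < 1:
                raise MapStructureError("F3 designs require n_f3_per_f2 >= 1")
        if self.distortion is not None:
            _, _, viability = self.distortion
            if not (0.0 <= viability <= 1.0):
                raise MapStructureError("distortion viability must lie in [0, 1]")

    @property
    def is_marked(self) -> bool:
        return self.tag.startswith("marked")


@dataclass
class PoolSample:
    """Phenotype/marker-selected F2s destined for pooled sequencing."""

    members: list[DiploidGenome]
    design: CrossDesign
    selection_label: str

    def __post_init__(self):
        if not self.members:
            raise MapStructureError("pool must be nonempty")

    def __len__(self):
        return len(self.members)


# ---------------------------------------------------------------------------
# Meiosis and crosses
# ---------------------------------------------------------------------------

def make_gamete(parent: DiploidGenome, gmap: GeneticMap,
                interference: Interference = "complete",
                rng=None) -> dict[str, Haplotype]:
    """One meiotic product per chromosome of ``parent``.

    Under complete interference each bivalent receives exactly one
    crossover (uniform on the genetic map) and the transmitted chromatid
    is recombinant with probability 1/2. Under no interference the
    transmitted product carries Poisson(genetic_length/100) crossovers.
    """
    rng = _as_rng(rng)
    gamete: dict[str, Haplotype] = {}
    for cmap in gmap:
        try:
            hap_a, hap_b = parent.pairs[cmap.name]
        except KeyError:
            raise MapMismatchError(
                f"parent lacks chromosome {cmap.name!r} of the genetic map"
            ) from None
        if hap_a == hap_b:
            # Recombination between identical haplotypes is invisible.
            gamete[cmap.name] = hap_a
            continue
        if interference == "complete":
            if rng.random() < 0.5:
                xo_cm = rng.uniform(0.0, cmap.length_cm)
                bp = int(round(cmap.cm_to_bp(xo_cm)))
                bp = min(max(bp, 1), cmap.length_bp - 1)
                first, second = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
                gamete[cmap.name] = splice(first, second, bp)
            else:
                gamete[cmap.name] = hap_a if rng.random() < 0.5 else hap_b
        elif interference == "none":
            n_xo = rng.poisson(cmap.length_cm / 100.0)
            order = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
            if n_xo == 0:
                gamete[cmap.name] = order[0]
                continue
            xo_cm = np.sort(rng.uniform(0.0, cmap.length_cm, size=n_xo))
            product = order[0]
            # Tail source alternates between the two parental haplotypes.
            for i, cm_pos in enumerate(xo_cm):
                bp = int(round(cmap.cm_to_bp(cm_pos)))
                bp = min(max(bp, 1), cmap.length_bp - 1)
                product = splice(product, order[(i + 1) % 2], bp)
            gamete[cmap.name] = product
        else:
            raise ValueError(f"unknown interference model {interference!r}")
    return gamete


def cross(p1: DiploidGenome, p2: DiploidGenome, gmap: GeneticMap,
          interference: Interference = "complete", rng=None) -> DiploidGenome:
    """Offspring of two parents: one gamete from each."""
    rng = _as_rng(rng)
    if set(p1.pairs) != set(p2.pairs):
        raise MapMismatchError("parents carry different chromosome sets")
    g1 = make_gamete(p1, gmap, interference, rng)
    g2 = make_gamete(p2, gmap, interference, rng)
    return DiploidGenome({name: (g1[name], g2[name]) for name in g1})


def f2_generator(gmap: GeneticMap, interference: Interference = "complete",
                 seed: int | np.random.SeedSequence = 0,
                 mutant_label: str = MUTANT_LABEL,
                 mapping_label: str = MAPPING_LABEL) -> Iterator[DiploidGenome]:
    """Endless stream of F2 individuals from a mutant x mapping-strain cross.

    The F1 is heterozygous everywhere (mutant homozygote x mapping-strain
    homozygote); F2s are produced by F1 selfing. Individual ``i`` always
    draws from the same child seed stream, so membership of any downstream
    selection is reproducible independent of consumption order.
    """
    mut = DiploidGenome.homozygous(gmap, mutant_label)
    hawaiian = DiploidGenome.homozygous(gmap, mapping_label)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    f1 = cross(mut, hawaiian, gmap, interference,
               np.random.default_rng(root.spawn(1)[0]))
    i = 0
    while True:
        i += 1
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(1, i))
        yield cross(f1, f1, gmap, interference, np.random.default_rng(child))


# ---------------------------------------------------------------------------
# Phenotype and selection
# ---------------------------------------------------------------------------

def phenotype_of(g: DiploidGenome, spec: MutationSpec, rng=None) -> str:
    """Phenotype label: ``mutant``, ``wild_type`` or ``intermediate``.

    Recessive mutations require homozygosity; dominant require one
    allele; semidominant heterozygotes are ``intermediate``. Two-gene
    synthetic specs require homozygosity at both loci. Incomplete
    penetrance flips a would-be mutant to wild type.
    """
    rng = _as_rng(rng)
    doses = [g.dose_at(c, p, spec.mutant_label) for c, p in spec.loci]
    if spec.interaction == "two_gene_synthetic":
        expressed = all(d == 2 for d in doses)
        label = "mutant" if expressed else "wild_type"
    else:
        dose = doses[0]
        if spec.dominance == "recessive":
            label = "mutant" if dose == 2 else "wild_type"
        elif spec.dominance == "dominant":
            label = "mutant" if dose >= 1 else "wild_type"
        else:  # semidominant
            label = {2: "mutant", 1: "intermediate", 0: "wild_type"}[dose]
    if label == "mutant" and spec.penetrance < 1.0:
        if rng.random() >= spec.penetrance:
            label = "wild_type"
    return label


def _selection_predicate(design: CrossDesign, spec: MutationSpec,
                         markers: MarkerSpec | None, rng: np.random.Generator):
    """Per-individual eligibility test for a design's pool."""
    tag = design.tag
    if tag in ("recessive_hawaiian", "two_gene_hawaiian", "dominant_f3"):
        return lambda g: phenotype_of(g, spec, rng) == "mutant"
    if tag == "semidominant_f3":
        # Zygosity unresolved at picking time: heterozygotes (intermediate)
        # and homozygotes both enter; the F3 screen separates them.
        return lambda g: phenotype_of(g, spec, rng) in ("mutant", "intermediate")
    if tag == "dominant_reverse":
        return lambda g: phenotype_of(g, spec, rng) == "wild_type"
    if tag in ("marked_single", "marked_reciprocal"):
        if markers is None:
            raise MapStructureError(f"design {tag!r} requires a MarkerSpec")

        def pred(g: DiploidGenome) -> bool:
            hom_mut = all(g.is_homozygous_at(c, p, spec.mutant_label)
                          for c, p in spec.loci)
            hom_marker = all(g.is_homozygous_at(c, p, spec.mutant_label)
                             for c, p, _ in markers.markers)
            return hom_mut and hom_marker and phenotype_of(g, spec, rng) == "mutant"

        return pred
    raise UnsupportedDesignError(f"no selection predicate for design {tag!r}")


_EXPECTED_ELIGIBLE = {
    "recessive_hawaiian": 0.25,
    "dominant_f3": 0.75,
    "semidominant_f3": 0.75,
    "dominant_reverse": 0.25,
    "two_gene_hawaiian": 1.0 / 16.0,
    "marked_single": 0.25,      # tight linkage: marker rides with the mutation
    "marked_reciprocal": 0.25,
}


def select_f2_pool(f2s: Iterable[DiploidGenome], design: CrossDesign,
                   spec: MutationSpec, markers: MarkerSpec | None = None,
                   rng=None, max_attempts: int | None = None,
                   mapping_label: str = MAPPING_LABEL) -> PoolSample:
    """Assemble a pool by rejection sampling from a stream of F2s.

    Optional segregation distortion removes mapping-strain homozygotes
    at the distortion locus (with probability 1 - viability) before the
    phenotype/marker predicate is applied. Raises
    :class:`PoolExhaustionError` if the stream or the attempt cap is
    exhausted before ``pool_size`` eligible members are found.
    """
    rng = _as_rng(rng)
    pred = _selection_predicate(design, spec, markers, rng)
    if max_attempts is None:
        frac = _EXPECTED_ELIGIBLE.get(design.tag, 0.25)
        max_attempts = int(np.ceil(100 * design.pool_size / frac))
    members: list[DiploidGenome] = []
    attempts = 0
    for g in f2s:
        if len(members) >= design.pool_size:
            break
        attempts += 1
        if attempts > max_attempts:
            break
        if design.distortion is not None:
            chrom, pos, viability = design.distortion
            if g.is_homozygous_at(chrom, pos, mapping_label):
                if rng.random() >= viability:
                    continue  # inviable: never reaches the plate
        if pred(g):
            members.append(g)
    if len(members) < design.pool_size:
        raise PoolExhaustionError(
            f"design {design.tag!r}: only {len(members)}/{design.pool_size} "
            f"eligible F2s after {attempts} attempts"
        )
    labels = {
        "recessive_hawaiian": "mutant F2",
        "dominant_f3": "mutant F2",
        "semidominant_f3": "mutant-or-intermediate F2",
        "two_gene_hawaiian": "mutant F2",
        "dominant_reverse": "wild-type F2",
        "marked_single": "marker+mutation homozygous F2",
        "marked_reciprocal": "marker+mutation homozygous F2",
    }
    return PoolSample(members, design, labels[design.tag])


def f3_homozygote_screen(f2: DiploidGenome, n_f3: int, spec: MutationSpec,
                         gmap: GeneticMap, rng=None,
                         interference: Interference = "complete") -> bool:
    """Classify an F2 as homozygous iff all ``n_f3`` selfed progeny are mutant.

    A true homozygote always passes (at full penetrance); a heterozygote
    sneaks through with probability (3/4)^n_f3.
    """
    if n_f3 < 1:
        raise ValueError("n_f3 must be >= 1")
    rng = _as_rng(rng)
    for _ in range(n_f3):
        child = cross(f2, f2, gmap, interference, rng)
        if phenotype_of(child, spec, rng) != "mutant":
            return False
    return True


def screen_pool_f3(pool: PoolSample, spec: MutationSpec, gmap: GeneticMap,
                   rng=None, n_f3: int | None = None,
                   interference: Interference = "complete") -> PoolSample:
    """Keep only pool members whose F3 broods are 100% mutant."""
    rng = _as_rng(rng)
    n = n_f3 if n_f3 is not None else pool.design.n_f3_per_f2
    if n is None:
        raise ValueError("n_f3 not given and design carries no n_f3_per_f2")
    kept = [g for g in pool.members
            if f3_homozygote_screen(g, n, spec, gmap, rng, interference)]
    if not kept:
        raise PoolExhaustionError("F3 screen rejected every pool member")
    return PoolSample(kept, pool.design, "F3-screened homozygous F2")


# ---------------------------------------------------------------------------
# Closed-form design expectations
# ---------------------------------------------------------------------------

def expected_locus_frequency(design_tag: str) -> tuple[float, float]:
    """(mapping-strain allele frequency at the locus, at unlinked loci).

    The numbers behind each pooling design: a recessive pool excludes the
    mapping-strain allele at the locus entirely; a dominant mutant pool
    (2:1 het:hom) dilutes it to 1/3; a wild-type (reverse) pool drives it
    to 1; an F3-screened homozygote pool behaves like a recessive pool.
    Unlinked loci always sit at 1/2.
    """
    table = {
        "recessive_hawaiian": (0.0, 0.5),
        "dominant_f3": (1.0 / 3.0, 0.5),
        "semidominant_f3": (1.0 / 3.0, 0.5),
        "dominant_reverse": (1.0, 0.5),
        "f3_screened": (0.0, 0.5),
        "two_gene_hawaiian": (0.0, 0.5),
    }
    if design_tag in ("marked_single", "marked_reciprocal"):
        raise UnsupportedDesignError(
            "marked designs have no panel-SNP expectation; their signal is "
            "the novel-variant homozygosity profile"
        )
    try:
        return table[design_tag]
    except KeyError:
        raise UnsupportedDesignError(f"unknown design tag {design_tag!r}") from None


def het_misclassification_prob(n_f3: int) -> float:
    """Probability a heterozygous F2 yields 100% mutant F3s: (3/4)^n.

    A dominant heterozygote's selfed brood is mutant with probability
    3/4 per offspring, so an all-mutant brood of n misclassifies it.
    """
    if n_f3 < 0:
        raise ValueError("n_f3 must be >= 0")
    return 0.75 ** n_f3


def screening_effort(k_recombinants: int, map_distance_cm: float) -> float:
    """Expected F2s screened to recover k recombinant homozygotes.

    Only half of the recombinant gametes at map distance d produce the
    desired class, so the expectation is k / (0.5 * d/100): e.g. 50
    animals at 2.54 cM cost ~4000 screened F2s.
    """
    if not (0.0 < map_distance_cm <= 50.0):
        raise ValueError("map distance must lie in (0, 50] cM")
    if k_recombinants < 1:
        raise ValueError("k_recombinants must be >= 1")
    r = map_distance_cm / 100.0
    return k_recombinants / (0.5 * r)


def pool_genotype_table(pool: PoolSample):
    """Segment-level dump of a pool's genomes, for debugging and oracles.

    Columns: individual_id, chromosome, segment_end_bp, ancestry,
    haplotype_index.
    """
    import pandas as pd  # local: keeps the simulator importable without pandas

    rows = []
    for i, g in enumerate(pool.members):
        for chrom, pair in g.pairs.items():
            for h, hap in enumerate(pair):
                for end, anc in zip(hap.ends, hap.ancestry):
                    rows.append((i, chrom, int(end), anc, h))
    return pd.DataFrame(rows, columns=[
        "individual_id", "chromosome", "segment_end_bp", "ancestry", "haplotype_index",
    ])


def marker_screen_reduction() -> float:
    """Fraction of F2s excluded by pre-screening for a recessive marker.

    Only marker homozygotes (1/4 of F2s) need be scored for the mutant
    phenotype, a 75% reduction in screening effort.
    """
    return 0.75
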