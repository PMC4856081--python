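"""Pooled-sequencing read-count simulation over a SNP panel.

Turns a selected F2 pool into the per-site allele counts a variant
caller would report: site depth is Poisson around the mean coverage,
optionally thinned through a finite-library duplication model (counts
are post-duplicate-removal, as in a standard WGS pipeline), and the
alternate-allele count is binomial around the pool allele frequency
perturbed by a symmetric per-base error rate.

Two kinds of site are simulated. *Panel* sites are the annotated
polymorphisms of the mapping strain (~1 per kbp by default, emulating
the annotated Hawaiian SNP set). *Background* sites are novel variants
riding on the mutagenized strain's haplotypes: the causative lesion(s),
mutagenesis passengers, and any pre-existing variants of a marked
strain. Each site's ``source`` label names the strain whose ancestry
carries the alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .cross_sim import MAPPING_LABEL, MUTANT_LABEL, PoolSample
from .errors import MapStructureError, NoAllelicDepthError, VcfParseError
from .genome import GeneticMap

__all__ = [
    "SNPPanel",
    "BackgroundVariantSet",
    "CoverageModel",
    "AlleleCountTable",
    "simulate_panel",
    "simulate_background",
    "pool_allele_frequency",
    "pool_allele_frequencies",
    "simulate_counts",
    "expected_duplicate_fraction",
    "detection_limit",
    "write_pool_vcf",
    "read_pool_vcf",
]

_BASES = np.array(["A", "C", "G", "T"])

SITE_COLUMNS = ["chromosome", "position", "ref", "alt", "source"]


def _check_sites(df: pd.DataFrame, what: str) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    for col in SITE_COLUMNS:
        if col not in df.columns:
            raise MapStructureError(f"{what} missing column {col!r}")
    if (df["ref"] == df["alt"]).any():
        raise MapStructureError(f"{what}: ref and alt alleles must differ")
    if df.duplicated(["chromosome", "position"]).any():
        raise MapStructureError(f"{what}: positions must be unique per chromosome")
    # Sites sorted by (chromosome, position), chromosome order preserved.
    order = {c: i for i, c in enumerate(pd.unique(df["chromosome"]))}
    df = df.sort_values(["chromosome", "position"],
                        key=lambda s: s.map(order) if s.name == "chromosome" else s)
    return df.reset_index(drop=True)


@dataclass
class SNPPanel:
    """Annotated polymorphic sites distinguishing the mapping strain."""

    sites: pd.DataFrame

    def __post_init__(self):
        self.sites = _check_sites(self.sites, "SNP panel")

    def __len__(self):
        return len(self.sites)

    def on(self, chromosome: str) -> pd.DataFrame:
        return self.sites[self.sites["chromosome"] == chromosome]

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


@dataclass
class BackgroundVariantSet(SNPPanel):
    """Novel homozygous variants of the mutagenized (or marked) strain.

    Same table layout as :class:`SNPPanel`; positions must be disjoint
    from the mapping panel. An optional boolean ``causative`` column
    marks the lesion(s) of interest, and a ``shared_with_reference``
    column marks pre-existing variants also present in the wild-type
    comparison sample (the ones background subtraction removes).
    """

    def __post_init__(self):
        self.sites = _check_sites(self.sites, "background variant set")
        if "causative" not in self.sites.columns:
            self.sites["causative"] = False
        if "shared_with_reference" not in self.sites.columns:
            self.sites["shared_with_reference"] = False

    def check_disjoint(self, panel: SNPPanel) -> None:
        merged = self.sites.merge(panel.sites, on=["chromosome", "position"], how="inner")
        if len(merged):
            raise MapStructureError(
                f"{len(merged)} background sites collide with panel positions"
            )


def simulate_panel(gmap: GeneticMap, density_per_bp: float = 0.001,
                   source: str = MAPPING_LABEL, rng=None) -> SNPPanel:
    """Random marker panel: a Poisson process at ``density_per_bp``.

    The default density of 1 site per kbp mirrors the annotated subset
    used for polymorphism mapping.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for cmap in gmap:
        n = rng.poisson(cmap.length_bp * density_per_bp)
        pos = np.unique(rng.integers(1, cmap.length_bp + 1, size=n))
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        rows.append(pd.DataFrame({
            "chromosome": cmap.name,
            "position": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "source": source,
        }))
    return SNPPanel(pd.concat(rows, ignore_index=True))


def simulate_background(gmap: GeneticMap, n_passengers: int,
                        causative: Iterable[tuple[str, int]] = (),
                        n_shared: int = 0,
                        source: str = MUTANT_LABEL,
                        panel: SNPPanel | None = None,
                        rng=None) -> BackgroundVariantSet:
    """Novel variants of the mutagenized strain.

    ``n_passengers`` mutagenesis passengers are scattered uniformly over
    the genome, the listed ``causative`` loci are added explicitly, and
    ``n_shared`` strain variants (also present in the wild-type
    reference) are scattered as well. Positions avoid the mapping panel
    when one is given.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lengths = gmap.lengths_bp()
    total = float(sum(lengths.values()))
    taken = set()
    if panel is not None:
        taken = set(zip(panel.sites["chromosome"], panel.sites["position"]))
    causative = list(causative)
    for chrom, pos in causative:
        gmap.check_position(chrom, pos)

    def scatter(n):
        out = []
        while len(out) < n:
            u = rng.random()
            acc = 0.0
            for name, length in lengths.items():
                acc += length / total
                if u <= acc:
                    pos = int(rng.integers(1, length + 1))
                    if (name, pos) not in taken:
                        taken.add((name, pos))
                        out.append((name, pos))
                    break
        return out

    records = ([(c, p, True, False) for c, p in causative]
               + [(c, p, False, False) for c, p in scatter(n_passengers)]
               + [(c, p, False, True) for c, p in scatter(n_shared)])
    ref_idx = rng.integers(0, 4, size=len(records))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(records))) % 4
    df = pd.DataFrame({
        "chromosome": [r[0] for r in records],
        "position": [r[1] for r in records],
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "source": source,
        "causative": [r[2] for r in records],
        "shared_with_reference": [r[3] for r in records],
    })
    bg = BackgroundVariantSet(df)
    if panel is not None:
        bg.check_disjoint(panel)
    return bg


@dataclass(frozen=True)
class CoverageModel:
    """Sequencing depth, error, and library-complexity parameters.

    ``library_complexity`` is the number of unique sequenceable
    fragments per site-equivalent; when set, the simulated depth is the
    number of *distinct* fragments among the Poisson read draws, i.e.
    the post-duplicate-removal depth. Leaving it unset models an
    effectively infinite library (no duplicates).
    """

    mean_depth: float = 25.0
    error_rate: float = 0.002
    library_complexity: int | None = None

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise MapStructureError("mean_depth must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise MapStructureError("error_rate must lie in [0, 0.5)")
        if self.library_complexity is not None and self.library_complexity <= 0:
            raise MapStructureError("library_complexity must be > 0 when set")


COUNT_COLUMNS = ["chromosome", "position", "ref", "alt",
                 "ref_count", "alt_count", "depth", "site_class"]


@dataclass
class AlleleCountTable:
    """Per-site ref/alt read counts for one pooled sample."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts.reset_index(drop=True)
        for col in COUNT_COLUMNS:
            if col not in df.columns:
                raise MapStructureError(f"allele count table missing column {col!r}")
        if ((df["ref_count"] + df["alt_count"]) != df["depth"]).any():
            raise MapStructureError("ref_count + alt_count must equal depth at every site")
        if (df["depth"] < 0).any():
            raise MapStructureError("depth must be >= 0")
        self.counts = df

    def __len__(self):
        return len(self.counts)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


# ---------------------------------------------------------------------------
# Pool allele frequencies
# ---------------------------------------------------------------------------

def pool_allele_frequency(pool: PoolSample, chromosome: str, position: int,
                          source: str) -> float:
    """Fraction of pool chromosomes whose ancestry carries the alt allele."""
    carriers = 0
    for g in pool.members:
        try:
            pair = g.pairs[chromosome]
        except KeyError:
            raise MapStructureError(f"pool genomes lack chromosome {chromosome!r}") from None
        for hap in pair:
            if position > hap.length_bp or position < 1:
                raise MapStructureError(
                    f"position {position} outside chromosome {chromosome}"
                )
            if hap.ancestry_at(position) == source:
                carriers += 1
    return carriers / (2 * len(pool.members))


def pool_allele_frequencies(pool: PoolSample, sites: pd.DataFrame) -> np.ndarray:
    """Vectorised pool allele frequency for every row of a site table."""
    freqs = np.zeros(len(sites), dtype=float)
    pos_all = sites["position"].to_numpy()
    src_all = sites["source"].to_numpy()
    for chrom, idx in sites.groupby("chromosome", sort=False).indices.items():
        pos = pos_all[idx]
        src = src_all[idx]
        carriers = np.zeros(pos.size, dtype=np.int64)
        for g in pool.members:
            for hap in g.pairs[chrom]:
                seg = np.searchsorted(hap.ends, pos, side="left")
                labels = np.array(hap.ancestry, dtype=object)[seg]
                carriers += labels == src
        freqs[idx] = carriers / (2 * len(pool.members))
    return freqs


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _dedup_depths(raw: np.ndarray, complexity: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Distinct-fragment count among ``raw`` draws from a finite library."""
    out = np.empty_like(raw)
    for i, n in enumerate(raw):
        if n == 0:
            out[i] = 0
        else:
            out[i] = np.unique(rng.integers(0, complexity, size=n)).size
    return out


def simulate_counts(pool: PoolSample, panel: SNPPanel | None,
                    background: BackgroundVariantSet | None = None,
                    model: CoverageModel = CoverageModel(),
                    rng=None) -> AlleleCountTable:
    """Sample an :class:`AlleleCountTable` for a pool over panel + background.

    Per site: raw depth ~ Poisson(mean_depth), optionally thinned by the
    finite-library dedup model; alt_count ~ Binomial(depth, f') with
    f' = f(1-e) + (1-f)e, f the pool allele frequency at the site and e
    the symmetric error rate. Background sites flagged
    ``shared_with_reference`` are present in both parental strains, so
    their pool frequency is 1 regardless of ancestry.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    frames = []
    if panel is not None:
        frames.append(panel.sites.assign(site_class="panel", shared_with_reference=False))
    if background is not None:
        if panel is not None:
            background.check_disjoint(panel)
        cols = SITE_COLUMNS + ["shared_with_reference"]
        frames.append(background.sites[cols].assign(site_class="background"))
    if not frames:
        raise MapStructureError("simulate_counts needs a panel and/or background sites")
    sites = pd.concat(frames, ignore_index=True)
    order = {c: i for i, c in enumerate(pd.unique(sites["chromosome"]))}
    sites = sites.sort_values(
        ["chromosome", "position"],
        key=lambda s: s.map(order) if s.name == "chromosome" else s,
    ).reset_index(drop=True)
    freqs = pool_allele_frequencies(pool, sites)
    freqs[sites["shared_with_reference"].to_numpy(bool)] = 1.0
    e = model.error_rate
    f_eff = freqs * (1.0 - e) + (1.0 - freqs) * e
    raw_depth = rng.poisson(model.mean_depth, size=len(sites))
    if model.library_complexity is not None:
        depth = _dedup_depths(raw_depth, model.library_complexity, rng)
    else:
        depth = raw_depth
    alt = rng.binomial(depth, f_eff)
    out = sites[["chromosome", "position", "ref", "alt", "site_class"]].copy()
    out["depth"] = depth
    out["alt_count"] = alt
    out["ref_count"] = depth - alt
    return AlleleCountTable(out[COUNT_COLUMNS])


def expected_duplicate_fraction(n_reads: int, library_complexity: int) -> float:
    """Expected duplicate-read fraction for N reads from C unique fragments.

    E[distinct] = C(1 - (1 - 1/C)^N), so the duplicate fraction is
    1 - E[distinct]/N. Small libraries sequenced deeply approach 1.
    """
    if n_reads <= 0 or library_complexity <= 0:
        raise ValueError("n_reads and library_complexity must be positive")
    n, c = float(n_reads), float(library_complexity)
    distinct = c * (1.0 - (1.0 - 1.0 / c) ** n)
    return 1.0 - distinct / n


def detection_limit(mean_depth: float) -> float:
    """Average minimum detectable allele fraction at a given coverage.

    A single supporting read out of ``mean_depth`` sets the floor: 1/20
    = 5% at 20-fold coverage.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    return 1.0 / mean_depth


# ---------------------------------------------------------------------------
# Pool VCF I/O (minimal VCF v4.2 dialect, one sample, DP + AD)
# ---------------------------------------------------------------------------

def write_pool_vcf(table: AlleleCountTable, sample_name: str, path,
                   contig_lengths: dict[str, int] | None = None) -> None:
    """Write a one-sample VCF v4.2 with per-allele depths (FORMAT DP:AD)."""
    df = table.counts
    if contig_lengths is None:
        contig_lengths = (df.groupby("chromosome", sort=False)["position"].max()
                          .astype(int).to_dict())
    lines = ["##fileformat=VCFv4.2",
             "##source=wgsmap",
             '##INFO=<ID=SC,Number=1,Type=String,Description="Site class: panel or background">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth after duplicate removal">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read depths (ref, alt)">']
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name)
    for row in df.itertuples(index=False):
        lines.append(
            f"{row.chromosome}\t{row.position}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
            f"SC={row.site_class}\tDP:AD\t{row.depth}:{row.ref_count},{row.alt_count}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_pool_vcf(path) -> AlleleCountTable:
    """Read a pool VCF (as written by :func:`write_pool_vcf`) back to counts."""
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    rows = []
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise VcfParseError(f"expected exactly one sample, found {len(samples)}")
        sample = samples[0]
        for i, rec in enumerate(vf):
            call = rec.samples[sample]
            ad = call.get("AD")
            if ad is None or all(a is None for a in ad):
                raise NoAllelicDepthError(
                    f"no allelic depth (AD) at {rec.chrom}:{rec.pos}"
                )
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfParseError(
                    f"expected one ALT allele at {rec.chrom}:{rec.pos}", line=i + 1
                )
            ref_count, alt_count = int(ad[0]), int(ad[1])
            rows.append({
                "chromosome": rec.chrom,
                "position": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "ref_count": ref_count,
                "alt_count": alt_count,
                "depth": ref_count + alt_count,
                "site_class": rec.info.get("SC", "panel"),
            })
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return AlleleCountTable(df)
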