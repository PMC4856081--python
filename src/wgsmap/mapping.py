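"""SNP-frequency mapping analysis.

Consumes per-site allele counts from a pooled sample and locates the
mapping interval that must contain the causative mutation. Four
detection procedures are provided, matching the four pooling designs:

* **gap** — recessive-style pools: the mapping-strain SNP frequency
  collapses to ~0 around the mutation; the interval is the longest
  region where the LOESS curve stays below a threshold.
* **peak** — reverse mapping (wild-type pools from a dominant cross):
  the mapping-strain SNP frequency rises to ~100%; the interval is the
  plateau of the binned homozygous-SNP frequency around its peak.
* **cluster** — marked-mutant backcross: novel homozygous variants
  chain together between the marker and the mutation.
* **reciprocal** — two pools marked on opposite sides: averaging the
  two homozygosity profiles and thresholding the LOESS curve at 0.75
  (midpoint between one-sample- and both-sample-homozygous levels)
  narrows the interval.

Coordinates are 1-based inclusive bp; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    MapStructureError,
    NoClusterError,
    NoIntervalError,
    NoSignalError,
)
from .readsim import AlleleCountTable, SNPPanel

__all__ = [
    "VariantCallSet",
    "FrequencySeries",
    "LoessCurve",
    "BinStats",
    "MappingInterval",
    "call_variants",
    "frequency_floor_filter",
    "snp_frequency_series",
    "fit_loess",
    "detect_gap_interval",
    "binned_homozygous_frequency",
    "detect_peak_interval",
    "subtract_background",
    "filter_homozygous",
    "detect_cluster_interval",
    "reciprocal_interval",
    "candidate_variants",
    "intervals_to_bed",
]


@dataclass
class VariantCallSet:
    """Per-site variant evidence with filter flags.

    ``alt_fraction`` is NaN at zero-depth sites, which are excluded from
    every downstream computation. ``passing`` combines depth, the
    minimum-read flag and the frequency-floor flag.
    """

    calls: pd.DataFrame
    min_reads: int = 3
    floor: float = 0.0

    def __post_init__(self):
        self.calls = self.calls.reset_index(drop=True)

    def __len__(self):
        return len(self.calls)

    @property
    def passing(self) -> pd.Series:
        c = self.calls
        return (c["depth"] > 0) & c["passed_min_reads"] & c["passed_min_freq"]

    def passing_calls(self) -> pd.DataFrame:
        return self.calls[self.passing].reset_index(drop=True)


@dataclass
class FrequencySeries:
    """Per-chromosome (position, frequency) observations for LOESS."""

    data: pd.DataFrame  # columns chromosome, position, frequency
    lengths: dict[str, int]
    empty_chromosomes: list[str] = field(default_factory=list)

    def on(self, chromosome: str) -> pd.DataFrame:
        return self.data[self.data["chromosome"] == chromosome]

    def chromosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in self.empty_chromosomes]


@dataclass
class LoessCurve:
    """Smoothed frequency curves on a uniform physical grid."""

    grids: dict[str, np.ndarray]
    fitted: dict[str, np.ndarray]
    span: float
    degree: int
    grid_step: int

    def on(self, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        return self.grids[chromosome], self.fitted[chromosome]


@dataclass
class BinStats:
    """Homozygous-SNP counts in fixed physical bins."""

    bins: pd.DataFrame  # chromosome, start, n_panel_sites, n_called_homozygous, normalized_frequency
    bin_bp: int
    hom_threshold: float


@dataclass(frozen=True)
class MappingInterval:
    """A called genomic interval (closed, 1-based)."""

    chromosome: str
    start: int
    end: int
    method: str  # gap | peak | cluster | reciprocal
    score: float
    degenerate: bool = False

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise MapStructureError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {"chromosome": self.chromosome, "start": self.start,
                "end": self.end, "method": self.method,
                "score": float(self.score), "degenerate": self.degenerate}


def intervals_to_bed(intervals: list[MappingInterval], path) -> None:
    """Write intervals as BED (0-based half-open)."""
    lines = [f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\t{iv.method}\t{iv.score:.6g}"
             for iv in intervals]
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def call_variants(counts: AlleleCountTable, min_reads: int = 3) -> VariantCallSet:
    """Flag sites by the minimum-supporting-reads rule (default 3)."""
    df = counts.counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["alt_fraction"] = np.where(df["depth"] > 0,
                                      df["alt_count"] / df["depth"], np.nan)
    df["passed_min_reads"] = df["alt_count"] >= min_reads
    df["passed_min_freq"] = True
    return VariantCallSet(df, min_reads=min_reads)


def frequency_floor_filter(calls: VariantCallSet, floor: float) -> VariantCallSet:
    """Flag sites below an allele-fraction floor (e.g. the detection limit).

    Removes error-driven low-frequency false positives at the price of
    bona fide low-frequency SNPs — the origin of the 0–5% discontinuity
    in filtered frequency plots.
    """
    if not (0.0 <= floor < 1.0):
        raise ValueError("floor must lie in [0, 1)")
    df = calls.calls.copy()
    df["passed_min_freq"] = df["passed_min_freq"] & ~(df["alt_fraction"] < floor)
    return VariantCallSet(df, min_reads=calls.min_reads, floor=floor)


# ---------------------------------------------------------------------------
# Frequency series and LOESS
# ---------------------------------------------------------------------------

def snp_frequency_series(calls: VariantCallSet, panel: SNPPanel,
                         lengths: dict[str, int],
                         failed_as_zero: bool = True) -> FrequencySeries:
    """Panel-site frequency observations along each chromosome.

    Panel positions are known a priori, so a covered site that fails the
    call filters is direct evidence of *absence* of the mapping-strain
    allele: with ``failed_as_zero`` (default) such sites enter the
    series at frequency 0, which lets the smoothed curve fall into the
    gap instead of interpolating across missing points. Zero-depth
    sites are always dropped; background sites never enter.
    """
    df = calls.calls
    mask = (df["site_class"] == "panel") & (df["depth"] > 0)
    panel_keys = set(zip(panel.sites["chromosome"], panel.sites["position"]))
    in_panel = [(c, p) in panel_keys
                for c, p in zip(df["chromosome"], df["position"])]
    mask &= pd.Series(in_panel, index=df.index)
    sub = df[mask].copy()
    passing = calls.passing[mask]
    if failed_as_zero:
        sub["frequency"] = np.where(passing, sub["alt_fraction"], 0.0)
    else:
        sub = sub[passing.to_numpy()]
        sub["frequency"] = sub["alt_fraction"]
    data = sub[["chromosome", "position", "frequency"]].reset_index(drop=True)
    empty = [c for c in lengths if (data["chromosome"] == c).sum() == 0]
    return FrequencySeries(data, dict(lengths), empty_chromosomes=empty)


def _loess_1d(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
              span: float, degree: int) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights."""
    n = x.size
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dx, dy, dd = xs[idx], ys[idx], d[idx]
        h = dd.max()
        if h <= 0:
            out[i] = dy.mean()
            continue
        w = (1.0 - np.clip(dd / h, 0.0, 1.0) ** 3) ** 3
        # Guard against an all-zero weight vector (all points at distance h).
        if not np.any(w > 0):
            w = np.ones_like(w)
        deg = min(degree, np.unique(dx).size - 1)
        xc = (dx - x0) / h  # centred/scaled for conditioning
        coeffs = np.polyfit(xc, dy, deg, w=np.sqrt(w))
        out[i] = np.polyval(coeffs, 0.0)
    return out


def fit_loess(series: FrequencySeries, span: float = 0.1, degree: int = 2,
              grid_step: int = 10_000, clip: tuple[float, float] | None = (0.0, 1.0),
              ) -> LoessCurve:
    """LOESS fit of each chromosome's frequency series on a uniform grid.

    Defaults (span 0.1, local quadratic) follow common practice for
    pooled-SNP mapping plots; fitted values are clipped to [0, 1].
    """
    grids: dict[str, np.ndarray] = {}
    fitted: dict[str, np.ndarray] = {}
    for chrom in series.chromosomes():
        sub = series.on(chrom)
        n = len(sub)
        if n < max(10, int(np.ceil(span * n))):
            raise InsufficientDataError(
                f"{chrom}: {n} points is too few for a LOESS fit (need >= 10)"
            )
        length = series.lengths[chrom]
        grid = np.arange(1, length + 1, grid_step, dtype=float)
        if grid[-1] != length:
            grid = np.append(grid, float(length))
        vals = _loess_1d(sub["position"].to_numpy(float),
                         sub["frequency"].to_numpy(float),
                         grid, span, degree)
        if clip is not None:
            vals = np.clip(vals, clip[0], clip[1])
        grids[chrom] = grid
        fitted[chrom] = vals
    return LoessCurve(grids, fitted, span, degree, grid_step)


# ---------------------------------------------------------------------------
# Gap detection (recessive-style designs)
# ---------------------------------------------------------------------------

def _runs_below(grid: np.ndarray, vals: np.ndarray, threshold: float,
                below: bool) -> list[tuple[int, int, float]]:
    """Contiguous index runs where vals < threshold (or >= when below=False)."""
    mask = vals < threshold if below else vals >= threshold
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j, float(vals[i:j + 1].mean())))
            i = j + 1
        else:
            i += 1
    return runs


def _crossing(grid, vals, i_edge, threshold, side):
    """Linear interpolation of the threshold crossing adjacent to a run edge."""
    if side == "left":
        if i_edge == 0:
            return grid[0]
        x0, x1 = grid[i_edge - 1], grid[i_edge]
        y0, y1 = vals[i_edge - 1], vals[i_edge]
    else:
        if i_edge == vals.size - 1:
            return grid[-1]
        x0, x1 = grid[i_edge], grid[i_edge + 1]
        y0, y1 = vals[i_edge], vals[i_edge + 1]
    if y1 == y0:
        return x0 if side == "left" else x1
    t = (threshold - y0) / (y1 - y0)
    return x0 + t * (x1 - x0)


def detect_gap_interval(series: FrequencySeries, curve: LoessCurve,
                        gap_threshold: float = 0.1) -> list[MappingInterval]:
    """Longest sub-threshold region of the LOESS curve per chromosome.

    Chromosomes whose curve never drops below the threshold contribute
    nothing; two-gene designs therefore yield two intervals. The score
    is interval length times the mean depression below the threshold.
    """
    intervals = []
    for chrom in curve.grids:
        grid, vals = curve.on(chrom)
        runs = _runs_below(grid, vals, gap_threshold, below=True)
        if not runs:
            continue
        best = max(runs, key=lambda r: grid[r[1]] - grid[r[0]])
        i, j, mean_val = best
        start = _crossing(grid, vals, i, gap_threshold, "left")
        end = _crossing(grid, vals, j, gap_threshold, "right")
        start_bp = max(1, int(round(start)))
        end_bp = max(start_bp, int(round(end)))
        score = (end_bp - start_bp + 1) * (gap_threshold - mean_val)
        intervals.append(MappingInterval(chrom, start_bp, end_bp, "gap", score))
    intervals.sort(key=lambda iv: -iv.score)
    return intervals


# ---------------------------------------------------------------------------
# Peak detection (reverse mapping)
# ---------------------------------------------------------------------------

def binned_homozygous_frequency(calls: VariantCallSet, panel: SNPPanel,
                                lengths: dict[str, int], bin_bp: int = 500_000,
                                hom_threshold: float = 0.95) -> BinStats:
    """Normalized homozygous-SNP frequency in fixed bins (default 0.5 Mbp).

    Per bin: the number of passing panel calls at alt fraction >=
    ``hom_threshold``, divided by the number of panel sites in the bin
    (guarded to 0 for empty bins).
    """
    passing = calls.passing_calls()
    passing = passing[passing["site_class"] == "panel"]
    hom = passing[passing["alt_fraction"] >= hom_threshold]
    rows = []
    for chrom, length in lengths.items():
        edges = np.arange(0, length + bin_bp, bin_bp)
        panel_pos = panel.on(chrom)["position"].to_numpy()
        hom_pos = hom[hom["chromosome"] == chrom]["position"].to_numpy()
        n_panel, _ = np.histogram(panel_pos, bins=edges)
        n_hom, _ = np.histogram(hom_pos, bins=edges)
        for b in range(len(edges) - 1):
            rows.append({
                "chromosome": chrom,
                "start": int(edges[b]) + 1,
                "n_panel_sites": int(n_panel[b]),
                "n_called_homozygous": int(n_hom[b]),
                "normalized_frequency": n_hom[b] / max(n_panel[b], 1),
            })
    return BinStats(pd.DataFrame(rows), bin_bp, hom_threshold)


def detect_peak_interval(bins: BinStats, plateau_drop: float = 0.2) -> MappingInterval:
    """Plateau of contiguous bins around the peak homozygous-SNP bin.

    The interval is the maximal run of bins at >= (1 - plateau_drop) of
    the maximum, containing the argmax bin. Ties on the maximum are
    broken toward the longer plateau, then leftmost. A plateau covering
    a whole chromosome is flagged degenerate.
    """
    df = bins.bins
    if (df["normalized_frequency"] <= 0).all():
        raise NoSignalError("all bins empty: no homozygous-SNP peak")
    peak = df["normalized_frequency"].max()
    cutoff = peak - plateau_drop * peak
    candidates = []
    for chrom, sub in df.groupby("chromosome", sort=False):
        sub = sub.reset_index(drop=True)
        vals = sub["normalized_frequency"].to_numpy()
        if not np.any(vals >= peak):
            continue
        runs = _runs_below(np.arange(vals.size), vals, cutoff, below=False)
        for i, j, mean_val in runs:
            if np.any(vals[i:j + 1] >= peak):
                start = int(sub.loc[i, "start"])
                end = int(sub.loc[j, "start"]) + bins.bin_bp - 1
                candidates.append((j - i + 1, chrom, start, end, mean_val,
                                   j - i + 1 == vals.size))
    # Longer plateau first, then leftmost.
    candidates.sort(key=lambda c: (-c[0], c[2]))
    n_bins, chrom, start, end, mean_val, whole = candidates[0]
    return MappingInterval(chrom, start, end, "peak", mean_val, degenerate=whole)


# ---------------------------------------------------------------------------
# Marked designs: background subtraction, homozygosity, clusters
# ---------------------------------------------------------------------------

def subtract_background(sample_calls: VariantCallSet,
                        reference_calls: VariantCallSet,
                        position_tolerance: int = 0) -> VariantCallSet:
    """Drop sample sites also called (passing) in a reference sample.

    Matching is on (chromosome, position, alt allele), optionally with a
    positional tolerance. Used to separate novel variants of a mutant
    strain from those shared with wild type.
    """
    ref = reference_calls.passing_calls()
    df = sample_calls.calls
    if position_tolerance == 0:
        key = ["chromosome", "position", "alt"]
        merged = df.merge(ref[key].drop_duplicates(), on=key,
                          how="left", indicator=True)
        keep = (merged["_merge"] == "left_only").to_numpy()
    else:
        keep = np.ones(len(df), dtype=bool)
        for (chrom, alt), sub in ref.groupby(["chromosome", "alt"]):
            rpos = np.sort(sub["position"].to_numpy())
            mask = (df["chromosome"] == chrom) & (df["alt"] == alt)
            pos = df.loc[mask, "position"].to_numpy()
            if rpos.size == 0 or pos.size == 0:
                continue
            idx = np.searchsorted(rpos, pos)
            near = np.zeros(pos.size, dtype=bool)
            for shift in (0, 1):
                j = np.clip(idx - shift, 0, rpos.size - 1)
                near |= np.abs(rpos[j] - pos) <= position_tolerance
            keep[np.flatnonzero(mask.to_numpy())[near]] = False
    out = df[keep].reset_index(drop=True)
    return VariantCallSet(out, min_reads=sample_calls.min_reads,
                          floor=sample_calls.floor)


def filter_homozygous(calls: VariantCallSet, min_depth: int = 15,
                      min_fraction: float = 0.8) -> VariantCallSet:
    """Homozygous-variant filter: depth >= 15 and alt fraction > 80%.

    The fraction cut is strict (> min_fraction); it tolerates sequencing
    errors and occasional mis-picked F2s. Calls at exactly 100% are
    additionally marked ``full_homozygous``.
    """
    df = calls.passing_calls()
    kept = df[(df["depth"] >= min_depth) & (df["alt_fraction"] > min_fraction)].copy()
    kept["full_homozygous"] = kept["alt_fraction"] >= 1.0
    return VariantCallSet(kept.reset_index(drop=True),
                          min_reads=calls.min_reads, floor=calls.floor)


def detect_cluster_interval(hom_calls: VariantCallSet, max_gap: float = 2e6,
                            min_members: int = 3) -> MappingInterval:
    """Span of the largest homozygous-variant chain on the plurality chromosome.

    Consecutive cluster members may be at most ``max_gap`` apart; the
    score is the chain's share of all homozygous calls (the enrichment
    fraction, e.g. "73 of 87").
    """
    df = hom_calls.calls
    if df.empty:
        raise NoClusterError("no homozygous calls to cluster")
    total = len(df)
    chrom = df["chromosome"].value_counts().idxmax()
    pos = np.sort(df.loc[df["chromosome"] == chrom, "position"].to_numpy())
    chains = []
    start = 0
    for i in range(1, pos.size + 1):
        if i == pos.size or pos[i] - pos[i - 1] > max_gap:
            chains.append((start, i - 1))
            start = i
    chains = [(i, j) for i, j in chains if j - i + 1 >= min_members]
    if not chains:
        raise NoClusterError(
            f"no chain of >= {min_members} homozygous calls within {max_gap:g} bp"
        )
    i, j = max(chains, key=lambda c: c[1] - c[0])
    members = j - i + 1
    return MappingInterval(chrom, int(pos[i]), int(pos[j]), "cluster",
                           members / total)


def reciprocal_interval(hom_calls_a: VariantCallSet, hom_calls_b: VariantCallSet,
                        lengths: dict[str, int], span: float = 0.3,
                        threshold: float = 0.75, grid_step: int = 10_000,
                        calls_a: VariantCallSet | None = None,
                        calls_b: VariantCallSet | None = None) -> MappingInterval:
    """Interval supported by two reciprocally marked pools.

    Over the union of homozygous sites from the two samples, each
    sample contributes its observed alt fraction (looked up in the full
    call set when provided, else 0 where it made no homozygous call);
    the two profiles are averaged, smoothed with LOESS, and the longest
    region where the curve stays >= ``threshold`` (default 0.75, the
    midpoint between one-sample- and both-sample-homozygous levels) is
    returned. The score is the mean curve value inside.
    """
    a = hom_calls_a.calls[["chromosome", "position", "alt_fraction"]]
    b = hom_calls_b.calls[["chromosome", "position", "alt_fraction"]]
    union = pd.merge(a, b, on=["chromosome", "position"], how="outer",
                     suffixes=("_a", "_b"))

    def _fill(col, full_calls):
        vals = union[col].to_numpy(float)
        missing = np.isnan(vals)
        if full_calls is not None and missing.any():
            lookup = full_calls.calls.set_index(["chromosome", "position"])["alt_fraction"]
            keys = list(zip(union["chromosome"][missing], union["position"][missing]))
            obs = [lookup.get(k, np.nan) for k in keys]
            vals[missing] = obs
            missing = np.isnan(vals)
        vals[missing] = 0.0
        return vals

    fa = _fill("alt_fraction_a", calls_a)
    fb = _fill("alt_fraction_b", calls_b)
    union["frequency"] = (fa + fb) / 2.0
    chrom = union["chromosome"].value_counts().idxmax()
    sub = union[union["chromosome"] == chrom].sort_values("position")
    series = FrequencySeries(
        sub[["chromosome", "position", "frequency"]].reset_index(drop=True),
        {chrom: lengths[chrom]},
    )
    curve = fit_loess(series, span=span, degree=1, grid_step=grid_step)
    grid, vals = curve.on(chrom)
    runs = _runs_below(grid, vals, threshold, below=False)
    # Restrict to the span of observed sites: LOESS extrapolates flat
    # beyond the outermost variants, where there is no evidence.
    lo, hi = sub["position"].min(), sub["position"].max()
    runs = [(i, j, m) for i, j, m in runs if grid[j] >= lo and grid[i] <= hi]
    if not runs:
        raise NoIntervalError(f"averaged variant fraction never reaches {threshold}")
    i, j, mean_val = max(runs, key=lambda r: grid[r[1]] - grid[r[0]])
    start = max(int(round(_crossing(grid, vals, i, threshold, "left"))), int(lo))
    end = min(int(round(_crossing(grid, vals, j, threshold, "right"))), int(hi))
    if end < start:
        start, end = end, start
    return MappingInterval(chrom, max(1, start), end, "reciprocal", mean_val)


# ---------------------------------------------------------------------------
# Candidate listing
# ---------------------------------------------------------------------------

_NONSYNONYMOUS = {"nonsynonymous", "missense", "nonsense", "stop_gained",
                  "stop_lost", "splice", "frameshift", "start_lost"}


def candidate_variants(novel_calls: VariantCallSet, interval: MappingInterval,
                       effect_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Homozygous novel calls inside a (closed) mapping interval.

    With an effect-annotation table (chromosome, position, gene,
    effect_class), protein-altering candidates sort ahead of the rest;
    within a class, by position.
    """
    df = novel_calls.calls
    mask = ((df["chromosome"] == interval.chromosome)
            & (df["position"] >= interval.start)
            & (df["position"] <= interval.end))
    out = df[mask].copy()
    if effect_annotation is not None:
        out = out.merge(effect_annotation, on=["chromosome", "position"], how="left")
        prio = out["effect_class"].map(
            lambda e: 0 if isinstance(e, str) and e.lower() in _NONSYNONYMOUS else 1)
        out = out.assign(_prio=prio).sort_values(["_prio", "position"]).drop(columns="_prio")
    else:
        out = out.sort_values("position")
    return out.reset_index(drop=True)
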