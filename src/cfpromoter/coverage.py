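"""Fragment counting over pTSS windows, depth normalization and profiles.

The counting unit is the cfDNA *fragment* (sequenced template interval),
not the individual read: a fragment counts once toward every region it
shares at least one base with.  Normalization is fragments per kilobase
of region per million total fragments (FPKM-style), which makes values
comparable across samples of different sequencing depth; any monotone
per-sample alternative would leave the downstream rank statistics
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import PTSSRegion

REGION_LENGTH = 2000
NORMALIZATION_TAG = "fragments_per_kb_per_million"


@dataclass(frozen=True)
class Fragment:
    """A cfDNA fragment interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    sample_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fragment_bed(path, sample_id: str = "") -> list[Fragment]:
    """Read fragments from BED3+ (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 fields")
            out.append(Fragment(parts[0], int(parts[1]), int(parts[2]), sample_id))
    return out


def write_fragment_bed6(fragments, path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            name = getattr(f, "name", None) or f.sample_id or "."
            strand = getattr(f, "strand", ".")
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{strand}\n")


@dataclass
class CoverageMatrix:
    """Samples x regions coverage: raw fragment counts plus normalized values."""

    sample_ids: list[str]
    region_ids: list[str]
    raw_counts: np.ndarray        # (n_samples, n_regions) int
    normalized: np.ndarray        # (n_samples, n_regions) float
    total_fragments: np.ndarray   # (n_samples,) int
    normalization_tag: str = NORMALIZATION_TAG

    def __post_init__(self) -> None:
        n_s, n_r = len(self.sample_ids), len(self.region_ids)
        if self.raw_counts.shape != (n_s, n_r) or self.normalized.shape != (n_s, n_r):
            raise ValueError("matrix shapes inconsistent with id lists")
        if np.any(self.normalized < 0):
            raise ValueError("normalized coverage must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.normalized, index=self.sample_ids, columns=self.region_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CoverageMatrix":
        """Load a normalized-coverage TSV (raw counts/totals unavailable: set to 0/-1)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        norm = df.to_numpy(dtype=float)
        return cls(sample_ids=list(df.index.astype(str)),
                   region_ids=list(df.columns.astype(str)),
                   raw_counts=np.zeros_like(norm, dtype=int),
                   normalized=norm,
                   total_fragments=np.full(len(df), -1, dtype=int),
                   normalization_tag="loaded:" + NORMALIZATION_TAG)

    @classmethod
    def from_counts(cls, sample_ids, region_ids, raw_counts, total_fragments,
                    region_length: int = REGION_LENGTH) -> "CoverageMatrix":
        raw = np.asarray(raw_counts)
        totals = np.asarray(total_fragments)
        norm = np.empty(raw.shape, dtype=float)
        for i, t in enumerate(totals):
            norm[i] = normalize_coverage(raw[i], int(t), region_length)
        return cls(list(sample_ids), list(region_ids), raw, norm, totals)


def count_fragments(fragments, regions: list[PTSSRegion]) -> np.ndarray:
    """Count fragments overlapping each region by >=1 bp (half-open intervals).

    A fragment spanning two regions counts once in each.  Raises if the
    fragments and regions use disjoint chromosome name sets (a chr1-vs-1
    naming mismatch).
    """
    counts = np.zeros(len(regions), dtype=int)
    if not regions:
        return counts
    frag_list = list(fragments)
    region_chroms = {r.chrom for r in regions}
    frag_chroms = {f.chrom for f in frag_list}
    if frag_list and not (frag_chroms & region_chroms):
        raise ValueError(
            "no chromosome shared between fragments and regions "
            f"(fragments use {sorted(frag_chroms)[:3]}..., regions use "
            f"{sorted(region_chroms)[:3]}...); harmonize naming, e.g. 'chr1' vs '1'")

    # regions per chromosome, sorted by start; windowed scan using the
    # maximum region length so overlapping regions are still all found
    by_chrom: dict[str, list[int]] = {}
    for idx, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(idx)
    chrom_index = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: regions[i].start)
        starts = np.array([regions[i].start for i in idxs])
        ends = np.array([regions[i].end for i in idxs])
        max_len = int((ends - starts).max())
        chrom_index[chrom] = (np.array(idxs), starts, ends, max_len)

    for f in frag_list:
        entry = chrom_index.get(f.chrom)
        if entry is None:
            continue
        idxs, starts, ends, max_len = entry
        # candidate regions: start in (f.start - max_len, f.end)
        lo = np.searchsorted(starts, f.start - max_len, side="right")
        hi = np.searchsorted(starts, f.end, side="left")
        for j in range(lo, hi):
            if ends[j] > f.start and starts[j] < f.end:
                counts[idxs[j]] += 1
    return counts


def normalize_coverage(raw, total_fragments: int, region_length: int = REGION_LENGTH):
    """FPKM-style normalization: raw / ((L/1000) * (total/1e6)).

    Scale-invariant: doubling both ``raw`` and ``total_fragments`` leaves
    the value unchanged.
    """
    if total_fragments <= 0:
        raise ValueError("total_fragments must be > 0 for normalization")
    return np.asarray(raw, dtype=float) / ((region_length / 1000.0) * (total_fragments / 1e6))


def gc_reweight(gc_fractions, n_bins: int = 100):
    """Per-fragment weights flattening the GC composition histogram.

    Weight for a GC bin is (median occupied-bin count) / (bin count);
    empty bins contribute weight 0.  With a uniform GC histogram every
    weight is 1, so the correction is a no-op on unbiased data.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    gc = np.asarray(gc_fractions, dtype=float)
    if gc.size and (gc.min() < 0 or gc.max() > 1):
        raise ValueError("GC fractions must lie in [0, 1]")
    bins = np.minimum((gc * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    occupied = counts[counts > 0]
    if occupied.size == 0:
        return np.zeros(0)
    med = float(np.median(occupied))
    weights_per_bin = np.zeros(n_bins)
    nz = counts > 0
    weights_per_bin[nz] = med / counts[nz]
    return weights_per_bin[bins]


@dataclass
class DepthProfile:
    """Mean per-base depth around oriented TSSs, with SEM over averaging units."""

    offsets: np.ndarray     # -1000 .. +999
    mean_depth: np.ndarray
    sem: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.mean_depth) or len(self.offsets) != len(self.sem):
            raise ValueError("profile arrays must share length")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")


def _per_region_depth(fragments, regions: list[PTSSRegion]) -> np.ndarray:
    """(n_regions, L) per-base fragment depth, flipped so offset 0 is the TSS
    and negative offsets are upstream on either strand."""
    if not regions:
        raise ValueError("depth_profile requires at least one region")
    length = regions[0].length
    depth = np.zeros((len(regions), length))
    by_chrom: dict[str, list[int]] = {}
    for idx, r in enumerate(regions):
        if r.length != length:
            raise ValueError("all regions in a profile must share one length")
        by_chrom.setdefault(r.chrom, []).append(idx)
    for f in fragments:
        for idx in by_chrom.get(f.chrom, ()):
            r = regions[idx]
            lo = max(f.start, r.start) - r.start
            hi = min(f.end, r.end) - r.start
            if hi > lo:
                depth[idx, lo:hi] += 1
    for idx, r in enumerate(regions):
        if r.strand == "-":
            depth[idx] = depth[idx, ::-1]
    return depth


def depth_profile(fragments, regions: list[PTSSRegion]) -> DepthProfile:
    """Composite footprint profile over a region set (e.g. the 500 most-expressed
    promoters): per-base depth per region, oriented by strand, scaled by the
    overall mean depth so samples of different depth are comparable, then
    averaged with SEM taken across regions."""
    depth = _per_region_depth(fragments, regions)
    overall = depth.mean()
    if overall > 0:
        depth = depth / overall
    n = depth.shape[0]
    mean = depth.mean(axis=0)
    sem = depth.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(depth.shape[1])
    half = depth.shape[1] // 2
    offsets = np.arange(-half, depth.shape[1] - half)
    return DepthProfile(offsets=offsets, mean_depth=mean, sem=sem, n_units=n)


def estimate_ff_chry(fragments, y_chrom_label: str = "chrY",
                     male_reference_fraction: float = 0.005,
                     female_background_fraction: float = 0.0) -> float:
    """Fetal fraction from the proportion of fragments mapping to chrY.

    Linear interpolation between the female background proportion (ff=0)
    and the proportion expected for a pregnancy with a fully male-derived
    cfDNA pool (ff=1), clipped to [0, 1].  Only meaningful for male
    fetuses.
    """
    if male_reference_fraction <= female_background_fraction:
        raise ValueError("male_reference_fraction must exceed the female background")
    frag_list = list(fragments)
    total = len(frag_list)
    if total == 0:
        raise ValueError("cannot estimate fetal fraction from zero fragments")
    p_y = sum(1 for f in frag_list if f.chrom == y_chrom_label) / total
    ff = (p_y - female_background_fraction) / (male_reference_fraction - female_background_fraction)
    return float(np.clip(ff, 0.0, 1.0))
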