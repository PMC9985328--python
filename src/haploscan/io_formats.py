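"""Readers and writers for the formats the scan touches.

Phased VCF goes in, together with a PLINK-format genetic map and optional
BED masks; genome-browser track files (BED5 + bedGraph) and serialized
TMRCA lookup tables come out.  Internally physical positions are 1-based
inclusive (VCF convention) and all BED output is 0-based half-open.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "GeneticMap",
    "IntervalMask",
    "TrackRecord",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_plink_map",
    "write_plink_map",
    "interpolate_cm",
    "read_bed_mask",
    "write_track",
    "write_lookup_table",
    "read_lookup_table",
]

_SNP_ALLELES = frozenset("ACGT")


@dataclass
class HaplotypeMatrix:
    """Binary haplotype alignment: k phased rows over n biallelic sites.

    ``alleles`` is a (k, n) uint8 array with REF coded 0 and ALT coded 1;
    blocks are polarization-independent so no ancestral-allele handling is
    performed.  ``positions_cm`` may be absent until a genetic map is
    attached (see :func:`interpolate_cm` / :meth:`with_genetic_map`).
    """

    alleles: np.ndarray
    positions_bp: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    positions_cm: np.ndarray | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.positions_cm is not None:
            self.positions_cm = np.asarray(self.positions_cm, dtype=np.float64)
        if not self.row_ids:
            self.row_ids = [f"h{i}" for i in range(self.alleles.shape[0])]
        self.validate()

    @property
    def k(self) -> int:
        return self.alleles.shape[0]

    @property
    def n(self) -> int:
        return self.alleles.shape[1]

    def validate(self) -> None:
        k, n = self.alleles.shape
        if k < 2 or n < 1:
            raise ValueError(f"matrix must have k >= 2 rows and n >= 1 columns, got {k}x{n}")
        if self.alleles.max(initial=0) > 1:
            raise ValueError("alleles must be 0/1 with no missing values")
        if self.positions_bp.shape != (n,):
            raise ValueError("positions_bp must have one entry per column")
        if n > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise ValueError("positions_bp must be strictly increasing")
        if len(self.row_ids) != k:
            raise ValueError("row_ids must have one entry per row")
        if self.positions_cm is not None:
            if self.positions_cm.shape != (n,):
                raise ValueError("positions_cm must align 1:1 with positions_bp")
            if n > 1 and np.any(np.diff(self.positions_cm) < 0):
                raise ValueError("positions_cm must be non-decreasing")

    def with_genetic_map(self, gmap: "GeneticMap") -> "HaplotypeMatrix":
        """Return a copy with cM coordinates interpolated from ``gmap``."""
        cm = interpolate_cm(gmap, self.positions_bp)
        return HaplotypeMatrix(self.alleles, self.positions_bp, list(self.row_ids), cm, self.chrom)

    def select_columns(self, idx: np.ndarray) -> "HaplotypeMatrix":
        cm = None if self.positions_cm is None else self.positions_cm[idx]
        return HaplotypeMatrix(
            self.alleles[:, idx], self.positions_bp[idx], list(self.row_ids), cm, self.chrom
        )


@dataclass
class GeneticMap:
    """PLINK-style genetic map: per-variant (chrom, id, cM, bp), bp-sorted."""

    chrom: np.ndarray
    ids: np.ndarray
    positions_cm: np.ndarray
    positions_bp: np.ndarray

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=np.float64)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        order = np.argsort(self.positions_bp, kind="stable")
        self.chrom = np.asarray(self.chrom, dtype=object)[order]
        self.ids = np.asarray(self.ids, dtype=object)[order]
        self.positions_cm = self.positions_cm[order]
        self.positions_bp = self.positions_bp[order]
        if len(self.positions_bp) > 1:
            if np.any(np.diff(self.positions_bp) == 0):
                raise ValueError("duplicate bp positions in genetic map")
            if np.any(np.diff(self.positions_cm) < 0):
                raise ValueError("genetic map cM positions not monotone after bp sort (corrupt map)")

    def __len__(self) -> int:
        return len(self.positions_bp)


@dataclass
class IntervalMask:
    """Merged, sorted set of 0-based half-open [start, end) bp intervals."""

    intervals: np.ndarray  # (m, 2) int64

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if len(iv) and np.any(iv[:, 0] >= iv[:, 1]):
            raise ValueError("mask interval with start >= end")
        self.intervals = _merge_intervals(iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains_positions(self, positions_bp: np.ndarray) -> np.ndarray:
        """Boolean mask: which 1-based bp positions fall inside an interval."""
        pos0 = np.asarray(positions_bp, dtype=np.int64) - 1
        if not len(self.intervals):
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], pos0, side="right") - 1
        inside = idx >= 0
        inside[inside] = pos0[inside] < self.intervals[idx[inside], 1]
        return inside

    def overlaps_span(self, start_bp: np.ndarray, end_bp: np.ndarray) -> np.ndarray:
        """Which 1-based inclusive [start_bp, end_bp] spans intersect the mask.

        A span [a, b] (1-based inclusive) intersects the half-open 0-based
        interval [s, e) iff a <= e and b > s.
        """
        a = np.atleast_1d(np.asarray(start_bp, dtype=np.int64))
        b = np.atleast_1d(np.asarray(end_bp, dtype=np.int64))
        hit = np.zeros(len(a), dtype=bool)
        for s, e in self.intervals:
            hit |= (a <= e) & (b > s)
        return hit


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if not len(iv):
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:  # touching intervals coalesce
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


@dataclass
class TrackRecord:
    """One reported block in browser coordinates (0-based half-open)."""

    chrom: str
    start_bp: int
    end_bp: int
    s_hat: float
    n_haplotypes: int
    frequency: float

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("track record with start >= end")
        if self.s_hat < 0:
            raise ValueError("negative selection coefficient in track record")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | os.PathLike,
    maf_min: float = 0.0,
    sample_exclude: Sequence[str] = (),
) -> HaplotypeMatrix:
    """Read a phased single-chromosome VCF into a binary haplotype matrix.

    Every phased allele becomes one row (a diploid sample contributes two
    rows; mixed ploidy is allowed).  Multi-allelic and non-SNP records are
    skipped, sites with minor allele frequency below ``maf_min`` are
    dropped, and any unphased or missing genotype is a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=False)
    excluded = set(sample_exclude)
    keep_samples = [s for s in vcf.samples if s not in excluded]
    if excluded:
        vcf.set_samples(keep_samples)

    row_ids: list[str] | None = None
    ploidies: list[int] | None = None
    chrom: str | None = None
    columns: list[np.ndarray] = []
    positions: list[int] = []
    seen_pos: set[int] = set()

    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        if rec.REF not in _SNP_ALLELES or rec.ALT[0] not in _SNP_ALLELES:
            continue
        if chrom is None:
            chrom = rec.CHROM
        elif rec.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in VCF ({chrom} and {rec.CHROM}); one chromosome per file"
            )
        gts = rec.genotypes  # per sample: [allele, ..., phased_flag]
        alleles: list[int] = []
        rec_ploidies: list[int] = []
        for sample, gt in zip(keep_samples, gts):
            a, phased = gt[:-1], gt[-1]
            if any(x < 0 for x in a):
                raise ValueError(f"missing allele at {rec.CHROM}:{rec.POS} sample {sample}")
            if len(a) > 1 and not phased:
                raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS} sample {sample}")
            alleles.extend(int(x) for x in a)
            rec_ploidies.append(len(a))
        if row_ids is None:
            ploidies = rec_ploidies
            row_ids = [
                f"{s}_{i}" for s, p in zip(keep_samples, rec_ploidies) for i in range(p)
            ]
        elif rec_ploidies != ploidies:
            raise ValueError(f"ploidy changes at {rec.CHROM}:{rec.POS}")
        if rec.POS in seen_pos:
            raise ValueError(f"duplicate position {rec.CHROM}:{rec.POS}")
        seen_pos.add(rec.POS)
        col = np.array(alleles, dtype=np.uint8)
        if maf_min > 0:
            af = col.mean()
            if min(af, 1.0 - af) < maf_min:
                continue
        columns.append(col)
        positions.append(rec.POS)
    vcf.close()

    if not columns:
        raise ValueError("no biallelic SNP sites survive filtering")
    order = np.argsort(positions, kind="stable")
    alleles_mat = np.stack([columns[i] for i in order], axis=1)
    pos = np.asarray(positions, dtype=np.int64)[order]
    return HaplotypeMatrix(alleles_mat, pos, row_ids or [], None, chrom or "1")


def write_phased_vcf(m: HaplotypeMatrix, path: str | os.PathLike, ploidy: int = 2) -> None:
    """Write a matrix back out as a minimal phased VCF (REF=A, ALT=C).

    Rows are grouped into samples of the given ploidy; k must be divisible
    by it.  The writer exists so simulated fixtures exercise the real VCF
    reader.
    """
    if m.k % ploidy:
        raise ValueError(f"k={m.k} not divisible by ploidy={ploidy}")
    n_samples = m.k // ploidy
    samples = [m.row_ids[i * ploidy].rsplit("_", 1)[0] for i in range(n_samples)]
    if len(set(samples)) != n_samples:
        samples = [f"s{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={m.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(m.n):
            col = m.alleles[:, j]
            gts = "\t".join(
                "|".join(str(col[i * ploidy + p]) for p in range(ploidy))
                for i in range(n_samples)
            )
            fh.write(f"{m.chrom}\t{m.positions_bp[j]}\tv{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK map
# ---------------------------------------------------------------------------

def read_plink_map(path: str | os.PathLike) -> GeneticMap:
    """Read a 4-column whitespace-delimited PLINK .map file, sorted by bp."""
    chroms: list[str] = []
    ids: list[str] = []
    cms: list[float] = []
    bps: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                cm = float(parts[2])
                bp = int(parts[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: unparseable map entry") from exc
            chroms.append(parts[0])
            ids.append(parts[1])
            cms.append(cm)
            bps.append(bp)
    return GeneticMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                      np.array(cms), np.array(bps))


def write_plink_map(gmap: GeneticMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c, i, cm, bp in zip(gmap.chrom, gmap.ids, gmap.positions_cm, gmap.positions_bp):
            fh.write(f"{c}\t{i}\t{cm:.10g}\t{bp}\n")


def interpolate_cm(gmap: GeneticMap, pos_bp: np.ndarray | int) -> np.ndarray | float:
    """Linearly interpolate cM positions for bp queries; clamped at the ends."""
    if len(gmap) == 0:
        raise ValueError("cannot interpolate from an empty genetic map")
    scalar = np.isscalar(pos_bp)
    q = np.atleast_1d(np.asarray(pos_bp, dtype=np.float64))
    out = np.interp(q, gmap.positions_bp.astype(np.float64), gmap.positions_cm)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# BED masks and track output
# ---------------------------------------------------------------------------

def read_bed_mask(path: str | os.PathLike) -> IntervalMask:
    """Read a BED3+ file into a merged interval mask (0-based half-open)."""
    iv: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 BED fields")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"line {lineno}: BED interval start >= end")
            iv.append((start, end))
    return IntervalMask(np.array(iv, dtype=np.int64).reshape(-1, 2))


def write_track(records: Iterable[TrackRecord], out_prefix: str | os.PathLike) -> tuple[str, str]:
    """Write reported blocks as a BED5 file and a per-position-max bedGraph.

    BED5 name is ``s=<s_hat>;k=<n_haplotypes>`` and score is
    min(1000, round(s_hat * 10000)).  The bedGraph holds, for every
    position, the maximum selection coefficient over all blocks covering
    it.  Returns the two file paths.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.start_bp, r.end_bp))
    for r in recs:
        if r.s_hat < 0:
            raise ValueError("negative selection coefficient in track record")
    bed_path = f"{out_prefix}.bed"
    bg_path = f"{out_prefix}.bedgraph"
    with open(bed_path, "w") as fh:
        fh.write('track name="haploscan_blocks" description="selection coefficient blocks"\n')
        for r in recs:
            score = min(1000, round(r.s_hat * 10000))
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\ts={r.s_hat:.4f};k={r.n_haplotypes}\t{score}\n"
            )
    with open(bg_path, "w") as fh:
        fh.write('track type=bedGraph name="haploscan_s_hat"\n')
        for chrom in sorted({r.chrom for r in recs}):
            sub = [r for r in recs if r.chrom == chrom]
            for start, end, val in _per_position_max(sub):
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")
    return bed_path, bg_path


def _per_position_max(recs: list[TrackRecord]) -> list[tuple[int, int, float]]:
    """Segment the union of record spans by the running maximum of s_hat."""
    bounds = sorted({r.start_bp for r in recs} | {r.end_bp for r in recs})
    out: list[tuple[int, int, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        vals = [r.s_hat for r in recs if r.start_bp <= a and r.end_bp >= b]
        if not vals:
            continue
        v = max(vals)
        if out and out[-1][1] == a and out[-1][2] == v:
            out[-1] = (out[-1][0], b, v)
        else:
            out.append((a, b, v))
    return out


# ---------------------------------------------------------------------------
# Lookup table serialization (thin wrappers over the filters module)
# ---------------------------------------------------------------------------

def write_lookup_table(table, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(table.to_tsv())


def read_lookup_table(path: str | os.PathLike):
    from .filters import TmrcaLookupTable

    with open(path) as fh:
        return TmrcaLookupTable.from_tsv(fh.read())
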