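"""End-to-end genome scan: read, mask, enumerate, estimate, filter, report.

The scan proceeds through fixed stages; per-stage block counts are logged
and written to a machine-readable JSON summary, and the surviving blocks
go out as a TSV plus BED5/bedGraph genome-track files.  Everything is
deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import filters as flt
from . import io_formats as iof
from . import sweep_model as swm
from .pbwt_blocks import enumerate_blocks

__all__ = ["ScanConfig", "ScanResult", "scan", "scan_matrix", "drop_gap_blocks", "drop_hidden_blocks"]

logger = logging.getLogger(__name__)

_BLOCK_COLUMNS = [
    "chrom", "start_bp", "end_bp", "i", "j", "n_haplotypes", "y_freq", "d_cm", "r",
    "s_hat", "t_hat1", "t_hat2", "log_cl", "drift_threshold", "coalescent_threshold",
]


@dataclass
class ScanConfig:
    """Paths and parameters of one chromosome scan."""

    vcf: str
    genetic_map: str
    out_prefix: str
    mask_bed: str | None = None
    gaps_bed: str | None = None
    lookup_table: str | None = None
    ne: float = 10_000.0
    s_min: float = 0.005
    maf_min: float = 0.0
    delta_r: float | None = None  # default: mean inter-SNP map distance
    min_sites: int = 1
    sample_exclude: tuple = ()

    def validate(self) -> None:
        for name in ("vcf", "genetic_map"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name in ("mask_bed", "gaps_bed", "lookup_table"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_key_value_file(cls, path: str) -> "ScanConfig":
        """Load a config from a flat ``key=value`` file (one pair per line)."""
        kwargs: dict = {}
        fields = {f for f in cls.__dataclass_fields__}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, sep, val = line.partition("=")
                key = key.strip()
                if not sep or key not in fields:
                    raise ValueError(f"line {lineno}: unknown or malformed entry {line!r}")
                if key in ("ne", "s_min", "maf_min", "delta_r"):
                    kwargs[key] = float(val)
                elif key == "min_sites":
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = val.strip()
        return cls(**kwargs)


@dataclass
class ScanResult:
    blocks: pd.DataFrame  # reported blocks (all filters passed)
    counts: dict
    config: ScanConfig | None = None
    delta_r: float = 0.0


def drop_gap_blocks(start_bp, end_bp, gaps: iof.IntervalMask) -> np.ndarray:
    """Keep mask for blocks whose 1-based span does not intersect any gap."""
    return ~gaps.overlaps_span(start_bp, end_bp)


def drop_hidden_blocks(start_bp, end_bp, s_hat) -> np.ndarray:
    """Keep mask removing blocks hidden behind others.

    A block is hidden when its span is fully contained in the span of
    another block with a selection coefficient at least as high, so only
    the highest coefficient remains visible at every position.  Ties keep
    the longer block, then the earlier start.
    """
    start = np.asarray(start_bp, dtype=np.int64)
    end = np.asarray(end_bp, dtype=np.int64)
    s = np.asarray(s_hat, dtype=np.float64)
    m = len(start)
    keep = np.ones(m, dtype=bool)
    if m < 2:
        return keep
    order = np.lexsort((-s, -end, start))  # start asc, end desc, s desc
    # Fenwick tree over end ranks holding the running max of s among
    # already-seen blocks (which all start no later than the current one).
    uniq_ends = np.unique(end)
    rank = np.searchsorted(uniq_ends, end[order])
    nr = len(uniq_ends)
    tree = np.full(nr + 1, -np.inf)

    def update(pos: int, val: float) -> None:
        pos += 1
        while pos <= nr:
            if tree[pos] < val:
                tree[pos] = val
            pos += pos & (-pos)

    def query(pos: int) -> float:  # max over ranks >= pos (stored reversed)
        pos = nr - pos
        best = -np.inf
        while pos > 0:
            if tree[pos] > best:
                best = tree[pos]
            pos -= pos & (-pos)
        return best

    for idx in order:
        rk = int(np.searchsorted(uniq_ends, end[idx]))
        if query(rk) >= s[idx]:
            keep[idx] = False
        else:
            update(nr - 1 - rk, float(s[idx]))
    return keep


def scan_matrix(
    m: iof.HaplotypeMatrix,
    ne: float = 10_000.0,
    s_min: float = 0.005,
    delta_r: float | None = None,
    table: flt.TmrcaLookupTable | None = None,
    mask: iof.IntervalMask | None = None,
    gaps: iof.IntervalMask | None = None,
    min_sites: int = 1,
    chrom: str | None = None,
) -> ScanResult:
    """Run the scan stages on an in-memory matrix with cM coordinates.

    This is the computational core of :func:`scan`; it returns the
    reported blocks and the per-stage counts.
    """
    if m.positions_cm is None:
        raise ValueError("matrix needs cM coordinates; attach a genetic map first")
    chrom = chrom or m.chrom
    counts: dict = {"sites": m.n, "haplotypes": m.k}

    if mask is not None and len(mask):
        keep_cols = ~mask.contains_positions(m.positions_bp)
        if keep_cols.sum() == 0:
            raise ValueError("mask removes every SNP")
        m = m.select_columns(np.flatnonzero(keep_cols))
        counts["sites_after_mask"] = m.n

    if delta_r is None:
        delta_r = swm.mean_delta_r(m.positions_cm)
    cfg = swm.ModelConfig(ne=ne, delta_r=delta_r, s_min=s_min)

    blocks = enumerate_blocks(m, min_sites=min_sites)
    counts["blocks_total"] = len(blocks)
    y_freq, d_cm, r = blocks.geometry()
    sizes = blocks.sizes
    start_bp, end_bp = blocks.spans_bp()

    s_hat, log_cl, t1, t2, estimable = swm.mcl_selection_arrays(
        r, y_freq, sizes, cfg, k_sample=m.k
    )
    counts["blocks_estimable"] = int(estimable.sum())

    pass_drift, drift_thr = flt.drift_filter_arrays(t1, y_freq, m.k, s_min, ne)
    pass_drift &= estimable
    counts["blocks_pass_drift"] = int(pass_drift.sum())

    if table is None:
        table = flt.build_lookup_table(ne, m.k)
    elif table.ne != ne:
        raise ValueError(f"lookup table built for Ne={table.ne}, scan uses Ne={ne}")
    pass_coal, coal_thr = flt.coalescent_filter_arrays(t2, sizes, r, table)
    pass_both = pass_drift & pass_coal
    counts["blocks_pass_both"] = int(pass_both.sum())

    idx = np.flatnonzero(pass_both)
    if gaps is not None and len(gaps):
        idx = idx[drop_gap_blocks(start_bp[idx], end_bp[idx], gaps)]
    counts["blocks_after_gap_removal"] = len(idx)

    idx = idx[drop_hidden_blocks(start_bp[idx], end_bp[idx], s_hat[idx])]
    counts["blocks_reported"] = len(idx)

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start_bp": start_bp[idx],
            "end_bp": end_bp[idx],
            "i": blocks.i[idx],
            "j": blocks.j[idx],
            "n_haplotypes": sizes[idx],
            "y_freq": y_freq[idx],
            "d_cm": d_cm[idx],
            "r": r[idx],
            "s_hat": s_hat[idx],
            "t_hat1": t1[idx],
            "t_hat2": t2[idx],
            "log_cl": log_cl[idx],
            "drift_threshold": drift_thr[idx],
            "coalescent_threshold": coal_thr[idx],
        },
        columns=_BLOCK_COLUMNS,
    ).sort_values(["start_bp", "end_bp"], kind="stable").reset_index(drop=True)

    for stage in ("blocks_total", "blocks_estimable", "blocks_pass_drift",
                  "blocks_pass_both", "blocks_after_gap_removal", "blocks_reported"):
        logger.info("%s: %d", stage, counts[stage])
    return ScanResult(blocks=df, counts=counts, delta_r=float(delta_r))


def scan(cfg: ScanConfig) -> ScanResult:
    """Full file-to-file scan; writes blocks TSV, track files and JSON summary."""
    cfg.validate()
    stage = "read_vcf"
    try:
        matrix = iof.read_phased_vcf(cfg.vcf, maf_min=cfg.maf_min,
                                     sample_exclude=cfg.sample_exclude)
        stage = "read_map"
        gmap = iof.read_plink_map(cfg.genetic_map)
        matrix = matrix.with_genetic_map(gmap)
        stage = "read_masks"
        mask = iof.read_bed_mask(cfg.mask_bed) if cfg.mask_bed else None
        gaps = iof.read_bed_mask(cfg.gaps_bed) if cfg.gaps_bed else None
        stage = "lookup_table"
        table = iof.read_lookup_table(cfg.lookup_table) if cfg.lookup_table else None
        stage = "scan"
        result = scan_matrix(
            matrix,
            ne=cfg.ne,
            s_min=cfg.s_min,
            delta_r=cfg.delta_r,
            table=table,
            mask=mask,
            gaps=gaps,
            min_sites=cfg.min_sites,
        )
    except Exception as exc:
        raise RuntimeError(f"scan aborted in stage {stage!r}: {exc}") from exc
    result.config = cfg

    df = result.blocks
    df.to_csv(f"{cfg.out_prefix}.blocks.tsv", sep="\t", index=False, float_format="%.8g")
    records = [
        iof.TrackRecord(
            chrom=row.chrom,
            start_bp=int(row.start_bp) - 1,  # 1-based inclusive -> 0-based half-open
            end_bp=int(row.end_bp),
            s_hat=float(row.s_hat),
            n_haplotypes=int(row.n_haplotypes),
            frequency=float(row.y_freq),
        )
        for row in df.itertuples()
    ]
    iof.write_track(records, cfg.out_prefix)
    summary = {"counts": result.counts, "delta_r": result.delta_r,
               "ne": cfg.ne, "s_min": cfg.s_min, "maf_min": cfg.maf_min}
    with open(f"{cfg.out_prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
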