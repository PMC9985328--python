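"""Maximal perfect haplotype block enumeration via the positional BWT.

A maximal perfect haplotype block is a triple (K, i, j): a set of at least
two rows that are identical over the column interval [i, j] and that can be
extended neither left, nor right, nor by an additional row.  The enumerator
builds the pBWT arrays a_j (colexicographic order of prefixes) and d_j
(divergence: start of the longest common suffix of neighbouring sorted
prefixes) column by column and reports, per column, the candidate row
intervals whose interior divergence maximum equals the block start, bounded
on both sides by strictly larger divergence.  Right-maximality is tested in
O(1) per candidate with prefix sums of a next-column change indicator, so
the total work is O(nk + z) for z blocks.

All coordinates are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numba import njit

from .io_formats import HaplotypeMatrix
from .sweep_model import haldane

__all__ = [
    "PbwtColumn",
    "HaploBlock",
    "BlockSet",
    "pbwt_step",
    "enumerate_blocks",
    "naive_blocks",
    "annotate_geometry",
]


@dataclass
class PbwtColumn:
    """pBWT state after processing columns 0..j (j = -1 means no columns).

    ``a`` sorts rows by their prefix read right-to-left; ``d[r]`` is the
    first column on which the prefixes of sorted rows r-1 and r agree
    through column j, with the sentinel d[0] = j + 1.
    """

    a: np.ndarray
    d: np.ndarray
    j: int

    @classmethod
    def initial(cls, k: int) -> "PbwtColumn":
        return cls(np.arange(k, dtype=np.int64), np.zeros(k, dtype=np.int64), -1)


def pbwt_step(prev: PbwtColumn, column_alleles: np.ndarray) -> PbwtColumn:
    """Advance the pBWT by one column (Durbin's update, O(k))."""
    c = np.asarray(column_alleles)
    if c.ndim != 1 or len(c) != len(prev.a):
        raise ValueError("column must have one allele per row")
    if np.any((c != 0) & (c != 1)):
        raise ValueError("non-binary allele in column")
    j = prev.j + 1
    k = len(c)
    a0, a1, d0, d1 = [], [], [], []
    p = q = j + 1
    for r in range(k):
        idx = prev.a[r]
        dr = prev.d[r]
        if dr > p:
            p = dr
        if dr > q:
            q = dr
        if c[idx] == 0:
            a0.append(idx)
            d0.append(p)
            p = 0
        else:
            a1.append(idx)
            d1.append(q)
            q = 0
    a = np.array(a0 + a1, dtype=np.int64)
    d = np.array(d0 + d1, dtype=np.int64)
    return PbwtColumn(a, d, j)


@dataclass(frozen=True)
class HaploBlock:
    """A maximal perfect haplotype block with optional geometry annotation."""

    K: frozenset
    i: int
    j: int
    y_freq: float = 0.0
    d_cm: float = 0.0
    r: float = 0.0

    def key(self) -> tuple:
        return (self.K, self.i, self.j)


@njit(cache=True)
def _scan_pass(Ht, min_sites, out_i, out_j, out_x, out_y, fill):
    """One pBWT sweep over all columns; counts blocks, optionally filling
    the preallocated output arrays (two-pass design keeps the hot loop
    free of reallocation)."""
    n, k = Ht.shape
    a = np.arange(k)
    d = np.zeros(k, dtype=np.int64)
    a_new = np.empty(k, dtype=np.int64)
    d_new = np.empty(k, dtype=np.int64)
    tmp_a1 = np.empty(k, dtype=np.int64)
    tmp_d1 = np.empty(k, dtype=np.int64)
    S = np.zeros(k, dtype=np.int64)  # prefix sums of next-column changes
    stack_i = np.empty(k + 1, dtype=np.int64)
    stack_x = np.empty(k + 1, dtype=np.int64)
    cnt = 0

    for j in range(n):
        col = Ht[j]
        # --- pBWT update: build a_j, d_j from a_{j-1}, d_{j-1} ---
        p = j + 1
        q = j + 1
        n0 = 0
        n1 = 0
        for r in range(k):
            idx = a[r]
            dr = d[r]
            if dr > p:
                p = dr
            if dr > q:
                q = dr
            if col[idx] == 0:
                a_new[n0] = idx
                d_new[n0] = p
                n0 += 1
                p = 0
            else:
                tmp_a1[n1] = idx
                tmp_d1[n1] = q
                n1 += 1
                q = 0
        for r in range(n1):
            a_new[n0 + r] = tmp_a1[r]
            d_new[n0 + r] = tmp_d1[r]
        a, a_new = a_new, a
        d, d_new = d_new, d

        # --- next-column change indicator prefix sums ---
        last = j == n - 1
        if not last:
            nxt = Ht[j + 1]
            s = 0
            S[0] = 0
            for r in range(1, k):
                if nxt[a[r]] != nxt[a[r - 1]]:
                    s += 1
                S[r] = s

        # --- stack scan over the divergence array ---
        top = -1
        for r in range(1, k + 1):
            dr = d[r] if r < k else j + 1
            x_new = r - 1
            while top >= 0 and stack_i[top] < dr:
                iv = stack_i[top]
                xv = stack_x[top]
                top -= 1
                yv = r - 1
                if iv <= j and (j - iv + 1) >= min_sites:
                    if last or S[yv] - S[xv] > 0:
                        if fill:
                            out_i[cnt] = iv
                            out_j[cnt] = j
                            out_x[cnt] = xv
                            out_y[cnt] = yv
                        cnt += 1
                x_new = xv
            if r < k:
                if top >= 0 and stack_i[top] == dr:
                    pass  # current divergence extends the open interval
                else:
                    top += 1
                    stack_i[top] = dr
                    stack_x[top] = x_new
    return cnt


def _scan_kernel(Ht, min_sites):
    empty = np.empty(0, dtype=np.int32)
    z = _scan_pass(Ht, min_sites, empty, empty, empty, empty, False)
    out_i = np.empty(z, dtype=np.int32)
    out_j = np.empty(z, dtype=np.int32)
    out_x = np.empty(z, dtype=np.int32)
    out_y = np.empty(z, dtype=np.int32)
    _scan_pass(Ht, min_sites, out_i, out_j, out_x, out_y, True)
    return out_i, out_j, out_x, out_y


@njit(cache=True)
def _materialize_kernel(Ht, want_j, want_x, want_y, offsets, rows_out):  # pragma: no cover
    """Replay the pBWT and copy a_j[x..y] for each requested block.

    ``want_*`` must be sorted by j; ``offsets`` gives each block's slice
    start in ``rows_out``.
    """
    n, k = Ht.shape
    a = np.arange(k)
    a_new = np.empty(k, dtype=np.int64)
    tmp_a1 = np.empty(k, dtype=np.int64)
    m = len(want_j)
    b = 0
    for j in range(n):
        col = Ht[j]
        n0 = 0
        n1 = 0
        for r in range(k):
            idx = a[r]
            if col[idx] == 0:
                a_new[n0] = idx
                n0 += 1
            else:
                tmp_a1[n1] = idx
                n1 += 1
        for r in range(n1):
            a_new[n0 + r] = tmp_a1[r]
        a, a_new = a_new, a
        while b < m and want_j[b] == j:
            off = offsets[b]
            for r in range(want_x[b], want_y[b] + 1):
                rows_out[off + r - want_x[b]] = a[r]
            b += 1


class BlockSet:
    """Columnar view of all maximal perfect haplotype blocks of a matrix.

    Blocks are stored as (i, j, x, y): column interval plus the contiguous
    interval of pBWT-sorted rows at column j.  Row IDs are materialized
    lazily (a second pBWT replay) and are exact.
    """

    def __init__(self, matrix: HaplotypeMatrix, i, j, x, y):
        self.matrix = matrix
        order = np.lexsort((x, i, j))  # grouped by end column, then start, then a-interval
        self.i = np.asarray(i)[order]
        self.j = np.asarray(j)[order]
        self.x = np.asarray(x)[order]
        self.y = np.asarray(y)[order]
        self._rows: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.i)

    @property
    def sizes(self) -> np.ndarray:
        return (self.y - self.x + 1).astype(np.int64)

    def geometry(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(y_freq, d_cm, r) arrays for all blocks; needs positions_cm."""
        m = self.matrix
        if m.positions_cm is None:
            raise ValueError("matrix has no cM coordinates; attach a genetic map first")
        y_freq = self.sizes / m.k
        d_cm = m.positions_cm[self.j] - m.positions_cm[self.i]
        return y_freq, d_cm, haldane(d_cm)

    def spans_bp(self) -> tuple[np.ndarray, np.ndarray]:
        return self.matrix.positions_bp[self.i], self.matrix.positions_bp[self.j]

    def materialize_rows(self) -> list[np.ndarray]:
        """Exact row indices of every block (replays the pBWT once)."""
        if self._rows is None:
            Ht = np.ascontiguousarray(self.matrix.alleles.T)
            sizes = self.sizes
            offsets = np.concatenate([[0], np.cumsum(sizes)])
            rows_out = np.empty(int(offsets[-1]), dtype=np.int64)
            _materialize_kernel(
                Ht,
                self.j.astype(np.int64),
                self.x.astype(np.int64),
                self.y.astype(np.int64),
                offsets[:-1].astype(np.int64),
                rows_out,
            )
            self._rows = [
                np.sort(rows_out[offsets[b]: offsets[b + 1]]) for b in range(len(self))
            ]
        return self._rows

    def __iter__(self) -> Iterator[HaploBlock]:
        rows = self.materialize_rows()
        has_cm = self.matrix.positions_cm is not None
        if has_cm:
            y_freq, d_cm, r = self.geometry()
        for b in range(len(self)):
            blk = HaploBlock(frozenset(int(v) for v in rows[b]), int(self.i[b]), int(self.j[b]))
            if has_cm:
                blk = HaploBlock(blk.K, blk.i, blk.j, float(y_freq[b]), float(d_cm[b]), float(r[b]))
            yield blk

    def to_set(self) -> set:
        return {(blk.K, blk.i, blk.j) for blk in self}

    def to_dataframe(self):
        """Debug table: one row per block with coordinates and geometry."""
        import pandas as pd

        m = self.matrix
        cols = {
            "chrom": m.chrom,
            "start_bp": m.positions_bp[self.i],
            "end_bp": m.positions_bp[self.j],
            "i": self.i,
            "j": self.j,
            "n_haplotypes": self.sizes,
        }
        if m.positions_cm is not None:
            y_freq, d_cm, r = self.geometry()
            cols.update({"y_freq": y_freq, "d_cm": d_cm, "r": r})
        return pd.DataFrame(cols)


def enumerate_blocks(m: HaplotypeMatrix, min_sites: int = 1) -> BlockSet:
    """Enumerate every maximal perfect haplotype block of ``m`` exactly once.

    ``min_sites`` optionally drops blocks spanning fewer columns (the
    definition permits single-column blocks; they are kept by default).
    """
    m.validate()
    Ht = np.ascontiguousarray(m.alleles.T)
    i, j, x, y = _scan_kernel(Ht, min_sites)
    return BlockSet(m, i, j, x, y)


def naive_blocks(m: HaplotypeMatrix) -> set:
    """Exhaustive oracle: all maximal blocks by direct definition check.

    For every column interval [i, j], rows are grouped into equivalence
    classes of their substring; a class of size >= 2 is a block iff the
    class is not constant on column i-1 (left-maximality) nor on column
    j+1 (right-maximality).  Row-maximality holds because classes are
    maximal row sets by construction.  Returns {(frozenset K, i, j)}.
    """
    k, n = m.k, m.n
    if k > 16 or n > 32:
        raise ValueError("naive oracle restricted to k <= 16, n <= 32")
    H = m.alleles
    out = set()
    for i in range(n):
        for j in range(i, n):
            groups: dict[bytes, list[int]] = {}
            for row in range(k):
                groups.setdefault(H[row, i: j + 1].tobytes(), []).append(row)
            for rows in groups.values():
                if len(rows) < 2:
                    continue
                if i > 0 and len({int(H[row, i - 1]) for row in rows}) == 1:
                    continue
                if j < n - 1 and len({int(H[row, j + 1]) for row in rows}) == 1:
                    continue
                out.add((frozenset(rows), i, j))
    return out


def annotate_geometry(b: HaploBlock, m: HaplotypeMatrix) -> HaploBlock:
    """Fill y_freq = |K|/k, d_cm, and the recombination fraction r."""
    if m.positions_cm is None:
        raise ValueError("matrix has no cM coordinates; attach a genetic map first")
    d_cm = float(m.positions_cm[b.j] - m.positions_cm[b.i])
    return HaploBlock(b.K, b.i, b.j, len(b.K) / m.k, d_cm, float(haldane(d_cm)))
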