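"""Genomic interval arithmetic on plain DataFrames.

All coordinates are 0-based half-open (BED convention). An interval set is a
pandas DataFrame with at least the columns ``chrom``, ``start``, ``end``;
extra columns are carried through where the operation permits.

The primitives here (merge, subtract, intersected base pairs, and the
multiinter-style breakpoint partition) back both the domain pipeline and the
per-base-pair oracles in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CORE_COLS = ["chrom", "start", "end"]


def _empty(extra: Sequence[str] = ()) -> pd.DataFrame:
    cols = CORE_COLS + list(extra)
    return pd.DataFrame({c: pd.Series(dtype=object if c == "chrom" else int) for c in cols})


def validate(df: pd.DataFrame) -> pd.DataFrame:
    """Check core columns and start < end; return a (chrom, start)-sorted copy."""
    for c in CORE_COLS:
        if c not in df.columns:
            raise ValueError(f"interval frame missing column {c!r}")
    if len(df) and not (df["end"] > df["start"]).all():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"invalid interval at row {bad}: end <= start")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge(df: pd.DataFrame, book_ended: bool = True) -> pd.DataFrame:
    """Union of intervals: overlapping (and, by default, book-ended) runs fuse.

    Extra columns are dropped; the result is the normal form used throughout.
    """
    df = validate(df)
    if not len(df):
        return _empty()
    out_chrom, out_start, out_end = [], [], []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            joins = s <= cur_e if book_ended else s < cur_e
            if joins:
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def total_bp(df: pd.DataFrame) -> int:
    if not len(df):
        return 0
    m = merge(df)
    return int((m["end"] - m["start"]).sum())


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """a minus b, per base pair. Extra columns of ``a`` propagate to fragments."""
    a = validate(a)
    if not len(a):
        return a.copy()
    b = merge(b) if len(b) else _empty()
    extra = [c for c in a.columns if c not in CORE_COLS]
    rows = []
    b_by_chrom = dict(tuple(b.groupby("chrom"))) if len(b) else {}
    for _, row in a.iterrows():
        sub = b_by_chrom.get(row["chrom"])
        pieces = [(row["start"], row["end"])]
        if sub is not None:
            for bs, be in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                nxt = []
                for s, e in pieces:
                    if be <= s or bs >= e:
                        nxt.append((s, e))
                        continue
                    if bs > s:
                        nxt.append((s, bs))
                    if be < e:
                        nxt.append((be, e))
                pieces = nxt
                if not pieces:
                    break
        for s, e in pieces:
            rec = {"chrom": row["chrom"], "start": s, "end": e}
            for c in extra:
                rec[c] = row[c]
            rows.append(rec)
    if not rows:
        return _empty(extra)
    return pd.DataFrame(rows, columns=CORE_COLS + extra)


def intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Base pairs covered by both sets."""
    a, b = merge(a), merge(b)
    total = 0
    b_by_chrom = dict(tuple(b.groupby("chrom"))) if len(b) else {}
    for chrom, sub in a.groupby("chrom"):
        other = b_by_chrom.get(chrom)
        if other is None:
            continue
        bs = other["start"].to_numpy()
        be = other["end"].to_numpy()
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            lo = np.maximum(bs, s)
            hi = np.minimum(be, e)
            total += int(np.clip(hi - lo, 0, None).sum())
    return total


def partition(sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Breakpoint partition over several interval sets (bedtools-multiinter style).

    Returns atomic segments ``chrom/start/end`` plus one 0/1 column per input
    set (``cov0``, ``cov1``, ...) indicating coverage, and ``count``. Only
    segments covered by at least one set are emitted.
    """
    normed = [merge(s) for s in sets]
    chroms = sorted({c for s in normed for c in s["chrom"].unique()})
    rows = []
    for chrom in chroms:
        per_set = []
        points = set()
        for s in normed:
            sub = s[s["chrom"] == chrom]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            per_set.append((starts, ends))
            points.update(starts.tolist())
            points.update(ends.tolist())
        bps = sorted(points)
        for lo, hi in zip(bps[:-1], bps[1:]):
            cov = []
            for starts, ends in per_set:
                i = np.searchsorted(starts, lo, side="right") - 1
                cov.append(1 if (i >= 0 and ends[i] > lo) else 0)
            if any(cov):
                rows.append([chrom, lo, hi, *cov, sum(cov)])
    cols = CORE_COLS + [f"cov{i}" for i in range(len(sets))] + ["count"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def overlap_flags(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap any target interval (same chrom)?"""
    query = validate(query)
    t = merge(targets) if len(targets) else _empty()
    flags = np.zeros(len(query), dtype=bool)
    t_by_chrom = dict(tuple(t.groupby("chrom"))) if len(t) else {}
    for chrom, sub in query.groupby("chrom"):
        other = t_by_chrom.get(chrom)
        if other is None:
            continue
        ts = other["start"].to_numpy()
        te = other["end"].to_numpy()
        for idx, (s, e) in zip(sub.index, zip(sub["start"].to_numpy(), sub["end"].to_numpy())):
            i = np.searchsorted(ts, e, side="left") - 1
            # any target starting before e that ends after s
            flags[idx] = i >= 0 and te[: i + 1].max() > s
    return flags
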