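"""Readers and writers for per-CpG methylation tracks, score tracks, BED
interval files and domain output.

One coordinate convention holds everywhere: 0-based half-open. A CpG record's
``start`` is the position of the C of the CG dinucleotide on the plus strand;
input is assumed destranded (one record per CpG dyad, the Biscuit vcf2bed
convention).

CpG tracks are tab-separated with columns chrom, start, end, beta, coverage
and an optional sixth column carrying a per-CpG hypomethylation score.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals

logger = logging.getLogger(__name__)

CPG_COLS = ["chrom", "start", "end", "beta", "coverage"]

#: Default coverage thresholds per pipeline stage. The general post-extraction
#: filter is >=3 informative reads; PMD segmentation and region-mean summaries
#: use the stricter >=5.
MIN_COVERAGE_SEGMENTATION = 5
MIN_COVERAGE_REGION_MEANS = 5
MIN_COVERAGE_REGION_TESTS = 3


class ParseError(ValueError):
    """Malformed line in an on-disk track, with 1-based line number."""


def read_cpg_track(path, min_coverage: int = MIN_COVERAGE_SEGMENTATION) -> pd.DataFrame:
    """Read a per-CpG methylation track, dropping low-coverage sites.

    Parameters
    ----------
    path
        TSV with columns chrom, start, end, beta, coverage[, score].
    min_coverage
        Sites with fewer informative reads are dropped (default 5, the
        threshold used ahead of PMD calling; region-level tests use 3).

    Returns
    -------
    DataFrame with columns chrom, start, end, beta, coverage (int) and, when
    the input has a sixth column, score (float, NaN allowed); sorted by
    (chrom, start), duplicate positions collapsed keep-first with a warning.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty CpG track")
    if raw.shape[1] < 5:
        raise ParseError(f"{path}: expected >=5 tab-separated columns, got {raw.shape[1]}")
    has_score = raw.shape[1] >= 6
    cols = CPG_COLS + (["score"] if has_score else [])
    df = raw.iloc[:, : len(cols)].copy()
    df.columns = cols

    for col in ["start", "end", "beta", "coverage"] + (["score"] if has_score else []):
        vals = pd.to_numeric(df[col], errors="coerce")
        if col != "score":
            bad = vals.isna()
            if bad.any():
                raise ParseError(f"{path}: non-numeric {col} at line {int(bad.idxmax()) + 1}")
        df[col] = vals
    out_of_range = (df["beta"] < 0) | (df["beta"] > 1)
    if out_of_range.any():
        raise ParseError(f"{path}: beta outside [0,1] at line {int(out_of_range.idxmax()) + 1}")
    if (df["coverage"] < 0).any():
        bad = (df["coverage"] < 0).idxmax()
        raise ParseError(f"{path}: negative coverage at line {int(bad) + 1}")

    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["coverage"] = df["coverage"].astype(np.int64)
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    dup = df.duplicated(subset=["chrom", "start"], keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate CpG positions collapsed (keep-first)", path, int(dup.sum()))
        df = df[~dup].reset_index(drop=True)

    n_before = len(df)
    df = df[df["coverage"] >= min_coverage].reset_index(drop=True)
    logger.info(
        "%s: %d/%d CpGs retained at coverage >= %d", path, len(df), n_before, min_coverage
    )
    return df


def read_score_track(path) -> pd.DataFrame:
    """Read a per-CpG score track (chrom, start, end, score)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty score track")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected >=4 columns in score track")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "score"]
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def attach_scores(cpgs: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Left-join a score track onto a CpG frame by (chrom, start)."""
    merged = cpgs.drop(columns=["score"], errors="ignore").merge(
        scores[["chrom", "start", "score"]], on=["chrom", "start"], how="left"
    )
    n_missing = int(merged["score"].isna().sum())
    if n_missing:
        logger.warning("%d CpGs have no score after join", n_missing)
    return merged


def read_intervals(path) -> pd.DataFrame:
    """Read a BED3/BED4 file; sort and merge book-ended or overlapping entries.

    Returns a normalized frame (chrom, start, end). An empty file yields an
    empty frame with a warning; end <= start raises naming the line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty interval file", path)
        return intervals._empty()
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected >=3 columns in BED file")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ParseError(f"{path}: end <= start at line {int(bad.idxmax()) + 1}")
    merged = intervals.merge(df)
    if len(merged) < len(df):
        logger.info("%s: merged %d raw intervals into %d", path, len(df), len(merged))
    return merged


def read_labeled_intervals(path) -> pd.DataFrame:
    """BED4 reader keeping the label column (no merging across labels)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected >=4 columns (BED4)")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "label"]
    return intervals.validate(df)


def write_domains(domains: pd.DataFrame, path) -> None:
    """Write PMD/HMD domains as BED6.

    Columns: chrom, start, end, state, round(mean_beta*1000), strand ".".
    Domains must be non-overlapping per chromosome; output is sorted by
    (chrom, start).
    """
    path = Path(path)
    req = {"chrom", "start", "end", "state"}
    missing = req - set(domains.columns)
    if missing:
        raise ValueError(f"domain frame missing columns {sorted(missing)}")
    df = intervals.validate(domains)
    for chrom, sub in df.groupby("chrom"):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping domains on {chrom}")
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            mb = row.get("mean_beta", np.nan)
            score = int(round(mb * 1000)) if np.isfinite(mb) else 0
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row['state']}\t{score}\t.\n"
            )


def read_genome_sizes(path) -> dict:
    """Two-column chrom/length TSV -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1])
    return {str(c): int(l) for c, l in zip(df[0], df[1])}


def write_bedgraph(df: pd.DataFrame, path, value_col: str) -> None:
    sub = df.dropna(subset=[value_col])
    sub = sub.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        for _, row in sub.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{row[value_col]:.6g}\n"
            )
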