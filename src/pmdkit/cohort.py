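"""Multi-sample integration of PMD calls.

Per-sample PMD interval sets from two groups are combined on the breakpoint
partition of the genome (the resolution of bedtools multiinter): every atomic
segment carries the fraction of samples in each group whose PMDs cover it,
and categories follow from two thresholds —

* common in a group: occurrence >= 2/3 (inclusive);
* absent from a group: occurrence < 1/3 (strict).

shared PMD = common in both groups; group-specific PMD = common in one group
and absent from the other; shared HMD = absent from both. Segments matching
none of these are reported as ``unassigned`` rather than dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import intervals

logger = logging.getLogger(__name__)

CATEGORIES = ("shared_PMD", "groupA_specific_PMD", "groupB_specific_PMD",
              "shared_HMD", "unassigned")
COMMON_FRAC = 2.0 / 3.0
ABSENT_FRAC = 1.0 / 3.0


def occurrence_map(per_sample_domains: list) -> pd.DataFrame:
    """Piecewise-constant PMD occurrence fraction over the genome.

    Parameters
    ----------
    per_sample_domains
        One normalized PMD interval frame per sample.

    Returns
    -------
    Atomic segments (chrom, start, end) with ``occurrence`` = fraction of
    samples covering the segment. Segments covered by no sample are omitted
    (occurrence 0 by convention elsewhere).
    """
    if not per_sample_domains:
        raise ValueError("occurrence_map needs at least one sample")
    part = intervals.partition(per_sample_domains)
    n = len(per_sample_domains)
    if not len(part):
        return pd.DataFrame(columns=["chrom", "start", "end", "occurrence"])
    out = part[["chrom", "start", "end"]].copy()
    out["occurrence"] = part["count"] / n
    return out


def _occ_at(occ: pd.DataFrame, chrom: str, pos: int) -> float:
    sub = occ[occ["chrom"] == chrom]
    hit = sub[(sub["start"] <= pos) & (sub["end"] > pos)]
    return float(hit["occurrence"].iloc[0]) if len(hit) else 0.0


def categorize(
    occ_a: pd.DataFrame,
    occ_b: pd.DataFrame,
    common_frac: float = COMMON_FRAC,
    absent_frac: float = ABSENT_FRAC,
) -> pd.DataFrame:
    """Assign shared / group-specific / HMD categories on the joint partition.

    The two occurrence maps are refined on the union of their breakpoints so
    both fractions are constant on every atomic segment; adjacent segments
    with the same category merge (occurrence reported bp-weighted).
    """
    points: dict = {}
    for occ in (occ_a, occ_b):
        for chrom, sub in occ.groupby("chrom"):
            pts = points.setdefault(chrom, set())
            pts.update(sub["start"].tolist())
            pts.update(sub["end"].tolist())
    rows = []
    for chrom in sorted(points):
        bps = sorted(points[chrom])
        for lo, hi in zip(bps[:-1], bps[1:]):
            fa = _occ_at(occ_a, chrom, lo)
            fb = _occ_at(occ_b, chrom, lo)
            common_a = fa >= common_frac
            common_b = fb >= common_frac
            if common_a and common_b:
                cat = "shared_PMD"
            elif common_a and fb < absent_frac:
                cat = "groupA_specific_PMD"
            elif common_b and fa < absent_frac:
                cat = "groupB_specific_PMD"
            elif fa < absent_frac and fb < absent_frac:
                cat = "shared_HMD"
            else:
                cat = "unassigned"
            rows.append([chrom, lo, hi, cat, fa, fb])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "occA", "occB"])
    if not len(df):
        return df
    # merge adjacent same-category atoms
    merged = []
    for _, row in df.iterrows():
        if (
            merged
            and merged[-1][0] == row["chrom"]
            and merged[-1][2] == row["start"]
            and merged[-1][3] == row["category"]
        ):
            prev = merged[-1]
            w0 = prev[2] - prev[1]
            w1 = row["end"] - row["start"]
            prev[4] = (prev[4] * w0 + row["occA"] * w1) / (w0 + w1)
            prev[5] = (prev[5] * w0 + row["occB"] * w1) / (w0 + w1)
            prev[2] = row["end"]
        else:
            merged.append([row["chrom"], row["start"], row["end"],
                           row["category"], row["occA"], row["occB"]])
    return pd.DataFrame(merged, columns=df.columns)


def genome_fraction(
    domains: pd.DataFrame,
    genome_sizes: dict,
    blacklist: pd.DataFrame | None = None,
) -> float:
    """Fraction of the genome covered by the given domains.

    The denominator is the total length of the listed chromosomes, minus
    blacklist base pairs when a blacklist is supplied (the numerator is
    assumed already blacklist-subtracted upstream).
    """
    if len(domains):
        for chrom, sub in domains.groupby("chrom"):
            if chrom not in genome_sizes:
                raise ValueError(f"domain on unlisted chromosome {chrom}")
            if int(sub["end"].max()) > genome_sizes[chrom]:
                raise ValueError(f"domain beyond end of {chrom}")
    denom = sum(genome_sizes.values())
    if blacklist is not None and len(blacklist):
        bl = blacklist[blacklist["chrom"].isin(genome_sizes)]
        denom -= intervals.total_bp(bl)
        logger.info("genome_fraction: %d blacklist bp excluded from denominator",
                    intervals.total_bp(bl))
    return intervals.total_bp(domains) / denom if denom else 0.0


def evaluate_against_reference(
    called: pd.DataFrame,
    reference: pd.DataFrame,
    genome_sizes: dict | None = None,
) -> dict:
    """Base-pair precision / recall / F1 of called PMDs against a reference set.

    TP = bp in both sets, FP = called only, FN = reference only. Zero
    denominators yield 0 with ``undefined`` flagging which quantities were
    degenerate.
    """
    called_bp = intervals.total_bp(called)
    ref_bp = intervals.total_bp(reference)
    tp = intervals.intersect_bp(called, reference) if called_bp and ref_bp else 0
    fp = called_bp - tp
    fn = ref_bp - tp
    undefined = []
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    if not (tp + fp):
        undefined.append("precision")
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if not (tp + fn):
        undefined.append("recall")
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    if not (precision + recall):
        undefined.append("f1")
    return {
        "tp_bp": tp, "fp_bp": fp, "fn_bp": fn,
        "precision": precision, "recall": recall, "f1": f1,
        "undefined": undefined,
    }


def tile_overlap_matrix(
    per_sample_domains: dict,
    genome_sizes: dict,
    tile_bp: int = 30_000,
    top_k: int = 5000,
) -> pd.DataFrame:
    """Samples x tiles matrix of PMD-overlap fractions, top-k most variable.

    The genome is split into consecutive non-overlapping ``tile_bp`` tiles;
    each entry is the fraction of the tile covered by that sample's PMDs.
    Tiles are ranked by across-sample variance; ties at the cutoff break by
    genomic order. Column labels are ``chrom:start-end``.
    """
    if len(per_sample_domains) < 2:
        raise ValueError("tile_overlap_matrix needs >= 2 samples")
    tiles = []
    for chrom in sorted(genome_sizes):
        size = genome_sizes[chrom]
        for s in range(0, size, tile_bp):
            tiles.append((chrom, s, min(s + tile_bp, size)))
    sample_names = list(per_sample_domains)
    mat = np.zeros((len(sample_names), len(tiles)))
    for i, name in enumerate(sample_names):
        dom = intervals.merge(per_sample_domains[name])
        by_chrom = dict(tuple(dom.groupby("chrom"))) if len(dom) else {}
        for j, (chrom, s, e) in enumerate(tiles):
            sub = by_chrom.get(chrom)
            if sub is None:
                continue
            lo = np.maximum(sub["start"].to_numpy(), s)
            hi = np.minimum(sub["end"].to_numpy(), e)
            mat[i, j] = np.clip(hi - lo, 0, None).sum() / (e - s)
    var = mat.var(axis=0)
    # stable sort descending by variance keeps genomic order within ties
    order = np.argsort(-var, kind="stable")[: min(top_k, len(tiles))]
    order = np.sort(order)  # columns back in genomic order
    labels = [f"{c}:{s}-{e}" for c, s, e in tiles]
    return pd.DataFrame(mat[:, order], index=sample_names,
                        columns=[labels[j] for j in order])
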