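"""Per-CpG and per-window features for PMD calling.

The caller works on non-overlapping windows of 201 consecutive retained CpGs.
Each window carries three features:

* ``alpha`` — the maximum-likelihood shape of a symmetric Beta(alpha, alpha)
  fit to the window's methylation fractions. Polarized distributions (mass
  near 0 and 1, typical of highly methylated domains) give alpha < 1;
  intermediate, PMD-like distributions give alpha >= 1.
* ``pcc`` — Pearson correlation between a per-CpG hypomethylation score and
  observed methylation. Inside PMDs, loss-prone (high-score) CpGs have lost
  more methylation, so the correlation is strongly negative; in highly
  methylated background it is near zero.
* ``m_value`` — log2(b/(1-b)) of the window's mean methylation, dispersing
  values near the boundaries; it rescues samples with extreme global loss
  where both alpha and pcc lose their signal.

Solo CpGs (<= 2 neighbours within a centered 151-bp window) exclude CpG-island
context and are the sites most prone to mitotic methylation loss; they drive
both model selection and the solo-WCGW region summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln

logger = logging.getLogger(__name__)

ALPHA_BOUNDS = (0.01, 100.0)
MIN_WINDOW_VALUES = 10


def find_solo_cpgs(
    positions: np.ndarray, window_bp: int = 151, max_neighbors: int = 2
) -> np.ndarray:
    """Mask of solo CpGs for one chromosome's sorted positions.

    A CpG is solo iff at most ``max_neighbors`` *other* CpGs lie within
    +/- (window_bp-1)/2 bp of it (ties at the boundary count as neighbours).
    """
    positions = np.asarray(positions)
    if len(positions) > 1 and (np.diff(positions) < 0).any():
        raise ValueError("positions must be sorted ascending")
    if window_bp % 2 != 1:
        raise ValueError("window_bp must be odd (window centered on the CpG)")
    half = (window_bp - 1) // 2
    left = np.searchsorted(positions, positions - half, side="left")
    right = np.searchsorted(positions, positions + half, side="right")
    n_neighbors = right - left - 1  # exclude the CpG itself
    return n_neighbors <= max_neighbors


def solo_mask(
    cpgs: pd.DataFrame,
    window_bp: int = 151,
    max_neighbors: int = 2,
    reference_positions: dict | None = None,
) -> np.ndarray:
    """Solo mask across a multi-chromosome CpG frame (sorted by chrom, start).

    Solo status is a property of the CpG landscape, not of which sites
    survived a coverage filter: when ``reference_positions`` (chrom -> sorted
    positions of *all* CpGs) is given, neighbours are counted against it, so
    a cluster member whose neighbours were dropped for low coverage does not
    masquerade as isolated.
    """
    mask = np.zeros(len(cpgs), dtype=bool)
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["start"].to_numpy()
        if reference_positions is None:
            mask[idx] = find_solo_cpgs(pos, window_bp, max_neighbors)
        else:
            ref = np.asarray(reference_positions.get(chrom, pos))
            half = (window_bp - 1) // 2
            left = np.searchsorted(ref, pos - half, side="left")
            right = np.searchsorted(ref, pos + half, side="right")
            present = ref[np.clip(np.searchsorted(ref, pos), 0, max(len(ref) - 1, 0))] == pos \
                if len(ref) else np.zeros(len(pos), dtype=bool)
            n_neighbors = right - left - present.astype(int)
            mask[idx] = n_neighbors <= max_neighbors
    return mask


_W = frozenset("ATat")


def wcgw_proxy_score(fasta, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Flanking-base proxy for the per-CpG hypomethylation score.

    For a CpG whose C is at ``pos`` the flanks are the bases at pos-1 and
    pos+2. Both flanks W (A/T) -> 1.0 (the WCGW context most prone to
    methylation loss), one W -> 0.5, none -> 0.0; an N flank -> NaN.

    ``fasta`` is a pyfaidx.Fasta-like mapping of chromosome name to sequence.
    """
    seq = fasta[chrom]
    n = len(seq)
    out = np.empty(len(positions), dtype=float)
    for i, pos in enumerate(np.asarray(positions)):
        if pos - 1 < 0 or pos + 2 >= n:
            raise ValueError(f"CpG at {chrom}:{pos} too close to chromosome edge for flanks")
        left = str(seq[pos - 1 : pos]).upper()
        right = str(seq[pos + 2 : pos + 3]).upper()
        if left not in "ATCG" or right not in "ATCG":
            out[i] = np.nan
            continue
        out[i] = 0.5 * ((left in _W) + (right in _W))
    return out


def make_windows(cpgs: pd.DataFrame, window_cpgs: int = 201) -> list:
    """Partition retained CpGs into consecutive non-overlapping index blocks.

    Returns a list of (chrom, lo, hi) where lo:hi index into ``cpgs`` (which
    must be sorted by chrom, start). The terminal remainder of a chromosome is
    kept as its own window when it has at least half a window of CpGs, else it
    is merged into the preceding window. Chromosomes with fewer than half a
    window of CpGs are skipped with a warning. Windows never span chromosomes.
    """
    half = window_cpgs / 2
    blocks = []
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if (np.diff(idx) != 1).any():
            raise ValueError("CpG frame index must be contiguous per chromosome")
        n = len(idx)
        if n < half:
            logger.warning("%s: only %d CpGs (< half a window); skipped", chrom, n)
            continue
        n_full = n // window_cpgs
        rem = n - n_full * window_cpgs
        bounds = [i * window_cpgs for i in range(n_full + 1)]
        if rem >= half or n_full == 0:
            bounds.append(n)
        else:
            bounds[-1] = n  # merge remainder into the last full window
        base = idx[0]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            blocks.append((chrom, base + lo, base + hi))
    return blocks


def alpha_score(betas: np.ndarray, smoothing_eps: float = 1e-3) -> float:
    """Maximum-likelihood alpha of a symmetric Beta(alpha, alpha) density.

    Betas are clamped to [eps, 1-eps] before likelihood evaluation; the MLE is
    found by bounded scalar optimization on [0.01, 100] and is deterministic.
    Returns NaN for fewer than 10 values (undefined-feature flag).
    """
    b = np.asarray(betas, dtype=float)
    if len(b) < MIN_WINDOW_VALUES:
        return np.nan
    b = np.clip(b, smoothing_eps, 1 - smoothing_eps)
    s = float(np.sum(np.log(b) + np.log1p(-b)))
    n = len(b)

    def nll(a: float) -> float:
        return n * betaln(a, a) - (a - 1.0) * s

    res = minimize_scalar(nll, bounds=ALPHA_BOUNDS, method="bounded", options={"xatol": 1e-8})
    return float(res.x)


def pcc_score(scores: np.ndarray, betas: np.ndarray) -> tuple:
    """Pearson correlation between score and methylation over one window.

    Pairs with NaN score are dropped. Returns (value, defined): fewer than 10
    usable pairs -> (NaN, False); zero variance in either vector -> the
    defined-fallback (0.0, False) so the genome partition stays contiguous.
    """
    s = np.asarray(scores, dtype=float)
    b = np.asarray(betas, dtype=float)
    keep = np.isfinite(s) & np.isfinite(b)
    s, b = s[keep], b[keep]
    if len(s) < MIN_WINDOW_VALUES:
        return np.nan, False
    if np.ptp(s) == 0 or np.ptp(b) == 0:
        return 0.0, False
    s = s - s.mean()
    b = b - b.mean()
    r = float(np.dot(s, b) / np.sqrt(np.dot(s, s) * np.dot(b, b)))
    return min(1.0, max(-1.0, r)), True


def m_value(mean_beta: float, eps: float = 0.01) -> float:
    """logit2 of a methylation fraction, clamped to [eps, 1-eps]."""
    b = min(max(float(mean_beta), eps), 1 - eps)
    return float(np.log2(b / (1 - b)))


@dataclass
class FeatureConfig:
    window_cpgs: int = 201
    solo_window_bp: int = 151
    max_neighbors: int = 2
    alpha_eps: float = 1e-3
    mvalue_eps: float = 0.01
    #: "solo": windows are built over solo CpGs only, excluding island-like
    #: dense context from all three features; "all": windows over every
    #: retained CpG.
    windows_on: str = "solo"


def window_features(cpgs: pd.DataFrame, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Compute the per-window feature table for a coverage-filtered CpG frame.

    The frame must be sorted by (chrom, start) with a RangeIndex and may carry
    a ``score`` column; without one, pcc is undefined everywhere and the
    segmentation degrades to an alpha+M model.

    Window spans are made contiguous within a chromosome: a window runs from
    its first CpG to the next window's first CpG (the chromosome's last window
    ends after its last CpG), so that domains assembled from window runs tile
    the windowed portion of the genome without gaps.

    Returns columns: chrom, start, end, n_cpgs, alpha, pcc, pcc_defined,
    mean_beta, m_value.
    """
    cfg = config or FeatureConfig()
    cpgs = cpgs.reset_index(drop=True)
    has_score = "score" in cpgs.columns
    blocks = make_windows(cpgs, cfg.window_cpgs)
    pos = cpgs["start"].to_numpy()
    betas_all = cpgs["beta"].to_numpy()
    rows = []
    for k, (chrom, lo, hi) in enumerate(blocks):
        betas = betas_all[lo:hi]
        start = int(pos[lo])
        last_in_chrom = k + 1 >= len(blocks) or blocks[k + 1][0] != chrom
        end = int(pos[hi - 1]) + 2 if last_in_chrom else int(pos[blocks[k + 1][1]])
        alpha = alpha_score(betas, cfg.alpha_eps)
        if has_score:
            pcc, pcc_defined = pcc_score(cpgs["score"].to_numpy()[lo:hi], betas)
        else:
            pcc, pcc_defined = np.nan, False
        mb = float(np.mean(betas)) if len(betas) else np.nan
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_cpgs": hi - lo,
                "alpha": alpha,
                "pcc": pcc,
                "pcc_defined": pcc_defined,
                "mean_beta": mb,
                "m_value": m_value(mb, cfg.mvalue_eps),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_cpgs", "alpha", "pcc", "pcc_defined",
            "mean_beta", "m_value",
        ],
    )
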