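"""Synthetic WGBS methylome generator with known PMD/HMD architecture.

The generator emulates the data regime the caller is designed for:

* a 10-Mb two-chromosome genome with ~50k CpGs (mean spacing 200 bp), laid
  down as isolated "solo" CpGs interspersed with dense CpG clusters (the
  island-like context the solo rule excludes);
* a domain architecture drawn by allocating a fixed genome-wide PMD budget
  (target fraction 0.4) across Gamma-distributed segment lengths, with each
  PMD segment assigned to shared / group-A-specific / group-B-specific
  status so all four multi-sample categories are populated;
* per-sample boundary jitter ("breadth" heterogeneity) and per-sample
  methylation depth, including an extreme-loss regime (PMD mean beta 0.03)
  in which the alpha and correlation features are expected to fail and the
  M-value must carry the signal;
* a per-CpG hypomethylation score in [0, 1] standing in for a
  sequence-derived loss-propensity score: high-scoring CpGs lose extra
  methylation inside PMDs only, producing the negative score-methylation
  correlation the PCC feature detects;
* beta-distributed latent methylation (broader within PMDs), Gamma-Poisson
  (negative-binomial) read depth, and binomial read sampling.

All randomness flows from ``config.seed`` through named substreams, so one
seed fully determines every emitted file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import intervals

logger = logging.getLogger(__name__)

EXTREME_PMD_BETA = 0.03  # depth used when the extreme-loss flag is set


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic methylome."""

    seed: int = 0
    chromosomes: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    mean_cpg_spacing_bp: float = 200.0
    solo_fraction: float = 0.5
    cluster_size: int = 4
    cluster_gap_bp: int = 20
    min_unit_gap_bp: int = 80
    pmd_fraction: float = 0.4
    mean_pmd_length_bp: float = 800_000.0
    pmd_mean_beta: float = 0.6
    hmd_mean_beta: float = 0.85
    island_beta: float = 0.1
    #: Fraction of solo CpGs that are constitutively lowly methylated
    #: (regulatory elements, island shores): this is what makes the HMD
    #: methylation distribution polarized rather than unimodal-high.
    low_solo_fraction: float = 0.15
    low_solo_beta: float = 0.1
    pmd_concentration: float = 8.0
    hmd_concentration: float = 20.0
    wcgw_fraction: float = 0.35
    score_effect: float = 0.3
    coverage_mean: float = 10.0
    coverage_dispersion: float = 8.0
    samples_per_group: tuple = (3, 3)
    breadth_overlap: float = 0.9
    extreme_loss: bool = False

    def __post_init__(self):
        for name in ("solo_fraction", "pmd_fraction", "wcgw_fraction", "breadth_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("pmd_mean_beta", "hmd_mean_beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if any(n <= 0 for n in self.samples_per_group):
            raise ValueError("samples_per_group entries must be positive")
        if self.pmd_fraction == 0:
            raise ValueError("pmd_fraction 0 cannot host the required PMD categories")

    @property
    def effective_pmd_beta(self) -> float:
        return EXTREME_PMD_BETA if self.extreme_loss else self.pmd_mean_beta

    @property
    def sample_names(self) -> list:
        na, nb = self.samples_per_group
        return [f"A{i + 1}" for i in range(na)] + [f"B{i + 1}" for i in range(nb)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples_per_group"] = list(self.samples_per_group)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        if "samples_per_group" in d:
            d["samples_per_group"] = tuple(d["samples_per_group"])
        return cls(**d)


@dataclass
class Architecture:
    """Genome layout and ground truth shared by all samples of a cohort."""

    config: SimulationConfig
    positions: dict          # chrom -> sorted CpG starts
    scores: dict             # chrom -> per-CpG score in [0, 1]
    solo: dict               # chrom -> per-CpG bool (isolated CpG)
    low_solo: dict           # chrom -> per-CpG bool (constitutively unmethylated)
    master_pmds: pd.DataFrame   # chrom/start/end/category (shared|A|B)
    sample_pmds: dict        # sample name -> PMD interval frame
    categories: pd.DataFrame    # full-genome category map incl. shared_HMD

    def truth_for_group(self, group: str) -> pd.DataFrame:
        """Union PMD set a group's samples are drawn around (shared + own)."""
        cats = ("shared", group)
        return self.master_pmds[self.master_pmds["category"].isin(cats)][
            ["chrom", "start", "end"]
        ].reset_index(drop=True)


def _cpg_landscape(config: SimulationConfig, rng: np.random.Generator):
    """CpG positions, scores and solo flags for every chromosome.

    CpGs arrive in "units": a singleton (always solo — units are kept at
    least ``min_unit_gap_bp`` apart, beyond the 75-bp neighbour radius) or a
    cluster of ``cluster_size`` CpGs at ``cluster_gap_bp`` spacing (all
    non-solo). The singleton share is chosen so the realized solo fraction
    matches ``solo_fraction``.
    """
    k = config.cluster_size
    s = config.solo_fraction
    u = k * s / (1 + (k - 1) * s) if s > 0 else 0.0  # P(unit is a singleton)
    cpgs_per_unit = u + k * (1 - u)
    mean_unit_span = (1 - u) * (k - 1) * config.cluster_gap_bp
    mean_gap = config.mean_cpg_spacing_bp * cpgs_per_unit - mean_unit_span
    geo_mean = max(mean_gap - config.min_unit_gap_bp, 1.0)
    positions, scores, solo, low_solo = {}, {}, {}, {}
    for chrom, length in config.chromosomes.items():
        pos_list, score_list, solo_list, low_list = [], [], [], []
        pos = int(config.min_unit_gap_bp)
        while True:
            pos += config.min_unit_gap_bp + int(rng.geometric(1.0 / geo_mean))
            if pos + 2 >= length - 2:
                break
            if rng.random() < u:
                pos_list.append(pos)
                if rng.random() < config.wcgw_fraction:
                    score_list.append(rng.uniform(0.7, 1.0))
                else:
                    score_list.append(rng.uniform(0.0, 0.7))
                solo_list.append(True)
                low_list.append(rng.random() < config.low_solo_fraction)
            else:
                for j in range(k):
                    p = pos + j * config.cluster_gap_bp
                    if p + 2 >= length - 2:
                        break
                    pos_list.append(p)
                    score_list.append(rng.uniform(0.0, 0.3))
                    solo_list.append(False)
                    low_list.append(False)
                pos = pos_list[-1]
        positions[chrom] = np.array(pos_list, dtype=np.int64)
        scores[chrom] = np.array(score_list)
        solo[chrom] = np.array(solo_list, dtype=bool)
        low_solo[chrom] = np.array(low_list, dtype=bool)
    return positions, scores, solo, low_solo


def _segment_chromosome(length: int, config: SimulationConfig, rng: np.random.Generator):
    """PMD intervals on one chromosome: fixed PMD budget, Gamma-length segments."""
    budget = length * config.pmd_fraction
    n_pmd = max(1, int(round(budget / config.mean_pmd_length_bp)))
    pmd_w = rng.gamma(4.0, 1.0, size=n_pmd)
    pmd_len = pmd_w / pmd_w.sum() * budget
    gap_w = rng.gamma(4.0, 1.0, size=n_pmd + 1)
    gap_len = gap_w / gap_w.sum() * (length - budget)
    segs = []
    pos = 0.0
    for i in range(n_pmd):
        pos += gap_len[i]
        start = int(round(pos))
        pos += pmd_len[i]
        end = int(round(pos))
        if end > start:
            segs.append((start, min(end, length)))
    return segs


def simulate_architecture(config: SimulationConfig) -> Architecture:
    """Draw the CpG landscape, domain architecture and per-sample PMD sets."""
    rng = np.random.default_rng([config.seed, 0])
    positions, scores, solo, low_solo = _cpg_landscape(config, rng)

    rows = []
    for chrom, length in config.chromosomes.items():
        for start, end in _segment_chromosome(length, config, rng):
            rows.append({"chrom": chrom, "start": start, "end": end})
    master = pd.DataFrame(rows)
    cats = list(rng.choice(["shared", "A", "B"], size=len(master), p=[0.5, 0.25, 0.25]))
    # guarantee every category exists (genomic-order deterministic fallback)
    if len(master) >= 3:
        for j, needed in enumerate(["shared", "A", "B"]):
            if needed not in cats:
                cats[j] = needed
    else:
        raise ValueError(
            f"only {len(master)} PMD segments; need >= 3 to host shared and "
            "both group-specific categories (raise pmd_fraction or genome size)"
        )
    master["category"] = cats

    jitter_sd = (1.0 - config.breadth_overlap) * 50_000.0
    na, nb = config.samples_per_group
    sample_pmds = {}
    for si, name in enumerate(config.sample_names):
        group = "A" if si < na else "B"
        own = master[master["category"].isin(("shared", group))]
        srng = np.random.default_rng([config.seed, 100 + si])
        recs = []
        for _, row in own.iterrows():
            length = config.chromosomes[row["chrom"]]
            if jitter_sd > 0:
                s = int(round(row["start"] + srng.normal(0, jitter_sd)))
                e = int(round(row["end"] + srng.normal(0, jitter_sd)))
            else:
                s, e = int(row["start"]), int(row["end"])
            s = max(0, min(s, length))
            e = max(0, min(e, length))
            if e > s:
                recs.append({"chrom": row["chrom"], "start": s, "end": e})
        sample_pmds[name] = intervals.merge(pd.DataFrame(recs))

    cat_map = {"shared": "shared_PMD", "A": "groupA_specific_PMD", "B": "groupB_specific_PMD"}
    cat_rows = []
    for chrom, length in config.chromosomes.items():
        sub = master[master["chrom"] == chrom].sort_values("start")
        prev = 0
        for _, row in sub.iterrows():
            if row["start"] > prev:
                cat_rows.append([chrom, prev, row["start"], "shared_HMD"])
            cat_rows.append([chrom, row["start"], row["end"], cat_map[row["category"]]])
            prev = row["end"]
        if prev < length:
            cat_rows.append([chrom, prev, length, "shared_HMD"])
    categories = pd.DataFrame(cat_rows, columns=["chrom", "start", "end", "category"])

    return Architecture(
        config=config, positions=positions, scores=scores, solo=solo,
        low_solo=low_solo, master_pmds=master, sample_pmds=sample_pmds,
        categories=categories,
    )


def simulate_track(arch: Architecture, sample_name: str) -> pd.DataFrame:
    """Per-CpG methylation track for one sample.

    Latent methylation is the HMD mean outside the sample's PMDs; inside, the
    PMD depth minus ``score_effect`` x score, clamped to [0.01, 0.99]. Island
    clusters and the flagged low-solo CpGs override this with their
    constitutive low level. A beta draw around the latent mean
    (state-specific concentration) gives the true per-CpG methylation
    probability; coverage is Gamma-Poisson and the observed beta is a
    binomial read fraction. Zero-coverage CpGs are not emitted (their beta
    is undefined).
    """
    config = arch.config
    si = config.sample_names.index(sample_name)
    rng = np.random.default_rng([config.seed, 1000 + si])
    pmds = arch.sample_pmds[sample_name]
    depth = config.effective_pmd_beta
    frames = []
    for chrom in config.chromosomes:
        pos = arch.positions[chrom]
        score = arch.scores[chrom]
        sub = pmds[pmds["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(starts):
            i = np.searchsorted(starts, pos, side="right") - 1
            in_pmd = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        else:
            in_pmd = np.zeros(len(pos), dtype=bool)
        latent = np.where(
            in_pmd,
            np.clip(depth - config.score_effect * score, 0.01, 0.99),
            config.hmd_mean_beta,
        )
        # dense CpG clusters emulate unmethylated island context in either
        # domain state
        latent = np.where(arch.solo[chrom], latent, config.island_beta)
        # constitutively unmethylated solo CpGs (regulatory context) keep the
        # HMD beta distribution polarized rather than unimodal-high
        latent = np.where(arch.low_solo[chrom], config.low_solo_beta, latent)
        conc = np.where(in_pmd, config.pmd_concentration, config.hmd_concentration)
        p = rng.beta(latent * conc, (1 - latent) * conc)
        lam = rng.gamma(config.coverage_dispersion,
                        config.coverage_mean / config.coverage_dispersion, size=len(pos))
        cov = rng.poisson(lam)
        meth = rng.binomial(cov, p)
        keep = cov > 0
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": pos[keep],
            "end": pos[keep] + 2,
            "beta": meth[keep] / cov[keep],
            "coverage": cov[keep],
            "score": score[keep],
        }))
    return pd.concat(frames, ignore_index=True)


def write_track(track: pd.DataFrame, path, with_score: bool = False) -> None:
    cols = ["chrom", "start", "end", "beta", "coverage"] + (["score"] if with_score else [])
    with open(path, "w") as fh:
        for row in track[cols].itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end)),
                      f"{row.beta:.6f}", str(int(row.coverage))]
            if with_score:
                fields.append(f"{row.score:.6f}")
            fh.write("\t".join(fields) + "\n")


def write_score_track(arch: Architecture, path) -> None:
    with open(path, "w") as fh:
        for chrom in arch.config.chromosomes:
            for pos, sc in zip(arch.positions[chrom], arch.scores[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 2}\t{sc:.6f}\n")


def write_fasta(arch: Architecture, path, line_width: int = 80) -> None:
    """Emit a genome FASTA whose CG flanks encode each CpG's score.

    Background sequence is strong (G/C) so spurious CG dinucleotides carry
    low proxy scores; at each simulated CpG the CG flanks are W/W, W/S or S/S
    according to whether its score is high (>= 0.75), middling or low, making
    the flanking-base proxy score reproduce the simulated score classes.
    """
    rng = np.random.default_rng([arch.config.seed, 7])
    with open(path, "w") as fh:
        for chrom, length in arch.config.chromosomes.items():
            seq = rng.choice(np.array(list("GCT"), dtype="U1"), size=length)
            # avoid accidental CG dinucleotides in the background
            cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
            seq[cg] = "T"
            for pos, sc in zip(arch.positions[chrom], arch.scores[chrom]):
                seq[pos], seq[pos + 1] = "C", "G"
                if sc >= 0.75:
                    flanks = ("A", "T")
                elif sc >= 0.25:
                    flanks = ("A", "G")
                else:
                    flanks = ("G", "C")
                if pos - 1 >= 0:
                    seq[pos - 1] = flanks[0]
                if pos + 2 < length:
                    seq[pos + 2] = flanks[1]
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i : i + line_width] + "\n")


def simulate_cohort(config: SimulationConfig, outdir, overwrite: bool = False) -> dict:
    """Write a full multi-sample dataset plus ground truth; returns file paths.

    Two invocations with the same config produce byte-identical files.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    arch = simulate_architecture(config)
    paths = {"outdir": str(outdir), "tracks": {}, "truth_pmds": {}}
    for name in config.sample_names:
        track = simulate_track(arch, name)
        tpath = outdir / f"{name}.cpg.tsv"
        write_track(track, tpath)
        paths["tracks"][name] = str(tpath)
        bpath = outdir / f"truth_{name}.pmd.bed"
        with open(bpath, "w") as fh:
            for row in arch.sample_pmds[name].itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tPMD\n")
        paths["truth_pmds"][name] = str(bpath)
    spath = outdir / "scores.tsv"
    write_score_track(arch, spath)
    paths["scores"] = str(spath)
    cpath = outdir / "truth_categories.bed"
    with open(cpath, "w") as fh:
        for row in arch.categories.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.category}\n")
    paths["categories"] = str(cpath)
    ypath = outdir / "config.yaml"
    with open(ypath, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    paths["config"] = str(ypath)
    gpath = outdir / "genome.sizes"
    with open(gpath, "w") as fh:
        for chrom, length in config.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["genome_sizes"] = str(gpath)
    logger.info("simulated cohort with %d samples in %s", len(config.sample_names), outdir)
    return paths
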