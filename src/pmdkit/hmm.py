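"""Two-state HMM segmentation of window features into PMD and HMD domains.

The workflow per sample:

1. :func:`select_model` — decide between the 2D feature model (alpha, pcc)
   and the 3D model (alpha, pcc, M-value) from the genome-wide distribution
   of solo-CpG methylation: if the bottom 10th percentile of solo-CpG betas
   falls below 0.025 the sample is in the extreme-loss regime, where alpha
   and pcc lose their contrast and the M-value is needed.
2. :func:`fit_hmm` — fit a 2-state Gaussian-emission HMM (full covariance) by
   EM on z-scored window features, concatenating chromosomes without
   transitions across their boundaries. Initialization is a deterministic
   median split on alpha; an optional multi-restart mode perturbs it.
3. :func:`decode` — Viterbi state path per chromosome; windows with undefined
   features inherit the nearest defined neighbour's state.
4. :func:`windows_to_domains` — run-length merge of window labels into
   domains, with optional absorption of short runs.
5. :func:`subtract_blacklist` — interval difference against blacklist regions.

:class:`PMDModel` / :class:`PMDResults` wrap these steps in a fit/results
pair for interactive use; the functions remain the stable low-level API.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

from . import intervals
from .features import FeatureConfig, solo_mask, window_features

logger = logging.getLogger(__name__)

STATE_NAMES = ("PMD", "HMD")
FEATURES_2D = ("alpha", "pcc")
FEATURES_3D = ("alpha", "pcc", "m_value")
#: Fallback when no per-CpG score is available: pcc cannot be computed and the
#: emission degrades to (alpha, M-value).
FEATURES_NO_SCORE = ("alpha", "m_value")

MIN_FIT_WINDOWS = 50
MIN_SOLO_SITES = 1000
COV_REG = 1e-6


class DegenerateStateError(RuntimeError):
    """One HMM state captured (almost) no windows; try the other 2D/3D model."""


def select_model(
    solo_betas: np.ndarray,
    percentile: float = 10.0,
    threshold: float = 0.025,
    min_sites: int = MIN_SOLO_SITES,
) -> int:
    """Choose the feature-model dimensionality (2 or 3) for a sample.

    Returns 3 iff the ``percentile``-th percentile (linear interpolation) of
    the genome-wide solo-CpG methylation values is strictly below
    ``threshold`` — the extreme-methylation-loss regime — else 2. Fewer than
    ``min_sites`` values: warn and default to 2.
    """
    b = np.asarray(solo_betas, dtype=float)
    b = b[np.isfinite(b)]
    if len(b) == 0:
        raise ValueError("select_model: no solo-CpG methylation values")
    if len(b) < min_sites:
        logger.warning(
            "select_model: only %d solo CpGs (< %d); defaulting to the 2D model",
            len(b), min_sites,
        )
        return 2
    q = float(np.quantile(b, percentile / 100.0))
    dim = 3 if q < threshold else 2
    logger.info(
        "select_model: %d solo CpGs, %.0fth percentile = %.4f (threshold %.3f) -> %dD",
        len(b), percentile, q, threshold, dim,
    )
    return dim


@dataclass
class SegmentationModel:
    """Fitted 2-state segmentation HMM. State 0 is always PMD, state 1 HMD."""

    features: tuple
    means: np.ndarray          # (2, dim), original feature units
    covars: np.ndarray         # (2, dim, dim), original feature units
    transmat: np.ndarray       # (2, 2) row-stochastic
    startprob: np.ndarray      # (2,)
    feat_mean: np.ndarray      # standardization constants
    feat_std: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = True
    seed: int = 0
    n_iter: int = 0

    @property
    def dim(self) -> int:
        return len(self.features)

    def __post_init__(self):
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities must sum to 1")

    def _to_hmmlearn(self) -> GaussianHMM:
        """Rebuild an hmmlearn model in standardized feature space."""
        m = GaussianHMM(n_components=2, covariance_type="full", init_params="", params="")
        m.startprob_ = self.startprob.copy()
        m.transmat_ = self.transmat.copy()
        m.means_ = (self.means - self.feat_mean) / self.feat_std
        scale = np.outer(1.0 / self.feat_std, 1.0 / self.feat_std)
        m.covars_ = np.array([c * scale for c in self.covars])
        return m

    def to_json(self, path=None) -> str:
        payload = {
            "state_names": list(STATE_NAMES),
            "features": list(self.features),
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "n_iter": int(self.n_iter),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SegmentationModel":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                payload = json.load(fh)
        elif isinstance(source, (str, bytes)):
            payload = json.loads(source)
        else:
            payload = json.load(source)
        return cls(
            features=tuple(payload["features"]),
            means=np.array(payload["means"]),
            covars=np.array(payload["covars"]),
            transmat=np.array(payload["transmat"]),
            startprob=np.array(payload["startprob"]),
            feat_mean=np.array(payload["feat_mean"]),
            feat_std=np.array(payload["feat_std"]),
            loglik_trace=payload.get("loglik_trace", []),
            converged=payload.get("converged", True),
            seed=payload.get("seed", 0),
            n_iter=payload.get("n_iter", 0),
        )


class _RelTolMonitor(ConvergenceMonitor):
    """Relative log-likelihood convergence with a full iteration trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.trace: list = []

    def report(self, log_prob):
        self.trace.append(float(log_prob))
        super().report(log_prob)

    @property
    def converged(self):
        if self.iter == self.n_iter:
            return True
        if len(self.trace) < 2:
            return False
        prev, cur = self.trace[-2], self.trace[-1]
        return (cur - prev) / max(abs(prev), 1e-300) < self.tol


def _defined_mask(windows: pd.DataFrame, features: tuple) -> np.ndarray:
    mask = np.ones(len(windows), dtype=bool)
    for f in features:
        mask &= np.isfinite(windows[f].to_numpy(dtype=float))
        if f == "pcc":
            mask &= windows["pcc_defined"].to_numpy(dtype=bool)
    return mask


def _sequences(windows: pd.DataFrame, mask: np.ndarray, features: tuple):
    """Concatenate per-chromosome defined-window feature rows for hmmlearn."""
    X_parts, lengths, index_parts = [], [], []
    F = windows.loc[:, list(features)].to_numpy(dtype=float)
    for _, sub in windows.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        keep = idx[mask[idx]]
        if len(keep) == 0:
            continue
        X_parts.append(F[keep])
        lengths.append(len(keep))
        index_parts.append(keep)
    if not X_parts:
        return np.empty((0, len(features))), [], np.array([], dtype=int)
    return np.vstack(X_parts), lengths, np.concatenate(index_parts)


def fit_hmm(
    windows: pd.DataFrame,
    dim: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 1,
    features: tuple | None = None,
) -> SegmentationModel:
    """Fit the 2-state Gaussian HMM to window features by EM.

    Features are z-scored with global mean/sd (stored on the model for
    decoding). Restart 0 initializes deterministically from a median split on
    alpha (high-alpha windows seed the PMD-candidate state); additional
    restarts perturb the initial means with the seeded RNG and the best
    log-likelihood wins. The EM log-likelihood trace is checked to be
    non-decreasing. Chromosome boundaries reset the chain.
    """
    if features is None:
        features = FEATURES_2D if dim == 2 else FEATURES_3D
    if len(features) != dim:
        raise ValueError(f"dim={dim} but {len(features)} features given")
    mask = _defined_mask(windows, features)
    X, lengths, _ = _sequences(windows, mask, features)
    if len(X) < MIN_FIT_WINDOWS:
        raise ValueError(
            f"fit_hmm needs >= {MIN_FIT_WINDOWS} windows with defined features, got {len(X)}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    alpha = windows.loc[mask, "alpha"].to_numpy(dtype=float)
    med = np.median(alpha)
    hi = alpha >= med
    if hi.sum() < 3 or (~hi).sum() < 3:
        raise DegenerateStateError(
            "median-alpha split is degenerate (identical features?); "
            "cannot initialize the HMM"
        )

    def initial_means():
        return np.array([Z[hi].mean(axis=0), Z[~hi].mean(axis=0)])

    def initial_covars():
        covs = []
        for sel in (hi, ~hi):
            c = np.cov(Z[sel].T) if sel.sum() > 1 else np.eye(len(features))
            c = np.atleast_2d(c) + COV_REG * np.eye(len(features))
            covs.append(c)
        return np.array(covs)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        m = GaussianHMM(
            n_components=2, covariance_type="full",
            n_iter=max_iter, tol=tol, init_params="", params="stmc",
            min_covar=COV_REG, random_state=seed,
        )
        m.monitor_ = _RelTolMonitor(tol, max_iter)
        m.startprob_ = np.array([0.5, 0.5])
        m.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        means0 = initial_means()
        if restart > 0:
            means0 = means0 + rng.normal(0.0, 0.25, size=means0.shape)
        m.means_ = means0
        m.covars_ = initial_covars()
        try:
            m.fit(Z, lengths)
        except np.linalg.LinAlgError as err:
            raise DegenerateStateError(f"EM failed on singular covariance: {err}") from err
        trace = list(m.monitor_.trace)
        # Exact monotonicity can break at machine-noise level once covariance
        # flooring kicks in; clip a tiny terminal dip, refuse a real decrease.
        while len(trace) >= 2 and trace[-1] < trace[-2]:
            if trace[-2] - trace[-1] > 1e-3 * max(1.0, abs(trace[-2])):
                raise AssertionError("EM log-likelihood decreased")
            trace.pop()
        if any(b < a - 1e-6 * max(1.0, abs(a)) for a, b in zip(trace, trace[1:])):
            raise AssertionError("EM log-likelihood decreased")
        ll = trace[-1] if trace else -np.inf
        if best is None or ll > best[0]:
            best = (ll, m, trace)
    ll, m, trace = best

    labels = np.concatenate(
        [m.predict(Z[o : o + n]) for o, n in zip(np.cumsum([0] + lengths[:-1]), lengths)]
    )
    counts = np.bincount(labels, minlength=2)
    if counts.min() <= 2:
        raise DegenerateStateError(
            f"state occupancy {counts.tolist()}: one state is (near) empty; "
            "consider switching between the 2D and 3D model"
        )

    # State identifiability uses only the model's own emission features.
    # Without an M-value dimension the alpha semantics of the field apply:
    # PMD is the state with larger mean alpha (intermediate methylation).
    # That rule is exactly what breaks under extreme methylation loss, where
    # PMD betas collapse to a polarized-at-zero distribution with alpha < 1;
    # a model carrying the M-value dimension therefore labels PMD as the
    # lower-M (lower-methylation) state instead.
    if "m_value" in features:
        j = features.index("m_value")
        pmd_state = int(np.argmin(m.means_[:, j]))
        if np.isclose(m.means_[0, j], m.means_[1, j]):
            ja = features.index("alpha")
            pmd_state = int(np.argmax(m.means_[:, ja]))
    else:
        ja = features.index("alpha")
        pmd_state = int(np.argmax(m.means_[:, ja]))
        if np.isclose(m.means_[0, ja], m.means_[1, ja]):
            mb = windows.loc[mask, "mean_beta"].to_numpy(dtype=float)
            state_mb = np.array([mb[labels == k].mean() for k in (0, 1)])
            pmd_state = int(np.argmin(state_mb))
    order = [pmd_state, 1 - pmd_state]

    means_std = m.means_[order]
    covars_std = m.covars_[order]
    converged = len(trace) < max_iter
    if not converged:
        logger.warning("fit_hmm: EM reached max_iter=%d without converging", max_iter)
    return SegmentationModel(
        features=tuple(features),
        means=means_std * sd + mu,
        covars=np.array([c * np.outer(sd, sd) for c in covars_std]),
        transmat=m.transmat_[np.ix_(order, order)],
        startprob=m.startprob_[order],
        feat_mean=mu,
        feat_std=sd,
        loglik_trace=trace,
        converged=converged,
        seed=seed,
        n_iter=len(trace),
    )


def decode(model: SegmentationModel, windows: pd.DataFrame) -> np.ndarray:
    """Viterbi PMD/HMD labels per window.

    The most probable state path is computed per chromosome over windows with
    defined features; undefined windows inherit the state of the nearest
    defined window on the same chromosome (ties broken toward the preceding
    one). Returns an array of "PMD"/"HMD".
    """
    missing = [f for f in model.features if f not in windows.columns]
    if missing:
        raise ValueError(f"windows lack model features {missing}: feature-order mismatch")
    m = model._to_hmmlearn()
    mask = _defined_mask(windows, model.features)
    labels = np.empty(len(windows), dtype=object)
    F = windows.loc[:, list(model.features)].to_numpy(dtype=float)
    for _, sub in windows.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        keep = idx[mask[idx]]
        if len(keep) == 0:
            labels[idx] = STATE_NAMES[1]
            logger.warning("decode: chromosome with no defined windows labeled HMD")
            continue
        Z = (F[keep] - model.feat_mean) / model.feat_std
        path = m.predict(Z)
        for i, s in zip(keep, path):
            labels[i] = STATE_NAMES[s]
        defined_pos = keep
        for i in idx[~mask[idx]]:
            d = np.abs(defined_pos - i)
            best = np.min(d)
            cands = defined_pos[d == best]
            src = cands.min()  # tie -> preceding window
            labels[i] = labels[src]
    return labels.astype(str)


def windows_to_domains(
    labels: np.ndarray, windows: pd.DataFrame, min_windows: int = 1
) -> pd.DataFrame:
    """Merge runs of same-state windows into domains.

    Runs shorter than ``min_windows`` are absorbed into the flanking run with
    more windows (ties toward the preceding run). Per-domain ``mean_beta`` is
    the CpG-count-weighted mean over contained windows.
    """
    out = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        runs = []  # [state, start, end, n_windows, beta_wsum, cpg_sum]
        for i in idx:
            st = labels[i]
            w = windows.loc[i]
            bsum = w["mean_beta"] * w["n_cpgs"]
            if runs and runs[-1][0] == st:
                runs[-1][2] = w["end"]
                runs[-1][3] += 1
                runs[-1][4] += bsum
                runs[-1][5] += w["n_cpgs"]
            else:
                runs.append([st, w["start"], w["end"], 1, bsum, w["n_cpgs"]])
        # absorb short runs: interior runs first (their merge can fuse the
        # two flanking runs into one), smallest first, earliest on ties
        while len(runs) > 1:
            short = [k for k, run in enumerate(runs) if run[3] < min_windows]
            if not short:
                break
            interior = [k for k in short if 0 < k < len(runs) - 1]
            pool = interior if interior else short
            k = min(pool, key=lambda j: (runs[j][3], j))
            run = runs[k]
            prev_n = runs[k - 1][3] if k > 0 else -1
            nxt_n = runs[k + 1][3] if k + 1 < len(runs) else -1
            target = k - 1 if prev_n >= nxt_n else k + 1
            tgt = runs[target]
            tgt[1] = min(tgt[1], run[1])
            tgt[2] = max(tgt[2], run[2])
            tgt[3] += run[3]
            tgt[4] += run[4]
            tgt[5] += run[5]
            runs.pop(k)
            # re-fuse neighbours that now share a state
            j = 0
            while j + 1 < len(runs):
                if runs[j][0] == runs[j + 1][0]:
                    a, b = runs[j], runs[j + 1]
                    a[2] = max(a[2], b[2])
                    a[3] += b[3]
                    a[4] += b[4]
                    a[5] += b[5]
                    runs.pop(j + 1)
                else:
                    j += 1
        for st, s, e, nw, bsum, ncpg in runs:
            out.append(
                {
                    "chrom": chrom, "start": int(s), "end": int(e), "state": st,
                    "n_windows": int(nw),
                    "mean_beta": bsum / ncpg if ncpg else np.nan,
                }
            )
    cols = ["chrom", "start", "end", "state", "n_windows", "mean_beta"]
    return pd.DataFrame(out, columns=cols)


def subtract_blacklist(domains: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Remove blacklist base pairs from domains; fragments keep their state."""
    if not len(domains) or blacklist is None or not len(blacklist):
        return domains.copy()
    return intervals.subtract(domains, blacklist).reset_index(drop=True)


class PMDModel:
    """PMD/HMD segmentation model for one WGBS sample.

    Parameters
    ----------
    cpgs
        Coverage-filtered per-CpG frame (chrom, start, end, beta, coverage
        [, score]) sorted by (chrom, start), e.g. from
        :func:`pmdkit.io.read_cpg_track`.
    config
        :class:`~pmdkit.features.FeatureConfig`; defaults follow the method
        (201-CpG windows, 151-bp solo rule with <=2 neighbours).
    """

    def __init__(
        self,
        cpgs: pd.DataFrame,
        config: FeatureConfig | None = None,
        all_positions: dict | None = None,
    ):
        self.config = config or FeatureConfig()
        self.cpgs = cpgs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.has_score = "score" in self.cpgs.columns and self.cpgs["score"].notna().any()
        # Solo status is a sequence property: count neighbours against all
        # CpG positions (all_positions), not just coverage-retained ones.
        self._solo = solo_mask(
            self.cpgs, self.config.solo_window_bp, self.config.max_neighbors,
            reference_positions=all_positions,
        )
        if self.config.windows_on == "solo":
            frame = self.cpgs[self._solo].reset_index(drop=True)
        elif self.config.windows_on == "all":
            frame = self.cpgs
        else:
            raise ValueError("windows_on must be 'solo' or 'all'")
        self.windows = window_features(frame, self.config)

    @classmethod
    def from_track(
        cls, path, score_path=None, fasta=None,
        min_coverage: int = 5, config: FeatureConfig | None = None,
    ) -> "PMDModel":
        """Build from on-disk tracks.

        The score source is pluggable: an explicit score track wins; else a
        FASTA enables the WCGW flanking-base proxy; else segmentation falls
        back to the score-free (alpha, M-value) emission with a warning.
        """
        from . import io as _io
        from .features import wcgw_proxy_score

        raw = _io.read_cpg_track(path, min_coverage=0)
        all_positions = {c: g["start"].to_numpy() for c, g in raw.groupby("chrom")}
        cpgs = raw[raw["coverage"] >= min_coverage].reset_index(drop=True)
        if score_path is not None:
            cpgs = _io.attach_scores(cpgs, _io.read_score_track(score_path))
        elif fasta is not None:
            parts = []
            for chrom, sub in cpgs.groupby("chrom", sort=False):
                parts.append(wcgw_proxy_score(fasta, chrom, sub["start"].to_numpy()))
            cpgs = cpgs.assign(score=np.concatenate(parts))
        return cls(cpgs, config=config, all_positions=all_positions)

    @property
    def solo_betas(self) -> np.ndarray:
        return self.cpgs.loc[self._solo, "beta"].to_numpy(dtype=float)

    def fit(
        self,
        dim: int | str = "auto",
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-4,
        n_restarts: int = 1,
        percentile: float = 10.0,
        threshold: float = 0.025,
        min_windows: int = 1,
        blacklist: pd.DataFrame | None = None,
    ) -> "PMDResults":
        """Select the feature model, fit the HMM, decode and build domains."""
        if dim == "auto":
            dim = select_model(self.solo_betas, percentile=percentile, threshold=threshold)
        dim = int(dim)
        if self.has_score:
            feats = FEATURES_2D if dim == 2 else FEATURES_3D
        else:
            logger.warning(
                "no per-CpG score available: PCC feature undefined; "
                "falling back to the (alpha, M-value) emission"
            )
            feats = FEATURES_NO_SCORE
            dim = 2
        seg = fit_hmm(
            self.windows, dim=dim, seed=seed, max_iter=max_iter, tol=tol,
            n_restarts=n_restarts, features=feats,
        )
        labels = decode(seg, self.windows)
        domains = windows_to_domains(labels, self.windows, min_windows=min_windows)
        if blacklist is not None and len(blacklist):
            domains = subtract_blacklist(domains, blacklist)
        return PMDResults(self, seg, labels, domains, dim)


class PMDResults:
    """Fitted segmentation: HMM parameters, window labels and PMD/HMD domains."""

    def __init__(self, model: PMDModel, segmentation: SegmentationModel,
                 labels: np.ndarray, domains: pd.DataFrame, dim: int):
        self.model = model
        self.segmentation = segmentation
        self.labels = labels
        self.domains = domains
        self.dim = dim
        self.windows = model.windows.assign(state=labels)

    @property
    def pmds(self) -> pd.DataFrame:
        return self.domains[self.domains["state"] == "PMD"].reset_index(drop=True)

    def genome_fraction(self, genome_sizes: dict | None = None,
                        blacklist: pd.DataFrame | None = None) -> float:
        """Fraction of the genome called PMD.

        Without explicit chromosome sizes the denominator is the windowed
        span (all domain base pairs), i.e. the portion of the genome the
        caller actually classified.
        """
        from . import cohort
        if genome_sizes is None:
            denom = intervals.total_bp(self.domains)
            return intervals.total_bp(self.pmds) / denom if denom else 0.0
        return cohort.genome_fraction(self.pmds, genome_sizes, blacklist=blacklist)

    def evaluate(self, reference: pd.DataFrame) -> dict:
        from . import cohort
        return cohort.evaluate_against_reference(self.pmds, reference)

    def to_bed(self, path) -> None:
        from . import io as _io
        _io.write_domains(self.domains, path)

    def save_model(self, path) -> None:
        self.segmentation.to_json(path)

    def summary(self) -> str:
        seg = self.segmentation
        n_pmd = int((self.domains["state"] == "PMD").sum())
        n_hmd = int((self.domains["state"] == "HMD").sum())
        lines = [
            "PMD segmentation results",
            "=" * 40,
            f"model:               {self.dim}D  features={'+'.join(seg.features)}",
            f"windows:             {len(self.windows)} "
            f"(PMD {int((self.windows['state'] == 'PMD').sum())}, "
            f"HMD {int((self.windows['state'] == 'HMD').sum())})",
            f"domains:             {n_pmd} PMD, {n_hmd} HMD",
            f"PMD genome fraction: {self.genome_fraction():.3f} (of windowed bp)",
            f"EM iterations:       {seg.n_iter} (converged: {seg.converged})",
            f"log-likelihood:      {seg.loglik_trace[-1]:.3f}" if seg.loglik_trace else "",
            "",
            "state emission means (original units):",
        ]
        for k, name in enumerate(STATE_NAMES):
            vals = ", ".join(f"{f}={seg.means[k, j]:.3f}" for j, f in enumerate(seg.features))
            lines.append(f"  {name}: {vals}")
        return "\n".join(line for line in lines if line != "")
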