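"""Continuous phase-bin inference.

Per subject and 60°/15° phase bin, tone responses (mean-centered within
subject and condition) are summarized and compared against a Gaussian
Monte Carlo surrogate baseline fit to that bin's UNSTIM responses
(200 draws).  Group inference runs one-sample t-tests on the paired
(STIM−MC) − (UNSTIM−MC) contrast per bin with Benjamini–Hochberg FDR over
the 24 bins; the Pairwise Response Index (PRI) summarizes, per subject,
how consistently one bin's STIM−MC contrast distribution exceeds the
others'; spindle likelihood is tested against a geometric-mean resampling
null with Welch t-tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .phase import PhaseBinGrid

__all__ = [
    "mean_center", "mc_baseline", "build_bin_summaries", "bin_contrast_tests",
    "compute_pri", "pri_group_tests", "spindle_likelihood_null",
    "spindle_likelihood_tests", "benjamini_hochberg", "welch_t",
    "continuous_phase_analysis",
]


def mean_center(values: np.ndarray) -> np.ndarray:
    """Subtract the mean; the output always averages to zero."""
    v = np.asarray(values, dtype=float)
    return v - v.mean() if len(v) else v


def mean_center_by_subject(df: pd.DataFrame, column: str,
                           group_cols=("subject_id", "is_stim")) -> pd.Series:
    """Center a response within each subject (and condition) independently."""
    return df.groupby(list(group_cols))[column].transform(lambda s: s - s.mean())


def mc_baseline(unstim_values: np.ndarray, n_draws: int,
                rng: np.random.Generator) -> Optional[np.ndarray]:
    """Gaussian surrogate draws from the bin's empirical mean and variance.

    Returns None when fewer than two UNSTIM values are available (variance
    undefined): the bin is missing for this subject.
    """
    v = np.asarray(unstim_values, dtype=float)
    if len(v) < 2:
        return None
    return rng.normal(v.mean(), v.std(ddof=1), size=n_draws)


def welch_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Welch's unequal-variance t with Satterthwaite degrees of freedom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, np.nan
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def benjamini_hochberg(p_values: Sequence[float],
                       alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control; returns (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# bin summaries and the contrast test
# ---------------------------------------------------------------------------

@dataclass
class BinSummary:
    subject_id: int
    bin_index: int
    bin_center: float
    n_stim: int
    n_unstim: int
    stim_mean: float
    unstim_mean: float
    mc_draws: Optional[np.ndarray]     # 200 surrogate baseline values

    @property
    def stim_mc_contrast(self) -> float:
        return self.stim_mean - float(self.mc_draws.mean())

    @property
    def unstim_mc_contrast(self) -> float:
        return self.unstim_mean - float(self.mc_draws.mean())

    @property
    def contrast_distribution(self) -> np.ndarray:
        """The 200 values stim_mean − mc_draw_k (PRI input)."""
        return self.stim_mean - self.mc_draws


def build_bin_summaries(trials: pd.DataFrame, phase_col: str, response_col: str,
                        grid: PhaseBinGrid, n_mc: int = 200,
                        min_trials: int = 5, seed: int = 0,
                        center: bool = True) -> Dict[Tuple[int, int], BinSummary]:
    """Per (subject, bin) response summaries with Monte Carlo baselines.

    A summary is produced only when the subject has >= min_trials STIM and
    >= 2 UNSTIM responses in the bin.  Monte Carlo draws are seeded per
    (seed, subject, bin) so the full table is reproducible.
    """
    df = trials.dropna(subset=[phase_col, response_col]).copy()
    df["_resp"] = (mean_center_by_subject(df, response_col)
                   if center else df[response_col])
    out: Dict[Tuple[int, int], BinSummary] = {}
    centers = grid.centers
    for subj, sub in df.groupby("subject_id"):
        member = grid.membership_matrix(sub[phase_col].to_numpy())
        resp = sub["_resp"].to_numpy()
        is_stim = sub["is_stim"].to_numpy(dtype=bool)
        for b in range(grid.n_bins):
            m = member[:, b]
            stim_v = resp[m & is_stim]
            unstim_v = resp[m & ~is_stim]
            if len(stim_v) < min_trials:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) % (2**31), int(subj), b]))
            draws = mc_baseline(unstim_v, n_mc, rng)
            if draws is None:
                continue
            out[(int(subj), b)] = BinSummary(
                subject_id=int(subj), bin_index=b, bin_center=centers[b],
                n_stim=len(stim_v), n_unstim=len(unstim_v),
                stim_mean=float(stim_v.mean()),
                unstim_mean=float(unstim_v.mean()), mc_draws=draws)
    return out


def bin_contrast_tests(summaries: Dict[Tuple[int, int], "BinSummary"],
                       grid: PhaseBinGrid, alpha: float = 0.05,
                       min_subjects: int = 3) -> pd.DataFrame:
    """Group one-sample t-test per bin on (STIM−MC) − (UNSTIM−MC).

    Bins with too few contributing subjects are excluded from the FDR
    family and reported as untested.  The separate STIM−MC and UNSTIM−MC
    means are also reported.
    """
    rows = []
    for b in range(grid.n_bins):
        diffs, stim_c, unstim_c = [], [], []
        for (subj, bb), s in summaries.items():
            if bb == b:
                diffs.append(s.stim_mc_contrast - s.unstim_mc_contrast)
                stim_c.append(s.stim_mc_contrast)
                unstim_c.append(s.unstim_mc_contrast)
        n = len(diffs)
        if n >= min_subjects and np.std(diffs) > 0:
            t, p = sps.ttest_1samp(diffs, 0.0)
            tested = True
        elif n >= min_subjects:
            t, p, tested = 0.0, 1.0, True
        else:
            t, p, tested = np.nan, np.nan, False
        rows.append(dict(bin_index=b, bin_center=grid.centers[b], n_subjects=n,
                         mean_contrast=float(np.mean(diffs)) if n else np.nan,
                         mean_stim_mc=float(np.mean(stim_c)) if n else np.nan,
                         mean_unstim_mc=float(np.mean(unstim_c)) if n else np.nan,
                         t_stat=float(t) if tested else np.nan,
                         p_raw=float(p) if tested else np.nan, tested=tested))
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    tested = out["tested"].to_numpy()
    if tested.any():
        reject, p_adj = benjamini_hochberg(out.loc[tested, "p_raw"], alpha)
        out.loc[tested, "p_fdr"] = p_adj
        out.loc[tested, "significant"] = reject
    return out


# ---------------------------------------------------------------------------
# Pairwise Response Index
# ---------------------------------------------------------------------------

def compute_pri(distributions: Dict[int, np.ndarray],
                n_bins: int) -> Dict[int, float]:
    """PRI per bin for one subject.

    ``distributions`` maps bin index -> that bin's STIM−MC contrast
    distribution.  For every ordered pair (a, b) the sign of the Welch
    t-statistic enters bin a's average; with all bins present each PRI is
    the mean of n_bins − 1 values from {−1, 0, +1} and the PRIs sum to 0
    absent exact ties.
    """
    bins = sorted(distributions)
    means = {b: distributions[b].mean() for b in bins}
    var_n = {b: distributions[b].var(ddof=1) / len(distributions[b])
             for b in bins}
    signs = {b: [] for b in bins}
    for i, a in enumerate(bins):
        for b in bins[i + 1:]:
            se2 = var_n[a] + var_n[b]
            t = 0.0 if se2 == 0 else (means[a] - means[b]) / np.sqrt(se2)
            s = int(np.sign(t))
            signs[a].append(s)
            signs[b].append(-s)
    return {b: float(np.mean(signs[b])) if signs[b] else np.nan for b in bins}


def pri_group_tests(summaries: Dict[Tuple[int, int], BinSummary],
                    grid: PhaseBinGrid, alpha: float = 0.05,
                    min_subjects: int = 3) -> pd.DataFrame:
    """Per-subject PRIs and group one-sample t-tests vs 0 with FDR."""
    per_subject: Dict[int, Dict[int, float]] = {}
    for subj in sorted({s for s, _ in summaries}):
        dists = {b: summaries[(subj, b)].contrast_distribution
                 for (ss, b) in summaries if ss == subj}
        per_subject[subj] = compute_pri(dists, grid.n_bins)
    rows = []
    for b in range(grid.n_bins):
        vals = [pri[b] for pri in per_subject.values()
                if b in pri and np.isfinite(pri[b])]
        n = len(vals)
        if n >= min_subjects and np.std(vals) > 0:
            t, p = sps.ttest_1samp(vals, 0.0)
            tested = True
        elif n >= min_subjects:
            t, p, tested = 0.0, 1.0, True
        else:
            t, p, tested = np.nan, np.nan, False
        rows.append(dict(bin_index=b, bin_center=grid.centers[b], n_subjects=n,
                         mean_pri=float(np.mean(vals)) if n else np.nan,
                         t_stat=float(t) if tested else np.nan,
                         p_raw=float(p) if tested else np.nan, tested=tested))
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    tested = out["tested"].to_numpy()
    if tested.any():
        reject, p_adj = benjamini_hochberg(out.loc[tested, "p_raw"], alpha)
        out.loc[tested, "p_fdr"] = p_adj
        out.loc[tested, "significant"] = reject
    return out


# ---------------------------------------------------------------------------
# spindle likelihood
# ---------------------------------------------------------------------------

def spindle_likelihood_null(unstim_flags: np.ndarray, n_resamples: int = 200,
                            frac: float = 2.0 / 3.0,
                            rng: Optional[np.random.Generator] = None) -> float:
    """Geometric-mean resampling null for one bin's spindle likelihood.

    Each iteration draws floor(frac·n) UNSTIM trials without replacement;
    iterations with zero likelihood contribute the continuity floor
    1/(2·m) so the geometric mean stays defined.
    """
    flags = np.asarray(unstim_flags, dtype=bool)
    n = len(flags)
    if n < 3:
        raise ValueError("need at least 3 UNSTIM trials for the null")
    rng = rng or np.random.default_rng()
    m = int(np.floor(frac * n))
    floor = 1.0 / (2 * m)
    liks = np.empty(n_resamples)
    for i in range(n_resamples):
        draw = rng.choice(n, size=m, replace=False)
        lik = flags[draw].mean()
        liks[i] = lik if lik > 0 else floor
    return float(np.exp(np.mean(np.log(liks))))


def spindle_likelihood_tests(trials: pd.DataFrame, phase_col: str,
                             grid: PhaseBinGrid, n_resamples: int = 200,
                             frac: float = 2.0 / 3.0, alpha: float = 0.05,
                             min_trials: int = 5, min_subjects: int = 3,
                             seed: int = 0) -> pd.DataFrame:
    """Welch tests of STIM vs UNSTIM spindle likelihood relative to the null.

    The null reference per bin comes from the pooled UNSTIM trials; each
    subject's STIM and UNSTIM likelihoods are expressed as a percentage of
    it and compared across subjects with Welch's t, FDR-corrected over the
    bins.
    """
    df = trials.dropna(subset=[phase_col]).copy()
    df = df[df["spindle"].notna()]
    member_all = grid.membership_matrix(df[phase_col].to_numpy())
    flags = df["spindle"].to_numpy(dtype=bool)
    is_stim = df["is_stim"].to_numpy(dtype=bool)
    subjects = df["subject_id"].to_numpy()
    rows = []
    for b in range(grid.n_bins):
        m = member_all[:, b]
        pooled_unstim = flags[m & ~is_stim]
        if len(pooled_unstim) < 3:
            rows.append(dict(bin_index=b, bin_center=grid.centers[b],
                             null_reference=np.nan, n_subjects=0,
                             mean_stim_pct=np.nan, mean_unstim_pct=np.nan,
                             t_stat=np.nan, p_raw=np.nan, tested=False))
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) % (2**31), 7919, b]))
        null = spindle_likelihood_null(pooled_unstim, n_resamples, frac, rng)
        stim_pct, unstim_pct = [], []
        for subj in np.unique(subjects):
            sm = m & (subjects == subj)
            s_fl = flags[sm & is_stim]
            u_fl = flags[sm & ~is_stim]
            if len(s_fl) >= min_trials and len(u_fl) >= min_trials:
                stim_pct.append(100.0 * s_fl.mean() / null)
                unstim_pct.append(100.0 * u_fl.mean() / null)
        n = len(stim_pct)
        if n >= min_subjects:
            t, p = welch_t(np.array(stim_pct), np.array(unstim_pct))
            if not np.isfinite(p):
                t, p = 0.0, 1.0
            tested = True
        else:
            t, p, tested = np.nan, np.nan, False
        rows.append(dict(bin_index=b, bin_center=grid.centers[b],
                         null_reference=null, n_subjects=n,
                         mean_stim_pct=float(np.mean(stim_pct)) if n else np.nan,
                         mean_unstim_pct=float(np.mean(unstim_pct)) if n else np.nan,
                         t_stat=t, p_raw=p, tested=tested))
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    tested = out["tested"].to_numpy()
    if tested.any():
        reject, p_adj = benjamini_hochberg(out.loc[tested, "p_raw"], alpha)
        out.loc[tested, "p_fdr"] = p_adj
        out.loc[tested, "significant"] = reject
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def continuous_phase_analysis(trials: pd.DataFrame,
                              phase_cols=("phi_so", "phi_lf", "phi_hf"),
                              response_cols=("so_p2p_uv", "swa_norm"),
                              grid: Optional[PhaseBinGrid] = None,
                              n_mc: int = 200, min_trials: int = 5,
                              min_subjects: int = 3, alpha: float = 0.05,
                              seed: int = 0,
                              include_spindles: bool = True,
                              include_hr: bool = True) -> Dict[str, pd.DataFrame]:
    """Run the full continuous-phase battery; one table per analysis.

    Keys are '<response>_by_<phase>' for contrast tests, 'pri_<response>_by_
    <phase>' for PRI, 'spindle_by_<phase>' for spindle likelihood, and
    'hr_p2p_bpm_by_phi_so' for the tone-evoked heart-rate response.
    """
    grid = grid or PhaseBinGrid()
    out: Dict[str, pd.DataFrame] = {}
    resp = list(response_cols)
    if include_hr and "hr_p2p_bpm" in trials.columns:
        hr_ok = trials["hr_p2p_bpm"].notna().any()
    else:
        hr_ok = False
    for phase_col in phase_cols:
        for response_col in resp:
            summaries = build_bin_summaries(trials, phase_col, response_col,
                                            grid, n_mc, min_trials, seed)
            out[f"{response_col}_by_{phase_col}"] = bin_contrast_tests(
                summaries, grid, alpha, min_subjects)
            out[f"pri_{response_col}_by_{phase_col}"] = pri_group_tests(
                summaries, grid, alpha, min_subjects)
        if include_spindles and "spindle" in trials.columns:
            out[f"spindle_by_{phase_col}"] = spindle_likelihood_tests(
                trials, phase_col, grid, alpha=alpha, min_trials=min_trials,
                min_subjects=min_subjects, seed=seed)
    if hr_ok:
        summaries = build_bin_summaries(trials, "phi_so", "hr_p2p_bpm",
                                        grid, n_mc, min_trials, seed)
        out["hr_p2p_bpm_by_phi_so"] = bin_contrast_tests(
            summaries, grid, alpha, min_subjects)
    return out
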