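"""SNR with Rician correction, test-retest reliability, and group comparisons.

Magnitude MR images have Rician-distributed noise: in signal-free background
the magnitude of complex Gaussian noise is Rayleigh, whose standard
deviation is sqrt(2 - pi/2) = 0.655 times the per-channel sigma.  SNR
measured as ROI mean over background-ROI s.d. is therefore multiplied by
0.655 to express signal over the true per-channel sigma.

Reliability follows the standard test-retest battery: intraclass
correlation (two-way random effects, absolute agreement, single measures)
with an F-based 95% CI, Pearson correlation, and per-subject coefficient of
variation.  Group comparisons from published summary statistics use Welch's
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

#: Rayleigh s.d. of background magnitude over per-channel Gaussian sigma.
RICIAN_SD_FACTOR = 0.655


@dataclass
class SummaryGroup:
    """Published group summary: mean, s.d., and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 2:
            raise ValueError("require sd >= 0 and n >= 2")


@dataclass
class ReliabilityReport:
    """Per-facet test-retest summary (ICC with CI, Pearson r, CV%)."""

    icc: float
    ci_low: float
    ci_high: float
    icc_p: float
    pearson_r: float
    pearson_p: float
    cv_mean: float
    cv_sd: float
    n_subjects: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.icc <= 1.0):
            raise ValueError("ICC must lie in [-1, 1]")
        if not (self.ci_low <= self.icc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the ICC")


def snr(signal_roi, noise_roi_sds) -> float:
    """Rician-corrected SNR: 0.655 x mean(signal ROI) / background s.d.

    With several background ROIs the per-ROI SNRs are averaged (the knee
    protocol uses four).  The 0.655 factor converts the Rayleigh background
    s.d. to the per-channel sigma scale.
    """
    signal_roi = np.asarray(signal_roi, dtype=float)
    sds = np.atleast_1d(np.asarray(noise_roi_sds, dtype=float))
    if signal_roi.size == 0 or sds.size == 0:
        raise ValueError("need at least one signal value and one noise s.d.")
    if np.any(sds <= 0):
        raise ValueError("noise s.d. must be positive")
    return float(np.mean(RICIAN_SD_FACTOR * signal_roi.mean() / sds))


def rician_background_sd_factor(n_draws: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of sd(|complex Gaussian noise|) / sigma.

    Draws ``n_draws`` zero-mean unit-sigma complex Gaussian samples, takes
    magnitudes, and returns their standard deviation (sigma = 1).  The
    closed-form value is sqrt(2 - pi/2) ~ 0.6551.
    """
    rng = np.random.default_rng(seed)
    mags = np.hypot(rng.standard_normal(n_draws), rng.standard_normal(n_draws))
    return float(np.std(mags))


def icc_absolute(test, retest) -> tuple[float, float, float, float]:
    """Two-way random, absolute-agreement, single-measures ICC.

    Returns (icc, ci_low, ci_high, p) with the F-based 95% CI.  Requires
    paired measurements from >= 3 subjects and nonzero total variance.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or test.ndim != 1 or test.size < 3:
        raise ValueError("need paired 1D arrays with n >= 3")
    if np.var(np.concatenate([test, retest])) == 0:
        raise ValueError("zero total variance: ICC undefined")
    n = test.size
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["test", "retest"], n),
            "score": np.concatenate([test, retest]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    # pingouin labels the two-way absolute-agreement single-measure row
    # "ICC2" or "ICC(A,1)" depending on version
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = row[ci_col]
    return float(row["ICC"]), float(ci_low), float(ci_high), float(row["pval"])


def pearson(test, retest) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.size < 3:
        raise ValueError("need n >= 3")
    r, p = sps.pearsonr(test, retest)
    return float(r), float(p)


def cv_testretest(test, retest) -> tuple[np.ndarray, float, float]:
    """Per-subject test-retest CV% and its (mean, s.d.) over subjects.

    CV = s.d. of the two measurements (ddof=1) over their mean, x100.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or np.any(test <= 0) or np.any(retest <= 0):
        raise ValueError("need paired positive values")
    pairs = np.stack([test, retest], axis=0)
    cv = pairs.std(axis=0, ddof=1) / pairs.mean(axis=0) * 100.0
    return cv, float(cv.mean()), float(cv.std(ddof=1) if cv.size > 1 else 0.0)


def welch_t_from_summary(a: SummaryGroup, b: SummaryGroup) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, Satterthwaite df, two-sided p).  Two identical degenerate
    groups (both s.d. zero, equal means) return t=0, p=1 by convention.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), float(p)


def snr_decay_projection(base_snr: float, t1rho_ms: float, tsl_ms: float) -> float:
    """SNR projected through mono-exponential decay: base * exp(-TSL/T1rho)."""
    if base_snr <= 0 or t1rho_ms <= 0 or tsl_ms < 0:
        raise ValueError("require positive base SNR and T1rho, nonnegative TSL")
    return base_snr * float(np.exp(-tsl_ms / t1rho_ms))


def reliability_report(test, retest) -> ReliabilityReport:
    """Full test-retest battery for one cartilage facet."""
    icc, lo, hi, p_icc = icc_absolute(test, retest)
    r, p_r = pearson(test, retest)
    _, cv_mean, cv_sd = cv_testretest(test, retest)
    return ReliabilityReport(
        icc=icc,
        ci_low=lo,
        ci_high=hi,
        icc_p=p_icc,
        pearson_r=r,
        pearson_p=p_r,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        n_subjects=len(np.asarray(test)),
    )
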