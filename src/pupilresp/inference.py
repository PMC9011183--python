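"""Statistical layer: frequentist tests with default-prior Bayes factors.

Every test returns a :class:`TestResult` carrying the statistic, degrees of
freedom, two-tailed p-value, an effect size, and (where defined) the base-10
log Bayes factor ``lgBF`` comparing H1 (an effect) against H0 (no effect).
Evidence conventions: |lgBF| above 0.5 is substantial, above 1 strong, above
2 decisive; the sign selects the favoured hypothesis.

Bayes factors for t-tests use the JZS default: a Cauchy prior with scale
0.707 (sqrt(2)/2) on the standardized effect size, integrated numerically
against the noncentral-t likelihood.  Correlations use the matching default
with a uniform prior on the correlation coefficient.  ANOVA terms get a
BIC-approximated lgBF, labeled approximate in the result: the exact
model-averaged g-prior machinery of point-and-click Bayesian ANOVA tools is
deliberately not replicated.

Power utilities invert the exact noncentral-t power function, e.g. to report
the smallest group difference (in Cohen's d) detectable at a given power and
alpha — the study-design sensitivity analysis.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

JZS_PRIOR_SCALE = math.sqrt(2) / 2

#: lgBF thresholds for the evidence categories.
SUBSTANTIAL, STRONG, DECISIVE = 0.5, 1.0, 2.0


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    name: str
    statistic: float
    df: float | tuple
    p_value: float
    lgbf: float = np.nan
    effect_size: float = np.nan
    effect_name: str = ""
    tails: str = "two-sided"
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class EvidenceLabel:
    """Qualitative reading of a log Bayes factor."""

    strength: str          # inconclusive | substantial | strong | decisive
    favors: str | None     # 'H1', 'H0', or None when inconclusive
    lgbf: float

    @property
    def category(self) -> str:
        return self.strength if self.favors is None else f"{self.strength}_{self.favors}"


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def two_sample_t(x, y, welch: bool = False, prior_scale: float = JZS_PRIOR_SCALE) -> TestResult:
    """Two-sample t-test on raw samples (pooled-variance Student by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    return two_sample_t_from_stats(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y),
        welch=welch, prior_scale=prior_scale,
    )


def two_sample_t_from_stats(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    welch: bool = False, prior_scale: float = JZS_PRIOR_SCALE,
) -> TestResult:
    """Two-sample t-test from group means, SDs (ddof=1) and sizes.

    The pooled-variance Student form is the default (df = n1 + n2 - 2);
    Welch's unequal-variance form is available behind ``welch=True``.
    Cohen's d uses the pooled SD in either case.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return TestResult("two-sample t", 0.0, n1 + n2 - 2, 1.0,
                              lgbf=np.nan, effect_size=0.0, effect_name="cohen_d")
        raise ValueError("zero pooled variance with unequal means")
    if welch:
        se = math.sqrt(s1**2 / n1 + s2**2 / n2)
        df = se**4 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    else:
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = (m1 - m2) / se
    p = 2 * stats.t.sf(abs(t), df)
    d = (m1 - m2) / math.sqrt(sp2)
    lgbf = jzs_bf_t(t, n1, n2, prior_scale=prior_scale)
    return TestResult("two-sample t", float(t), float(df), float(p),
                      lgbf=lgbf, effect_size=float(d), effect_name="cohen_d")


def paired_t(diffs, prior_scale: float = JZS_PRIOR_SCALE) -> TestResult:
    """One-sample t-test on paired differences (df = n - 1).

    Note this is *not* equivalent to a two-sample test of the differences
    against zeros except in degenerate balanced constructions: the paired
    test conditions on the pairing and uses the SD of the differences.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult("paired t", 0.0, n - 1, 1.0, effect_size=0.0, effect_name="cohen_dz")
        warnings.warn("zero-variance nonzero differences; t is infinite")
        return TestResult("paired t", math.inf * np.sign(d.mean()), n - 1, 0.0,
                          lgbf=math.inf, effect_size=math.inf, effect_name="cohen_dz")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return TestResult("paired t", float(t), n - 1, float(p),
                      lgbf=jzs_bf_t(t, n, paired=True, prior_scale=prior_scale),
                      effect_size=float(d.mean() / sd), effect_name="cohen_dz")


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _bic_lgbf(ss_effect: float, ss_error: float, df_effect: float, n_obs: int) -> float:
    # BIC approximation to the Bayes factor for dropping one model term
    # (Wagenmakers-style unit-information prior); reported as approximate.
    if ss_error <= 0:
        return math.inf if ss_effect > 0 else 0.0
    dbic = n_obs * math.log((ss_effect + ss_error) / ss_error) - df_effect * math.log(n_obs)
    return dbic / (2 * math.log(10))


def rm_anova_oneway(data) -> TestResult:
    """One-way repeated-measures ANOVA on a subject x condition matrix.

    Subjects with any missing cell are dropped (complete-case) with a
    warning.  Returns F with (df_condition, df_error), the p-value, partial
    eta-squared, and a BIC-approximate lgBF for the condition effect.
    """
    y = np.atleast_2d(np.asarray(data, dtype=float))
    complete = np.isfinite(y).all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} subject(s) with missing cells")
        y = y[complete]
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond, ms_err = ss_cond / df_cond, ss_err / df_err
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else math.inf)
    p = stats.f.sf(F, df_cond, df_err) if np.isfinite(F) else 0.0
    np2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return TestResult("rm one-way ANOVA", float(F), (df_cond, df_err), float(p),
                      lgbf=_bic_lgbf(ss_cond, ss_err, df_cond, n * k),
                      effect_size=float(np2), effect_name="partial_eta2",
                      note="lgBF is a BIC approximation")


def mixed_anova_2x2(data, groups) -> dict[str, TestResult]:
    """Mixed-design ANOVA: within-subject conditions x between-subject group.

    ``data`` is a subject x condition matrix (2+ conditions), ``groups`` a
    per-subject label array with two or more levels; unbalanced group sizes
    are allowed (sums of squares then follow the weighted, Type-II
    decomposition).  Returns the within main effect, between main effect and
    interaction, each tested against the standard mixed-design error term
    (between: subjects within groups; within and interaction: condition x
    subjects within groups).
    """
    y = np.atleast_2d(np.asarray(data, dtype=float))
    groups = np.asarray(groups)
    complete = np.isfinite(y).all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} subject(s) with missing cells")
        y, groups = y[complete], groups[complete]
    n, k = y.shape
    if len(groups) != n:
        raise ValueError("groups must label every subject")
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    if k < 2:
        raise ValueError("need at least 2 conditions")

    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    # between-subject stratum
    ss_betw = ss_resbetw = 0.0
    for g in levels:
        m = groups == g
        gm = subj_means[m].mean()
        ss_betw += k * m.sum() * (gm - grand) ** 2
        ss_resbetw += k * ((subj_means[m] - gm) ** 2).sum()
    # within-subject stratum (weighted condition means, cell residuals)
    ss_with = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_resall = 0.0
    for g in levels:
        cell = y[groups == g]
        ss_resall += ((cell - cell.mean(axis=0)) ** 2).sum()
    ss_inter = ss_total - ss_resall - ss_with - ss_betw
    ss_reswith = ss_total - ss_betw - ss_resbetw - ss_with - ss_inter

    G = len(levels)
    df_betw, df_resbetw = G - 1, n - G
    df_with, df_inter = k - 1, (k - 1) * (G - 1)
    df_reswith = (k - 1) * (n - G)
    ms = lambda ss, df: ss / df

    def _res(name, ss_eff, df_eff, ss_err, df_err, n_obs):
        mse = ms(ss_err, df_err)
        F = ms(ss_eff, df_eff) / mse if mse > 0 else (0.0 if ss_eff <= 0 else math.inf)
        F = max(F, 0.0)
        p = stats.f.sf(F, df_eff, df_err) if np.isfinite(F) else 0.0
        np2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return TestResult(name, float(F), (df_eff, df_err), float(p),
                          lgbf=_bic_lgbf(max(ss_eff, 0.0), ss_err, df_eff, n_obs),
                          effect_size=float(max(np2, 0.0)), effect_name="partial_eta2",
                          note="lgBF is a BIC approximation")

    return {
        "within": _res("mixed ANOVA: within", ss_with, df_with, ss_reswith, df_reswith, n * k),
        "between": _res("mixed ANOVA: between", ss_betw, df_betw, ss_resbetw, df_resbetw, n),
        "interaction": _res("mixed ANOVA: interaction", ss_inter, df_inter,
                            ss_reswith, df_reswith, n * k),
    }


# ---------------------------------------------------------------------------
# correlation, contingency, variance homogeneity
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with df = n - 2 and a default-prior lgBF.

    The Bayes factor integrates the exact sampling density of r against a
    uniform prior on the population correlation (the stretched-beta default
    with width 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf * np.sign(r), 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
    return TestResult("pearson r", r, df, float(p),
                      lgbf=jzs_bf_r(r, n), effect_size=r, effect_name="r")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], no continuity
    correction, df = 1.  Effect size is the phi coefficient."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal total")
    expected = np.outer(row, col) / n
    x2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(x2, df=1))
    phi = math.sqrt(x2 / n)
    return TestResult("chi-square 2x2", x2, 1, p, effect_size=phi, effect_name="phi")


def levene_check(x, y) -> TestResult:
    """Levene's test (mean-centered) for equality of variances, as a thin
    cross-group variability check."""
    stat, p = stats.levene(np.asarray(x, float), np.asarray(y, float), center="mean")
    return TestResult("levene", float(stat), (1, len(x) + len(y) - 2), float(p))


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


def jzs_bf_t(
    t: float,
    n1: int,
    n2: int | None = None,
    paired: bool = False,
    prior_scale: float = JZS_PRIOR_SCALE,
) -> float:
    """Base-10 log of the JZS default Bayes factor for a t statistic.

    H1 places a Cauchy(0, ``prior_scale``) prior on the standardized effect
    size; the marginal likelihood is the noncentral-t density integrated over
    that prior, evaluated by adaptive quadrature.  Positive values favour H1.

    For a two-sample test pass both group sizes; for a one-sample/paired test
    pass ``n1`` (the number of pairs) with ``paired=True``.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if paired or n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        n_eff, df = float(n1), n1 - 1
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2
    sqrt_n = math.sqrt(n_eff)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, scale=prior_scale)

    # split at the likelihood mode so the adaptive rule cannot miss the
    # spike when |t| is large
    mode = t / sqrt_n
    n_lo, e_lo = integrate.quad(integrand, -np.inf, mode, limit=200)
    n_hi, e_hi = integrate.quad(integrand, mode, np.inf, limit=200)
    num, err = n_lo + n_hi, e_lo + e_hi
    if num <= 0 or not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise ArithmeticError(
            f"JZS quadrature failed: marginal={num!r}, abserr={err!r}, t={t}, df={df}"
        )
    den = stats.t.pdf(t, df)
    return float(np.log10(num) - np.log10(den))


def jzs_bf_r(r: float, n: int) -> float:
    """Base-10 log Bayes factor for a Pearson correlation, uniform prior on
    the population correlation coefficient (-1, 1).

    Uses the exact sampling density of r given rho (hypergeometric form) and
    integrates over the prior by quadrature.
    """
    if not -1 < r < 1:
        return math.inf
    if n < 4:
        raise ValueError("need n >= 4 for the correlation Bayes factor")

    log_norm = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2 * math.pi)
        - special.gammaln(n - 0.5)
        + (n - 4) / 2 * math.log1p(-r * r)
    )

    def density(rho):
        return math.exp(
            log_norm
            + (n - 1) / 2 * math.log1p(-rho * rho)
            - (n - 1.5) * math.log1p(-rho * r)
        ) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)

    num, err = integrate.quad(lambda rho: 0.5 * density(rho), -1, 1, limit=200)
    den = density(0.0)
    if num <= 0 or den <= 0 or not np.isfinite(num):
        raise ArithmeticError(f"correlation BF quadrature failed: num={num!r}, den={den!r}")
    return float(np.log10(num) - np.log10(den))


def evidence_label(lgbf: float) -> EvidenceLabel:
    """Classify a log10 Bayes factor by the substantial/strong/decisive
    conventions.  The boundary value 0.5 itself counts as substantial (the H0
    side is inclusive by symmetry of the reporting rule)."""
    if not np.isfinite(lgbf):
        raise ValueError("lgBF must be finite")
    a = abs(lgbf)
    if a < SUBSTANTIAL:
        return EvidenceLabel("inconclusive", None, lgbf)
    strength = "decisive" if a > DECISIVE else "strong" if a > STRONG else "substantial"
    return EvidenceLabel(strength, "H1" if lgbf > 0 else "H0", lgbf)


# ---------------------------------------------------------------------------
# power / sensitivity
# ---------------------------------------------------------------------------


def power_t(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Exact two-tailed power of the two-sample t-test at effect size d.

    Noncentrality is d * sqrt(n1 n2 / (n1 + n2)) with df = n1 + n2 - 2.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    tc = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))


def sensitivity_d(n1: int, n2: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest Cohen's d detectable at the given power and alpha.

    Inverts :func:`power_t` by root finding.  With power <= alpha the answer
    is 0 (any effect, including none, reaches that 'power').
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if power <= alpha:
        return 0.0
    if not alpha < power < 1:
        raise ValueError("power must be in (alpha, 1)")
    return float(optimize.brentq(lambda d: power_t(d, n1, n2, alpha) - power, 1e-12, 20.0,
                                 xtol=1e-10))


# ---------------------------------------------------------------------------
# AQ questionnaire scoring
# ---------------------------------------------------------------------------

AQ_RESPONSES = ("strongly agree", "slightly agree", "slightly disagree", "strongly disagree")


def load_aq_key() -> list[str]:
    """Autistic-keyed direction ('agree'/'disagree') for the 50 AQ items."""
    ref = importlib.resources.files("pupilresp").joinpath("data/aq_key.csv")
    with ref.open() as fh:
        rows = list(csv.DictReader(fh))
    key = [r["keyed_direction"] for r in sorted(rows, key=lambda r: int(r["item"]))]
    if len(key) != 50 or set(key) - {"agree", "disagree"}:
        raise ValueError("malformed AQ key resource")
    return key


def aq_score(responses, key: list[str] | None = None) -> int:
    """Total AQ score: 1 point per item answered in the autistic-keyed
    direction, whether slightly or strongly; 0 otherwise.

    ``responses`` must be 50 answers on the 4-point agree/disagree scale.  An
    incomplete questionnaire makes the total undefined and raises.
    """
    if key is None:
        key = load_aq_key()
    responses = list(responses)
    if len(responses) != len(key):
        raise ValueError(f"expected {len(key)} responses, got {len(responses)}")
    total = 0
    for i, (resp, direction) in enumerate(zip(responses, key), start=1):
        if resp is None or (isinstance(resp, float) and np.isnan(resp)):
            raise ValueError(f"item {i} unanswered; AQ total undefined")
        r = str(resp).strip().lower()
        if r not in AQ_RESPONSES:
            raise ValueError(f"item {i}: unrecognized response {resp!r}")
        total += int(r.split()[-1] == direction)
    return total
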