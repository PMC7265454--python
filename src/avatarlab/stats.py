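"""Statistical battery for the 2 x 6 mixed design.

Implements: Greenhouse–Geisser and Huynh–Feldt epsilons, a multisample
sphericity likelihood-ratio test, the classical split-plot (mixed) ANOVA with
the epsilon-threshold correction rule (GG when eps_GG < 0.75, HF otherwise),
per-occasion planned comparisons with Holm's step-down adjustment, the
Jacobson–Truax / Christensen–Mendoza reliable change index, a one-way
random-effects ICC, Cohen's kappa with asymptotic confidence interval, and
Goldstein–Healy adjusted confidence-interval levels for overlap inference.

The multisample sphericity test factors the likelihood ratio exactly into a
Box-M test of equal contrast covariances across groups and a Mauchly test of
sphericity on the pooled contrast covariance; each factor carries its
standard Bartlett correction and the corrected chi-squares add, with
df = g*p*(p+1)/2 - 1 for p = k-1 contrasts and g groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

#: Two-sided 90% normal quantile: the reliable-change threshold.
RCI_THRESHOLD = 1.645


class InsufficientDataError(ValueError):
    pass


class ComputationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# results

@dataclass
class SphericityResult:
    statistic: float
    df: int
    p: float


@dataclass
class AnovaResult:
    effect: str  # "group" | "time" | "interaction"
    F: float
    df1: float
    df2: float
    epsilon_gg: float
    epsilon_hf: float
    correction_used: str  # "none" | "GG" | "HF"
    df1_corrected: float
    df2_corrected: float
    p: float
    partial_eta_sq: float
    observed_power: float


@dataclass
class ComparisonResult:
    interview_index: int
    F: float
    d: float
    p_raw: float
    p_holm: float
    significant: bool


@dataclass
class RCIResult:
    x1: float
    followup_mean: float
    sd_baseline: float
    icc: float
    rci: float
    reliable: bool
    direction: str  # "increase" | "decrease" | "none"


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    percent_agreement: float
    pa_ci_low: float
    pa_ci_high: float
    n: int
    degenerate: bool = False


@dataclass
class AdjustedCILevel:
    se_ratio: float
    alpha: float
    level: float  # two-sided confidence percentage in (0, 100)


# ---------------------------------------------------------------------------
# sphericity epsilons

def epsilons(within_covariance: np.ndarray, n: int, g: int) -> tuple[float, float]:
    """Greenhouse–Geisser and Huynh–Feldt epsilons from a k x k covariance.

    ``n`` is the total number of subjects, ``g`` the number of groups.  The GG
    epsilon uses the trace form on the orthonormal-contrast projection; the HF
    epsilon uses the multi-group adjustment of Huynh (1978),
    ((n-g+1)(k-1)e - 2) / ((k-1)(n-g-(k-1)e)), clipped to [e_GG, 1].
    """
    S = np.asarray(within_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"covariance must be square, got shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, float(np.abs(S).max()))):
        raise ValueError("covariance matrix must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    C = helmert(k, full=False)  # (k-1) x k, orthonormal rows
    Sc = C @ S @ C.T
    tr = float(np.trace(Sc))
    tr2 = float(np.trace(Sc @ Sc))
    gg = tr * tr / ((k - 1) * tr2)
    num = (n - g + 1) * (k - 1) * gg - 2.0
    den = (k - 1) * (n - g - (k - 1) * gg)
    hf = num / den if den > 0 else 1.0
    hf = float(np.clip(hf, gg, 1.0))
    return float(gg), hf


# ---------------------------------------------------------------------------
# multisample sphericity test

def mendoza_test(groups: Sequence[np.ndarray]) -> SphericityResult:
    """Multisample sphericity LR test on per-group n_g x k score matrices.

    Tests jointly that the orthonormal-contrast covariance is equal across
    groups and proportional to the identity (the validity condition of the
    univariate mixed-model F).  For k = 2 the test is vacuous (p = 1).
    """
    mats = [np.asarray(m, dtype=float) for m in groups]
    if not mats:
        raise InsufficientDataError("no groups supplied")
    k = mats[0].shape[1]
    if any(m.ndim != 2 or m.shape[1] != k for m in mats):
        raise ValueError("all groups must be 2-D with the same number of occasions")
    if k == 2:
        return SphericityResult(statistic=0.0, df=0, p=1.0)
    p = k - 1
    C = helmert(k, full=False)
    g = len(mats)
    dfs, ssps = [], []
    for m in mats:
        n_g = m.shape[0]
        if n_g - 1 < p or n_g <= 2:
            raise InsufficientDataError(
                f"group with n={n_g} too small for k={k} occasions (need n-1 >= k-1)"
            )
        z = m @ C.T
        zc = z - z.mean(axis=0)
        ssps.append(zc.T @ zc)
        dfs.append(n_g - 1)
    N = sum(dfs)
    A = sum(ssps)
    S_pool = A / N

    # Box-M part: equality of contrast covariances across groups
    sign, logdet_pool = np.linalg.slogdet(S_pool)
    if sign <= 0:
        raise ComputationError("pooled contrast covariance is singular")
    M = N * logdet_pool
    for A_g, N_g in zip(ssps, dfs):
        sign_g, logdet_g = np.linalg.slogdet(A_g / N_g)
        if sign_g <= 0:
            raise ComputationError("a group contrast covariance is singular")
        M -= N_g * logdet_g
    if g > 1:
        c1 = (sum(1.0 / d for d in dfs) - 1.0 / N) * (2 * p * p + 3 * p - 1) / (
            6.0 * (p + 1) * (g - 1)
        )
        chi_m = (1.0 - c1) * M
        df_m = (g - 1) * p * (p + 1) // 2
    else:
        chi_m, df_m = 0.0, 0

    # Mauchly part: sphericity of the pooled contrast covariance
    lnW = logdet_pool - p * math.log(np.trace(S_pool) / p)
    rho = 1.0 - (2 * p * p + p + 2) / (6.0 * p * N)
    chi_s = -N * rho * lnW
    df_s = p * (p + 1) // 2 - 1

    statistic = float(max(chi_m + chi_s, 0.0))
    df = df_m + df_s
    return SphericityResult(statistic=statistic, df=df, p=float(sps.chi2.sf(statistic, df)))


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA

def _observed_power(F: float, df1: float, df2: float, alpha: float) -> float:
    """Post-hoc power from the noncentral F with ncp = F * df1."""
    if not np.isfinite(F) or F < 0:
        return math.nan
    ncp = F * df1
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, ncp))


def mixed_anova_arrays(
    groups: Sequence[np.ndarray],
    *,
    alpha: float = 0.05,
    epsilon_threshold: float = 0.75,
) -> dict[str, AnovaResult]:
    """Split-plot ANOVA on per-group n_g x k matrices (one row per subject).

    Between effect ("group") is uncorrected; within effects ("time",
    "interaction") are corrected by GG when eps_GG < ``epsilon_threshold``
    and by HF otherwise, mirroring the conventional two-branch rule.
    """
    mats = [np.asarray(m, dtype=float) for m in groups]
    if len(mats) < 1:
        raise InsufficientDataError("no groups supplied")
    k = mats[0].shape[1]
    if any(m.shape[1] != k for m in mats):
        raise ValueError("groups disagree on the number of occasions")
    if any(m.shape[0] < 2 for m in mats):
        raise InsufficientDataError("need >= 2 subjects per group")
    g = len(mats)
    ns = [m.shape[0] for m in mats]
    N = sum(ns)
    allY = np.vstack(mats)
    GM = allY.mean()
    if not allY.var() > 0:
        raise ComputationError("dependent variable has zero variance")

    subj_means = allY.mean(axis=1)
    group_means = np.array([m.mean() for m in mats])
    occ_means = allY.mean(axis=0)
    ss_between_subj = k * float(((subj_means - GM) ** 2).sum())
    ss_group = k * float(sum(n * (gm - GM) ** 2 for n, gm in zip(ns, group_means)))
    ss_subj_within = ss_between_subj - ss_group
    ss_time = N * float(((occ_means - GM) ** 2).sum())
    ss_cells = float(sum(n * ((m.mean(axis=0) - GM) ** 2).sum() for n, m in zip(ns, mats)))
    ss_interaction = ss_cells - ss_group - ss_time
    ss_total = float(((allY - GM) ** 2).sum())
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_interaction

    df_group, df_subj = g - 1, N - g
    df_time = k - 1
    df_int = (g - 1) * (k - 1)
    df_errw = (N - g) * (k - 1)
    ms_subj = ss_subj_within / df_subj
    ms_errw = ss_err_within / df_errw
    if ms_subj <= 0 or ms_errw <= 0:
        raise ComputationError("error sums of squares vanish; no residual variance")

    S_pool = sum((n - 1) * np.cov(m, rowvar=False) for n, m in zip(ns, mats)) / (N - g)
    eps_gg, eps_hf = epsilons(S_pool, N, g)
    correction = "HF" if eps_gg >= epsilon_threshold else "GG"
    eps_used = eps_hf if correction == "HF" else eps_gg

    results: dict[str, AnovaResult] = {}

    def add(effect, ss_eff, df1, df2, ms_err, ss_err, corrected):
        F = (ss_eff / df1) / ms_err
        if corrected:
            d1, d2, corr = df1 * eps_used, df2 * eps_used, correction
        else:
            d1, d2, corr = df1, df2, "none"
        results[effect] = AnovaResult(
            effect=effect,
            F=float(F),
            df1=float(df1),
            df2=float(df2),
            epsilon_gg=eps_gg,
            epsilon_hf=eps_hf,
            correction_used=corr,
            df1_corrected=float(d1),
            df2_corrected=float(d2),
            p=float(sps.f.sf(F, d1, d2)),
            partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
            observed_power=_observed_power(float(F), d1, d2, alpha),
        )

    if g > 1:
        add("group", ss_group, df_group, df_subj, ms_subj, ss_subj_within, corrected=False)
    add("time", ss_time, df_time, df_errw, ms_errw, ss_err_within, corrected=True)
    if g > 1:
        add("interaction", ss_interaction, df_int, df_errw, ms_errw, ss_err_within, corrected=True)
    return results


def _pivot_groups(table: pd.DataFrame, dv: str) -> tuple[list[str], list[np.ndarray]]:
    """Wide per-group matrices from a long metrics table; errors on missing cells."""
    required = {"participant_id", "group", "interview_index", dv}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    occasions = sorted(table["interview_index"].unique())
    labels, mats = [], []
    bad: list[str] = []
    for label, sub in table.groupby("group", sort=True):
        wide = sub.pivot(index="participant_id", columns="interview_index", values=dv)
        wide = wide.reindex(columns=occasions)
        incomplete = wide.index[wide.isna().any(axis=1)]
        bad.extend(str(pid) for pid in incomplete)
        labels.append(str(label))
        mats.append(wide.to_numpy(dtype=float))
    if bad:
        raise ValueError(f"participants with missing interview cells: {sorted(bad)}")
    return labels, mats


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    *,
    alpha: float = 0.05,
    epsilon_threshold: float = 0.75,
) -> dict[str, AnovaResult]:
    """Mixed ANOVA of ``dv`` from a long table (participant_id, group, interview_index)."""
    _, mats = _pivot_groups(table, dv)
    return mixed_anova_arrays(mats, alpha=alpha, epsilon_threshold=epsilon_threshold)


# ---------------------------------------------------------------------------
# planned comparisons and Holm

def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted.tolist()


def planned_comparisons(
    table: pd.DataFrame, dv: str, *, alpha: float = 0.05
) -> list[ComparisonResult]:
    """Per-occasion between-group one-way F tests, Holm-adjusted as a family."""
    labels, mats = _pivot_groups(table, dv)
    if len(mats) != 2:
        raise ValueError(f"planned comparisons need exactly 2 groups, got {len(labels)}")
    a, b = mats
    k = a.shape[1]
    occasions = sorted(table["interview_index"].unique())
    raw: list[tuple[int, float, float, float]] = []
    for j in range(k):
        x, y = a[:, j], b[:, j]
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 <= 0:
            F, d, pval = 0.0, 0.0, 1.0
        else:
            t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            F = t * t
            d = (x.mean() - y.mean()) / math.sqrt(sp2)
            pval = float(sps.f.sf(F, 1, n1 + n2 - 2))
        raw.append((occasions[j], float(F), float(d), pval))
    adj = holm_adjust([r[3] for r in raw])
    return [
        ComparisonResult(
            interview_index=occ, F=F, d=d, p_raw=p, p_holm=ph, significant=ph < alpha
        )
        for (occ, F, d, p), ph in zip(raw, adj)
    ]


# ---------------------------------------------------------------------------
# reliable change

def rci(x1: float, followup_mean: float, sd_baseline: float, icc: float) -> RCIResult:
    """Reliable change index: (follow-up − baseline) / (SD1 * sqrt(2(1−ICC))).

    The denominator is the Jacobson–Truax standard error of a difference with
    the Christensen–Mendoza reliability plug-in; |RCI| > 1.645 marks reliable
    change at the two-sided 90% level.
    """
    if sd_baseline <= 0:
        raise ValueError(f"sd_baseline must be > 0, got {sd_baseline}")
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    value = (followup_mean - x1) / (sd_baseline * math.sqrt(2.0 * (1.0 - icc)))
    reliable = abs(value) > RCI_THRESHOLD
    direction = "none" if not reliable else ("increase" if value > 0 else "decrease")
    return RCIResult(
        x1=float(x1),
        followup_mean=float(followup_mean),
        sd_baseline=float(sd_baseline),
        icc=float(icc),
        rci=float(value),
        reliable=reliable,
        direction=direction,
    )


def icc_repeated(scores: np.ndarray, variant: str = "oneway") -> float:
    """Intraclass correlation of an n x k repeated-measures score matrix.

    ``oneway``: ICC(1), one-way random effects, (MSB - MSW)/(MSB + (k-1)MSW).
    ``consistency``: two-way mixed consistency ICC(3,1), which removes the
    occasion effect from the error term.  Both are floored at 0.
    """
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InsufficientDataError(f"need an n>=2 x k>=2 matrix, got shape {m.shape}")
    if np.isnan(m).any():
        raise ValueError("score matrix contains missing cells")
    n, k = m.shape
    row_means = m.mean(axis=1)
    grand = m.mean()
    ms_between = k * ((row_means - grand) ** 2).sum() / (n - 1)
    if variant == "oneway":
        ms_within = ((m - row_means[:, None]) ** 2).sum() / (n * (k - 1))
        val = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
    elif variant == "consistency":
        col_means = m.mean(axis=0)
        resid = m - row_means[:, None] - col_means[None, :] + grand
        ms_error = (resid ** 2).sum() / ((n - 1) * (k - 1))
        val = (ms_between - ms_error) / (ms_between + (k - 1) * ms_error)
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return float(max(0.0, val))


def rci_table(
    table: pd.DataFrame,
    dv: str = "prop_recommended",
    *,
    control_label: str = "control",
    icc_variant: str = "oneway",
) -> pd.DataFrame:
    """Per-participant reliable-change results for ``dv``.

    Baseline SD is taken over the whole sample at the first interview; the
    reliability plug-in is the ICC of the control group over all occasions.
    The follow-up score is the participant's mean over occasions 2..k.
    """
    labels, mats = _pivot_groups(table, dv)
    if control_label not in labels:
        raise ValueError(f"no group labelled {control_label!r} among {labels}")
    control = mats[labels.index(control_label)]
    icc = icc_repeated(control, variant=icc_variant)
    allY = np.vstack(mats)
    sd_baseline = float(allY[:, 0].std(ddof=1))
    rows = []
    for label, m in zip(labels, mats):
        sub = table[table["group"] == label]
        pids = sorted(sub["participant_id"].unique(), key=str)
        for pid, row in zip(pids, m):
            res = rci(row[0], row[1:].mean(), sd_baseline, icc)
            rows.append(
                {
                    "participant_id": pid,
                    "group": label,
                    "x1": res.x1,
                    "followup_mean": res.followup_mean,
                    "sd_baseline": res.sd_baseline,
                    "icc": res.icc,
                    "rci": res.rci,
                    "reliable": res.reliable,
                    "direction": res.direction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inter-rater agreement

def kappa_agreement(pairs: Sequence[tuple]) -> KappaResult:
    """Cohen's kappa between two coders over paired categorical labels.

    Asymptotic variance follows Fleiss, Cohen & Everitt (1969); the percent
    agreement carries a normal-approximation binomial CI.  When both coders
    use a single identical category throughout, chance agreement is 1 and
    kappa is undefined: a degenerate result is returned rather than raised.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("need at least 2 coded pairs")
    a_labels = [a for a, _ in pairs]
    b_labels = [b for _, b in pairs]
    cats = sorted(set(a_labels) | set(b_labels), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    n = len(pairs)
    m = len(cats)
    table = np.zeros((m, m))
    for a, b in pairs:
        table[idx[a], idx[b]] += 1
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)

    z = sps.norm.isf(0.025)
    pa_se = math.sqrt(max(po * (1 - po), 0.0) / n)
    pa_lo, pa_hi = max(0.0, po - z * pa_se), min(1.0, po + z * pa_se)

    if pe >= 1.0 - 1e-12:
        return KappaResult(
            kappa=math.nan, se=math.nan, ci_low=math.nan, ci_high=math.nan,
            percent_agreement=100 * po, pa_ci_low=100 * pa_lo, pa_ci_high=100 * pa_hi,
            n=n, degenerate=True,
        )

    kappa = (po - pe) / (1 - pe)
    # Fleiss-Cohen-Everitt asymptotic variance of kappa-hat
    term_a = sum(
        p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(m)
    )
    term_b = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(m) for j in range(m) if i != j
    )
    term_c = (po * pe - 2 * pe + po) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    return KappaResult(
        kappa=float(kappa),
        se=float(se),
        ci_low=float(max(-1.0, kappa - z * se)),
        ci_high=float(min(1.0, kappa + z * se)),
        percent_agreement=100 * po,
        pa_ci_low=100 * pa_lo,
        pa_ci_high=100 * pa_hi,
        n=n,
    )


# ---------------------------------------------------------------------------
# adjusted confidence levels for overlap inference

def goldstein_healy_level(se1: float, se2: float, alpha: float = 0.05) -> AdjustedCILevel:
    """Two-sided CI level such that just-touching intervals match a z-test at alpha.

    Solves z_gamma = z_{alpha/2} * sqrt(se1^2 + se2^2) / (se1 + se2); with
    equal standard errors at alpha = 0.05 the level is 83.4%, rising toward
    the nominal level as the SE ratio grows.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError(f"standard errors must be > 0, got {se1}, {se2}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z_alpha = sps.norm.isf(alpha / 2)
    z_gamma = z_alpha * math.sqrt(se1 * se1 + se2 * se2) / (se1 + se2)
    level = 100.0 * (2.0 * sps.norm.cdf(z_gamma) - 1.0)
    ratio = max(se1, se2) / min(se1, se2)
    return AdjustedCILevel(se_ratio=float(ratio), alpha=float(alpha), level=float(level))
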