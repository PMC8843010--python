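"""Trial statistics: baseline tests, mixed ANOVA, and survival comparison.

Everything here is implemented from first principles on top of scipy's
distribution functions only:

* Welch two-sample t from summary statistics (mean, SD, n per group) with
  Satterthwaite degrees of freedom — printed trial tables rarely carry raw
  data, so the summary form is the primary interface;
* Fisher's exact test for 2×2 tables with the probability-mass two-sided
  convention (sum the hypergeometric probabilities of every table, margins
  fixed, whose probability does not exceed the observed table's);
* 2×2 mixed repeated-measures ANOVA (time within, group between) via the
  change/average decomposition, with partial eta squared and Bonferroni
  post-hoc paired comparisons;
* Kaplan–Meier product-limit estimator with Greenwood log(−log) pointwise
  confidence limits and a Brookmeyer–Crowley-style median CI;
* the Gehan–Breslow generalized Wilcoxon test (a log-rank variant weighting
  each event time by the number at risk), the standard "Breslow test" of
  survival software;
* sample size for a within-between interaction in a repeated-measures
  ANOVA under the noncentral F with λ = f²·N·m/(1−ρ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InvalidInputError


@dataclass(frozen=True)
class SummaryStat:
    """Group summary as printed in a trial table: mean ± SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")
        if self.n < 2:
            raise InvalidInputError("n must be >= 2")


@dataclass(frozen=True)
class SurvivalSample:
    time: float          # days; 0 allowed for immediate events
    event: bool          # False = censored at `time`
    group: str = ""


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def welch_t_from_summary(a: SummaryStat, b: SummaryStat):
    """Welch's t with Satterthwaite df; two-sided p.

    Degenerate zero-variance-both-groups input with equal means returns
    ``(0, df, 1)`` by convention.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0.0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise InvalidInputError("zero variance with unequal means")
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table (probability-mass rule)."""
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2):
        raise InvalidInputError("table must be 2x2")
    if (tab < 0).any():
        raise InvalidInputError("counts must be non-negative")
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def mixed_anova_2x2(pre_a: Sequence[float], post_a: Sequence[float],
                    pre_b: Sequence[float], post_b: Sequence[float]):
    """2 (group, between) × 2 (time, within) mixed repeated-measures ANOVA.

    Decomposes each subject into change ``d = post − pre`` and average
    ``m = (pre + post)/2``: the group main effect is the two-sample ANOVA on
    ``m``, the time effect and interaction come from ``d``.  Returns a dict
    with :class:`AnovaResult` entries for ``interaction``, ``group`` and
    ``time``, plus Bonferroni-corrected paired post-hoc p-values per group.

    The interaction F on 1 numerator df equals the squared pooled
    two-sample t on the change scores — a useful identity for validation.
    """
    pre_a, post_a = np.asarray(pre_a, float), np.asarray(post_a, float)
    pre_b, post_b = np.asarray(pre_b, float), np.asarray(post_b, float)
    if pre_a.shape != post_a.shape or pre_b.shape != post_b.shape:
        raise InvalidInputError("pre/post must be complete (equal lengths)")
    if np.isnan([pre_a, post_a]).any() or np.isnan([pre_b, post_b]).any():
        raise InvalidInputError("missing cells are not supported")
    na, nb = len(pre_a), len(pre_b)
    if na < 2 or nb < 2:
        raise InvalidInputError("need >= 2 subjects per group")
    N = na + nb
    d_a, d_b = post_a - pre_a, post_b - pre_b
    m_a, m_b = 0.5 * (pre_a + post_a), 0.5 * (pre_b + post_b)

    # within-subject part: change scores (factor-out 2 from the time contrast)
    dbar_a, dbar_b = d_a.mean(), d_b.mean()
    ss_err_w = 0.5 * (((d_a - dbar_a) ** 2).sum() + ((d_b - dbar_b) ** 2).sum())
    df_w = N - 2
    ms_err_w = ss_err_w / df_w
    # unweighted (Type III) effects with harmonic-mean cell size
    h = 2.0 / (1.0 / na + 1.0 / nb)
    dbar = 0.5 * (dbar_a + dbar_b)
    ss_time = h * dbar**2
    ss_int = h * (dbar_a - dbar_b) ** 2 / 4.0

    # between-subject part: subject averages (2 measurements each)
    mbar_a, mbar_b = m_a.mean(), m_b.mean()
    ss_err_b = 2.0 * (((m_a - mbar_a) ** 2).sum() + ((m_b - mbar_b) ** 2).sum())
    ms_err_b = ss_err_b / df_w
    ss_group = h * (mbar_a - mbar_b) ** 2

    def _res(ss_effect: float, ms_err: float) -> AnovaResult:
        F = ss_effect / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, 1, df_w))
        eta = F / (F + df_w) if (F + df_w) > 0 else 0.0
        return AnovaResult(F=float(F), df1=1, df2=df_w, p=p,
                           partial_eta_sq=float(eta))

    def _paired_p(diff: np.ndarray) -> float:
        n = len(diff)
        sd = diff.std(ddof=1)
        if sd == 0.0:
            return 1.0 if diff.mean() == 0.0 else 0.0
        t = diff.mean() / (sd / math.sqrt(n))
        return float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 1) * 2.0))

    return {
        "interaction": _res(ss_int, ms_err_w),
        "time": _res(ss_time, ms_err_w),
        "group": _res(ss_group, ms_err_b),
        "posthoc_bonferroni": {"a": _paired_p(d_a), "b": _paired_p(d_b)},
    }


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial η² of an ANOVA effect from its F and degrees of freedom."""
    return F * df1 / (F * df1 + df2)


def f_p_value(F: float, df1: int, df2: int) -> float:
    return float(sps.f.sf(F, df1, df2))


# ---------------------------------------------------------------------------
# survival

@dataclass
class KMEstimate:
    times: np.ndarray        # distinct event times
    survival: np.ndarray     # S(t) just after each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float | None     # None = not reached
    median_ci: tuple[float | None, float | None]
    n: int

    def survival_at(self, t: float) -> float:
        """Right-continuous S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_samples(samples) -> list[SurvivalSample]:
    out = []
    for s in samples:
        if isinstance(s, SurvivalSample):
            out.append(s)
        else:
            t, e = s[0], bool(s[1])
            out.append(SurvivalSample(time=float(t), event=e))
    if not out:
        raise InvalidInputError("need at least one survival sample")
    if any(s.time < 0 for s in out):
        raise InvalidInputError("survival times must be >= 0")
    return out


def km_estimate(samples, alpha: float = 0.05) -> KMEstimate:
    """Kaplan–Meier product-limit estimator.

    Pointwise CIs use the Greenwood variance on the log(−log S) scale.  The
    median is the first time at which S(t) ≤ 0.5 (None if the curve never
    drops that far — "not reached"); its CI is Brookmeyer–Crowley style,
    the first times at which the upper/lower confidence limits reach 0.5.
    """
    obs = _as_samples(samples)
    times = np.array([s.time for s in obs])
    events = np.array([s.event for s in obs], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events])
    n = len(times)
    surv, var_sum = [], []
    s, g = 1.0, 0.0
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int((events & (times == t)).sum())
        s *= 1.0 - d / at_risk
        if at_risk > d:
            g += d / (at_risk * (at_risk - d))
        surv.append(s)
        var_sum.append(g)
    surv = np.array(surv)
    var_sum = np.array(var_sum)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    lo = np.ones_like(surv)
    hi = np.ones_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (surv > 0.0) & (surv < 1.0)
        logs = np.log(surv[ok])
        se = np.sqrt(var_sum[ok]) / np.abs(logs)
        theta_lo = np.log(-logs) + z * se
        theta_hi = np.log(-logs) - z * se
        lo[ok] = np.exp(-np.exp(theta_lo))
        hi[ok] = np.exp(-np.exp(theta_hi))
    lo[surv == 0.0] = 0.0
    hi[surv == 0.0] = 0.0

    def _first_leq(curve, level=0.5):
        idx = np.nonzero(curve <= level)[0]
        return float(uniq[idx[0]]) if idx.size else None

    median = _first_leq(surv)
    median_ci = (_first_leq(hi), _first_leq(lo))
    return KMEstimate(times=uniq, survival=surv, ci_low=lo, ci_high=hi,
                      median=median, median_ci=median_ci, n=n)


def gehan_breslow_statistic(group_a, group_b):
    """Gehan–Breslow generalized Wilcoxon statistic and its variance.

    Weighted log-rank with weight w_i = total number at risk n_i at each
    distinct event time; hypergeometric variance.  Returns (U, Var).
    """
    a = _as_samples(group_a)
    b = _as_samples(group_b)
    times = np.array([s.time for s in a + b])
    events = np.array([s.event for s in a + b], dtype=bool)
    in_a = np.array([True] * len(a) + [False] * len(b))
    uniq = np.unique(times[events])
    if uniq.size == 0:
        raise InvalidInputError("need at least one event")
    U = 0.0
    V = 0.0
    for t in uniq:
        at = times >= t
        n_i = int(at.sum())
        n1 = int((at & in_a).sum())
        d = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & in_a).sum())
        w = n_i
        U += w * (d1 - n1 * d / n_i)
        if n_i > 1:
            V += w**2 * (n1 * (n_i - n1) * d * (n_i - d)
                         / (n_i**2 * (n_i - 1)))
    return U, V


def breslow_test(group_a, group_b):
    """Gehan–Breslow test: χ² on 1 df and its p-value."""
    U, V = gehan_breslow_statistic(group_a, group_b)
    if V <= 0.0:
        return 0.0, 1.0
    chi = U * U / V
    return float(chi), float(sps.chi2.sf(chi, 1))


def breslow_permutation_p(group_a, group_b, n_perm: int = 100_000,
                          seed: int = 0) -> float:
    """Permutation reference for the Gehan–Breslow χ² (label shuffling).

    Computes the same χ² statistic under ``n_perm`` random group-label
    permutations and returns the fraction at least as extreme as observed.
    Independent of the asymptotic χ²(1) approximation.
    """
    a = _as_samples(group_a)
    b = _as_samples(group_b)
    all_s = a + b
    na, n = len(a), len(a) + len(b)
    chi_obs, _ = breslow_test(a, b)
    times = np.array([s.time for s in all_s])
    events = np.array([s.event for s in all_s], dtype=bool)
    uniq = np.unique(times[events])
    # subject-by-time incidence matrices; permuting labels = permuting columns
    at_risk = times[None, :] >= uniq[:, None]            # (T, n)
    event_at = events[None, :] & (times[None, :] == uniq[:, None])
    n_i = at_risk.sum(axis=1).astype(float)              # (T,)
    d_i = event_at.sum(axis=1).astype(float)
    w = n_i
    rng = np.random.default_rng(seed)
    count = 0
    batch = 20_000
    done = 0
    while done < n_perm:
        b_sz = min(batch, n_perm - done)
        mask = np.argsort(rng.random((b_sz, n)), axis=1) < na   # (B, n)
        n1 = mask @ at_risk.T.astype(float)                     # (B, T)
        d1 = mask @ event_at.T.astype(float)
        U = ((d1 - n1 * (d_i / n_i)) * w).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            V = (w**2 * n1 * (n_i - n1) * d_i * (n_i - d_i)
                 / (n_i**2 * np.maximum(n_i - 1.0, 1.0))).sum(axis=1)
        chi = np.where(V > 0, U * U / np.maximum(V, 1e-300), 0.0)
        count += int((chi >= chi_obs - 1e-12).sum())
        done += b_sz
    return count / n_perm


def breslow_exact_p(group_a, group_b) -> float:
    """Exact permutation p of the Gehan–Breslow χ² by full enumeration.

    Enumerates every assignment of group labels (fixed group sizes) and
    returns the fraction whose χ² is at least the observed one.  Only
    feasible for small samples (C(n, n_a) assignments); the asymptotic
    χ²(1) p of :func:`breslow_test` is anticonservative relative to this
    exact p at very small n.
    """
    from itertools import combinations

    a = _as_samples(group_a)
    b = _as_samples(group_b)
    all_s = a + b
    na, n = len(a), len(a) + len(b)
    if math.comb(n, na) > 200_000:
        raise InvalidInputError("sample too large for exact enumeration")
    chi_obs, _ = breslow_test(a, b)
    hits = total = 0
    idx = range(n)
    for combo in combinations(idx, na):
        in_a = set(combo)
        ga = [all_s[i] for i in idx if i in in_a]
        gb = [all_s[i] for i in idx if i not in in_a]
        chi, _ = breslow_test(ga, gb)
        hits += chi >= chi_obs - 1e-12
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# sample size

def rm_anova_sample_size(effect_f: float, alpha: float = 0.05,
                         power: float = 0.80, groups: int = 2,
                         measurements: int = 2, rm_correlation: float = 0.5,
                         attrition: float = 0.0, max_n: int = 100_000) -> int:
    """Total N for a within-between interaction in repeated-measures ANOVA.

    Noncentrality λ = f²·N·m/(1−ρ) with m measurements and repeated-measures
    correlation ρ; numerator df (groups−1)(m−1), denominator df (N−groups)
    for m=2 (scaled by (m−1) otherwise).  The correlation is an explicit
    argument because published power statements usually omit it.  The
    smallest group-divisible N reaching the target power is then inflated by
    the attrition fraction and rounded up to stay group-divisible.
    """
    if effect_f <= 0:
        raise ConfigurationError("effect_f must be > 0")
    if not (0 < power < 1):
        raise ConfigurationError("power must lie in (0, 1)")
    if not (0 <= rm_correlation < 1):
        raise ConfigurationError("rm_correlation must lie in [0, 1)")
    if not (0 <= attrition < 1):
        raise ConfigurationError("attrition must lie in [0, 1)")
    df1 = (groups - 1) * (measurements - 1)
    for n in range(2 * groups, max_n + 1, groups):
        df2 = (n - groups) * (measurements - 1)
        lam = effect_f**2 * n * measurements / (1.0 - rm_correlation)
        crit = sps.f.isf(alpha, df1, df2)
        achieved = float(sps.ncf.sf(crit, df1, df2, lam))
        if achieved >= power:
            total = n / (1.0 - attrition)
            return int(math.ceil(total / groups) * groups)
    raise ConfigurationError("no feasible N below max_n")


def rm_anova_power(effect_f: float, n_total: int, alpha: float = 0.05,
                   groups: int = 2, measurements: int = 2,
                   rm_correlation: float = 0.5) -> float:
    """Achieved interaction power at a given total N (same conventions)."""
    df1 = (groups - 1) * (measurements - 1)
    df2 = (n_total - groups) * (measurements - 1)
    lam = effect_f**2 * n_total * measurements / (1.0 - rm_correlation)
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


# ---------------------------------------------------------------------------
# report assembly

def analyze_trial(outcomes: pd.DataFrame, survival: pd.DataFrame) -> dict:
    """Full statistics report for simulated-trial output tables.

    Baseline comparability (Welch t on age/days-post-stroke, Fisher on
    sex/side), 2×2 mixed ANOVA per outcome with partial η² and Bonferroni
    post-hocs, and per-muscle Kaplan–Meier + Gehan–Breslow comparison.
    """
    study = outcomes[outcomes.group == "study"]
    ctrl = outcomes[outcomes.group == "control"]

    def summ(col, sub):
        return SummaryStat(float(sub[col].mean()), float(sub[col].std(ddof=1)),
                           int(len(sub)))

    report: dict = {"n_study": int(len(study)), "n_control": int(len(ctrl)),
                    "baseline": {}, "anova": {}, "survival": {}}
    for col in ("age", "days_post_stroke"):
        t, df, p = welch_t_from_summary(summ(col, study), summ(col, ctrl))
        report["baseline"][col] = {"t": t, "df": df, "p": p}
    sex_tab = [[int((study.sex == "m").sum()), int((study.sex == "f").sum())],
               [int((ctrl.sex == "m").sum()), int((ctrl.sex == "f").sum())]]
    side_tab = [[int((study.affected_side == "left").sum()),
                 int((study.affected_side == "right").sum())],
                [int((ctrl.affected_side == "left").sum()),
                 int((ctrl.affected_side == "right").sum())]]
    report["baseline"]["sex"] = {"table": sex_tab,
                                 "p": fisher_exact_2x2(sex_tab)}
    report["baseline"]["affected_side"] = {"table": side_tab,
                                           "p": fisher_exact_2x2(side_tab)}
    for name in ("fmle", "arom", "pf_mvc", "df_mvc"):
        res = mixed_anova_2x2(study[f"{name}_pre"], study[f"{name}_post"],
                              ctrl[f"{name}_pre"], ctrl[f"{name}_post"])
        inter = res["interaction"]
        report["anova"][name] = {
            "interaction": {"F": inter.F, "df1": inter.df1, "df2": inter.df2,
                            "p": inter.p, "partial_eta_sq": inter.partial_eta_sq},
            "time_p": res["time"].p, "group_p": res["group"].p,
            "posthoc_bonferroni": res["posthoc_bonferroni"],
        }
    for muscle in ("pf", "df"):
        sub = survival[survival.muscle == muscle] if "muscle" in survival \
            else survival
        sa = [SurvivalSample(r.time_days, bool(r.event), "study")
              for r in sub[sub.group == "study"].itertuples()]
        sb = [SurvivalSample(r.time_days, bool(r.event), "control")
              for r in sub[sub.group == "control"].itertuples()]
        km_a, km_b = km_estimate(sa), km_estimate(sb)
        chi, p = breslow_test(sa, sb)
        report["survival"][muscle] = {
            "study_median": km_a.median, "study_median_ci": km_a.median_ci,
            "control_median": km_b.median, "control_median_ci": km_b.median_ci,
            "breslow_chi_sq": chi, "breslow_p": p,
            "events_study": int(sum(s.event for s in sa)),
            "events_control": int(sum(s.event for s in sb)),
        }
    return report


def render_table(report: dict, summary: dict) -> str:
    """Plain-text Table-1-style rendering of a trial summary + report."""
    s, c = summary.get("study", {}), summary.get("control", {})

    def ms(g, key):
        v = g.get(key, {})
        return f"{v.get('mean', float('nan')):.2f}±{v.get('sd', float('nan')):.2f}"

    lines = [
        f"{'':28s}{'Study':>16s}{'Control':>16s}{'p':>8s}",
        f"{'n':28s}{s.get('n', '?'):>16}{c.get('n', '?'):>16}",
        f"{'Gender (men/women)':28s}{s.get('gender_men_women', ''):>16s}"
        f"{c.get('gender_men_women', ''):>16s}"
        f"{report['baseline']['sex']['p']:>8.3f}",
        f"{'Affected side (L/R)':28s}{s.get('affected_left_right', ''):>16s}"
        f"{c.get('affected_left_right', ''):>16s}"
        f"{report['baseline']['affected_side']['p']:>8.3f}",
        f"{'Age (year)':28s}{ms(s, 'age'):>16s}{ms(c, 'age'):>16s}"
        f"{report['baseline']['age']['p']:>8.3f}",
    ]
    for label, key in (("FMLE pre", "fmle_pre"), ("FMLE post", "fmle_post"),
                       ("AROM pre (deg)", "arom_pre"),
                       ("AROM post (deg)", "arom_post"),
                       ("PF MVC pre (Nm)", "pf_mvc_pre"),
                       ("PF MVC post (Nm)", "pf_mvc_post"),
                       ("DF MVC pre (Nm)", "df_mvc_pre"),
                       ("DF MVC post (Nm)", "df_mvc_post")):
        base = key.rsplit("_", 1)[0]
        extra = ""
        if key.endswith("post") and base in report["anova"]:
            extra = f"{report['anova'][base]['interaction']['p']:>8.3f}"
        lines.append(f"{label:28s}{ms(s, key):>16s}{ms(c, key):>16s}{extra}")
    for muscle, label in (("pf", "PF recovery"), ("df", "DF recovery")):
        sv = report["survival"][muscle]
        med = sv["study_median"]
        med_s = f"{med:.1f} d" if med is not None else "not reached"
        medc = sv["control_median"]
        med_c = f"{medc:.1f} d" if medc is not None else "not reached"
        lines.append(f"{label + ' (KM median)':28s}{med_s:>16s}{med_c:>16s}"
                     f"{sv['breslow_p']:>8.3f}")
    return "\n".join(lines)
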