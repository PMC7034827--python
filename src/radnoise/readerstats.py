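"""Paired non-inferiority reader-study statistics.

Implements the complete statistical pipeline of a two-arm (baseline vs
low-dose), two-reader, two-session Likert scoring study: score
aggregation, inter-observer ICC with the conventional
poor/fair/good/excellent banding, Shapiro-Wilk-gated paired testing
(paired t with a mean difference and t CI when normality holds, Wilcoxon
signed rank with a Hodges-Lehmann pseudo-median and signed-rank CI when
it does not), the non-inferiority decision against a margin (0.5 per
item, 3.5 = 0.5 x 7 for the seven-landmark total), one-way ANOVA with
Tukey HSD for between-group homogeneity, and entrance-skin-exposure dose
accounting.

A synthetic score generator (subject random effect + arm shift + reader
bias + session noise, discretized to the 1-5 Likert scale) provides
study-shaped data so the operating characteristics of the whole chain can
be measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANATOMICAL_LANDMARKS",
    "ABNORMAL_FINDINGS",
    "GROUP_AEC_CUTOFFS",
    "DoseRecord",
    "NormalityResult",
    "NonInfResult",
    "IccResult",
    "ReaderStudyConfig",
    "aggregate_scores",
    "reduction_rate",
    "icc_band",
    "icc_inter_observer",
    "normality_gate",
    "hodges_lehmann",
    "signed_rank_ci",
    "noninferiority_paired",
    "group_homogeneity",
    "synthesize_reader_scores",
]

#: The seven scored anatomical landmarks (AL1..AL7) and their total.
ANATOMICAL_LANDMARKS = ("AL1", "AL2", "AL3", "AL4", "AL5", "AL6", "AL7")
#: Abnormal findings: nodule, consolidation, interstitial marking.
ABNORMAL_FINDINGS = ("ND", "CD", "IST")

#: AEC cutoff bookkeeping (uGy): baseline arm and the discrete steps of
#: the three reduced-dose groups (nominally 60/50/40% of baseline).
BASELINE_AEC_CUTOFF = 4.2
GROUP_AEC_CUTOFFS = {"A": 2.5, "B": 2.11, "C": 1.78}

SCORE_COLUMNS = ["subject_id", "arm", "reader", "session", "item", "score"]


@dataclass(frozen=True)
class DoseRecord:
    """Entrance skin exposure (uGy) of one subject's paired acquisitions."""

    subject_id: str
    baseline_ese: float
    low_ese: float
    group: str = "A"
    aec_cutoff_baseline: float = BASELINE_AEC_CUTOFF
    aec_cutoff_low: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_ese <= 0 or self.low_ese <= 0:
            raise ValueError("doses must be > 0")
        if self.low_ese >= self.baseline_ese:
            raise ValueError("low-dose ESE must be below baseline ESE")
        if self.aec_cutoff_low is None:
            object.__setattr__(self, "aec_cutoff_low",
                               GROUP_AEC_CUTOFFS.get(self.group))


@dataclass
class NormalityResult:
    normal: bool
    p: float
    degenerate: bool = False

    @property
    def label(self) -> str:
        return "normal" if self.normal else "non_normal"


@dataclass
class NonInfResult:
    """Outcome of one paired non-inferiority comparison.

    ``location_estimate`` is baseline minus low (positive = quality loss
    at the reduced dose); non-inferiority holds iff the 95% CI upper bound
    is below the margin.
    """

    item: str
    n: int
    location_estimate: float
    ci95: tuple[float, float]
    margin: float
    test_used: str  # "paired_t" | "wilcoxon" | "degenerate"
    normality_p: float
    non_inferior: bool

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.location_estimate <= hi + 1e-12):
            raise ValueError("estimate must lie inside its CI")


@dataclass
class IccResult:
    icc_value: float
    band: str
    n: int = 0


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score table contract and return it."""
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    scores = table["score"]
    if not np.array_equal(scores, scores.astype(int)) or \
            scores.min() < 1 or scores.max() > 5:
        raise ValueError("scores must be integers in 1..5")
    bad_arms = set(table["arm"].unique()) - {"baseline", "low"}
    if bad_arms:
        raise ValueError(f"unknown arms: {bad_arms}")
    counts = table.groupby(["subject_id", "arm", "item"]).size()
    if (counts > 4).any():
        raise ValueError("more than 2 readers x 2 sessions for some cell")
    return table


def aggregate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, arm, item) mean scores plus the AL_total row sum.

    The mean is over the available reader x session observations (granularity
    0.25 when all four are present).  Subjects missing one arm are dropped
    with a warning.  Returns a wide frame indexed by (subject_id, arm) with
    one column per item and ``AL_total``.
    """
    table = validate_score_table(table)
    arms_per_subject = table.groupby("subject_id")["arm"].nunique()
    incomplete = arms_per_subject[arms_per_subject < 2].index
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} subject(s) missing a paired arm: "
            f"{sorted(incomplete)[:5]}", stacklevel=2)
        table = table[~table["subject_id"].isin(incomplete)]
    means = (table.groupby(["subject_id", "arm", "item"])["score"]
             .mean().unstack("item"))
    al_cols = [c for c in ANATOMICAL_LANDMARKS if c in means.columns]
    if len(al_cols) == len(ANATOMICAL_LANDMARKS):
        means["AL_total"] = means[list(ANATOMICAL_LANDMARKS)].sum(axis=1)
    return means


def reduction_rate(rec: DoseRecord | tuple[float, float]) -> float:
    """Low-dose ESE as a percentage of baseline, to one decimal.

    E.g. (42.9, 21.2) -> 49.4.
    """
    if isinstance(rec, DoseRecord):
        baseline, low = rec.baseline_ese, rec.low_ese
    else:
        baseline, low = rec
    if baseline <= 0 or low <= 0:
        raise ValueError("doses must be > 0")
    return round(100.0 * low / baseline, 1)


def icc_band(icc_value: float) -> str:
    """Conventional interpretation bands for the ICC.

    < 0.40 poor; 0.40-0.59 fair; 0.60-0.74 good; 0.75-1.00 excellent
    (so 0.747 is "good", 0.75 "excellent").
    """
    if icc_value < 0.40:
        return "poor"
    if icc_value < 0.60:
        return "fair"
    if icc_value < 0.75:
        return "good"
    return "excellent"


def icc_inter_observer(table: pd.DataFrame, target: str = "all",
                       item: str = "AL_total") -> IccResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC (ICC2).

    Computed on per-image scores (reader means over sessions) of ``item``;
    ``target`` selects all images or one arm.  An "image" is a
    (subject, arm) pair, matching a study where every subject contributes
    one baseline and one low-dose image.
    """
    import pingouin as pg

    table = validate_score_table(table)
    if table["reader"].nunique() < 2:
        raise ValueError("need two readers for inter-observer ICC")
    if target not in ("all", "baseline", "low"):
        raise ValueError("target must be all|baseline|low")
    if target != "all":
        table = table[table["arm"] == target]
    per_reader = (table.groupby(["subject_id", "arm", "reader", "item"])["score"]
                  .mean().unstack("item"))
    if item == "AL_total":
        per_reader = per_reader[list(ANATOMICAL_LANDMARKS)].sum(axis=1)
    else:
        per_reader = per_reader[item]
    df = per_reader.reset_index()
    df["image"] = df["subject_id"].astype(str) + "|" + df["arm"].astype(str)
    df = df.rename(columns={df.columns[3]: "rating"})
    res = pg.intraclass_corr(data=df, targets="image", raters="reader",
                             ratings="rating")
    # two-way random, absolute agreement, single rater: labelled ICC2 in
    # Shrout-Fleiss terms, ICC(A,1) in McGraw-Wong terms
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    val = float(res.loc[sel, "ICC"].iloc[0])
    return IccResult(icc_value=val, band=icc_band(val),
                     n=df["image"].nunique())


def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk gate: p >= alpha -> treat the differences as normal."""
    d = np.asarray(differences, dtype=np.float64)
    if d.size < 3:
        raise ValueError("need at least 3 differences")
    if np.ptp(d) == 0:
        return NormalityResult(normal=False, p=float("nan"), degenerate=True)
    p = float(stats.shapiro(d).pvalue)
    return NormalityResult(normal=p >= alpha, p=p)


def hodges_lehmann(differences: np.ndarray) -> float:
    """Pseudo-median: median of all Walsh averages (d_i + d_j)/2, i <= j."""
    d = np.asarray(differences, dtype=np.float64)
    w = (d[:, None] + d[None, :]) / 2.0
    iu = np.triu_indices(d.size)
    return float(np.median(w[iu]))


def _signrank_cdf(n: int) -> np.ndarray:
    """Exact null CDF of the Wilcoxon signed-rank statistic for n pairs."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):  # polynomial product (1 + x^r)
        counts[r:] += counts[:-r].copy()
    return np.cumsum(counts) / counts.sum()


def signed_rank_ci(differences: np.ndarray, alpha: float = 0.05,
                   exact_max_n: int = 25) -> tuple[float, float]:
    """95% CI for the pseudo-median from the signed-rank distribution.

    Walsh averages are order-statistics-bracketed at the critical value of
    the null signed-rank distribution: exact for n <= ``exact_max_n``,
    normal approximation with continuity correction above.
    """
    d = np.asarray(differences, dtype=np.float64)
    n = d.size
    w = (d[:, None] + d[None, :]) / 2.0
    walsh = np.sort(w[np.triu_indices(n)])
    m = walsh.size  # n(n+1)/2
    if n <= exact_max_n:
        cdf = _signrank_cdf(n)
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right") - 1)
    else:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(np.floor(m / 2.0 - 0.5 - z * sd))
    k = max(k, 0)
    if k + 1 > m - k:  # degenerate tiny-n case: whole range
        return float(walsh[0]), float(walsh[-1])
    return float(walsh[k]), float(walsh[m - k - 1])


def noninferiority_paired(baseline: np.ndarray, low: np.ndarray,
                          margin: float = 0.5, item: str = "",
                          alpha: float = 0.05) -> NonInfResult:
    """Paired non-inferiority test of low-dose vs baseline quality scores.

    d = baseline - low.  If Shapiro-Wilk accepts normality the estimate is
    mean(d) with a two-sided 95% t CI; otherwise the Hodges-Lehmann
    pseudo-median with a signed-rank CI.  Non-inferiority is concluded iff
    the CI upper bound is below ``margin`` (a one-sided alpha/2 procedure
    via the two-sided CI).  Margin defaults to 0.5 per item; use 3.5 for
    the seven-landmark total.
    """
    b = np.asarray(baseline, dtype=np.float64)
    l = np.asarray(low, dtype=np.float64)
    if b.shape != l.shape:
        raise ValueError("baseline and low arrays must be paired (equal length)")
    n = b.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = b - l
    gate = normality_gate(d, alpha=0.05)
    if gate.degenerate:
        est = float(d[0])
        return NonInfResult(item=item, n=n, location_estimate=est,
                            ci95=(est, est), margin=margin,
                            test_used="degenerate", normality_p=gate.p,
                            non_inferior=bool(est < margin))
    if gate.normal:
        est = float(d.mean())
        se = d.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
        ci = (est - tcrit * se, est + tcrit * se)
        test = "paired_t"
    else:
        est = hodges_lehmann(d)
        ci = signed_rank_ci(d, alpha=alpha)
        test = "wilcoxon"
    return NonInfResult(item=item, n=n, location_estimate=est,
                        ci95=(float(ci[0]), float(ci[1])), margin=margin,
                        test_used=test, normality_p=gate.p,
                        non_inferior=bool(ci[1] < margin))


def noninferiority_table(agg: pd.DataFrame,
                         items: tuple[str, ...] | None = None,
                         margin_per_item: float = 0.5) -> pd.DataFrame:
    """Run :func:`noninferiority_paired` for every item of an aggregate.

    ``agg`` is the output of :func:`aggregate_scores`.  AL_total uses a
    margin of 7 x ``margin_per_item``.
    """
    base = agg.xs("baseline", level="arm")
    low = agg.xs("low", level="arm")
    common = base.index.intersection(low.index)
    base, low = base.loc[common], low.loc[common]
    if items is None:
        items = tuple(agg.columns)
    rows = []
    for it in items:
        margin = margin_per_item * 7 if it == "AL_total" else margin_per_item
        r = noninferiority_paired(base[it].to_numpy(), low[it].to_numpy(),
                                  margin=margin, item=it)
        rows.append({
            "item": r.item, "n": r.n, "estimate": r.location_estimate,
            "ci_lower": r.ci95[0], "ci_upper": r.ci95[1],
            "margin": r.margin, "test": r.test_used,
            "normality_p": r.normality_p, "non_inferior": r.non_inferior,
        })
    return pd.DataFrame(rows).set_index("item")


def group_homogeneity(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA + Tukey HSD across the dose groups (A/B/C).

    Returns ``{"anova_p": p, "tukey": {(g1, g2): adj_p}}``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k} has fewer than 2 observations")
    if all(a.std(ddof=0) == 0 for a in arrays.values()):
        raise ValueError("all groups are constant; ANOVA is degenerate")
    f, p = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels)
    pairs = {}
    for row in tk.summary().data[1:]:
        pairs[(str(row[0]), str(row[1]))] = float(row[3])
    return {"anova_p": float(p), "anova_F": float(f), "tukey": pairs}


@dataclass(frozen=True)
class ReaderStudyConfig:
    """Generative model for synthetic reader scores.

    Latent score = item baseline mean - arm_shift (low arm only)
    + subject random effect + reader bias + session noise, then rounded to
    the nearest integer and clipped to 1..5.  ``arm_shift`` is the true
    baseline-minus-low quality difference.
    """

    n_subjects: int = 69
    items: tuple[str, ...] = ANATOMICAL_LANDMARKS
    item_means: dict[str, float] | None = None
    arm_shift: float = 0.15
    sigma_subject: float = 0.4
    sigma_session: float = 0.3
    reader_bias: tuple[float, float] = (0.0, 0.0)
    default_mean: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_subject < 0 or self.sigma_session < 0:
            raise ValueError("variance parameters must be nonnegative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def synthesize_reader_scores(config: ReaderStudyConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate a full two-reader, two-session, two-arm score table."""
    rng = np.random.default_rng(seed)
    means = dict.fromkeys(config.items, config.default_mean)
    if config.item_means:
        means.update(config.item_means)
    rows = []
    subj_re = rng.normal(0.0, config.sigma_subject, size=config.n_subjects)
    for s in range(config.n_subjects):
        for arm in ("baseline", "low"):
            shift = config.arm_shift if arm == "low" else 0.0
            for reader in (1, 2):
                bias = config.reader_bias[reader - 1]
                for session in (1, 2):
                    noise = rng.normal(0.0, config.sigma_session,
                                       size=len(config.items))
                    for it, eps in zip(config.items, noise):
                        latent = means[it] - shift + subj_re[s] + bias + eps
                        score = int(np.clip(np.floor(latent + 0.5), 1, 5))
                        rows.append((f"S{s:03d}", arm, reader, session, it, score))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
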