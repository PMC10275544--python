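"""Group comparison and metric–score correlation.

The testing policy is a normality-gated switch: every group's values must pass
Shapiro–Wilk and the groups must pass a Levene variance-homogeneity test
(median-centered) at the gate level for one-way ANOVA to be used; otherwise
the Kruskal–Wallis H test.  Pairwise follow-up tests (t or Mann–Whitney,
matching the omnibus family) are Bonferroni-corrected over the number of group
pairs — for three groups the corrected threshold is 0.05 / 3 ≈ .016.  Both raw
and corrected p values are always reported.

Correlations auto-select Pearson when both variables pass Shapiro–Wilk at .05
and Spearman otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "CognitiveScores",
    "PairwiseResult",
    "GroupTestResult",
    "CorrelationResult",
    "choose_test",
    "compare_samples",
    "compare_groups",
    "correlate",
    "compare_regional_counts",
    "load_scores",
]

SCORE_FIELDS = ("FSIQ", "VCI", "PRI", "WMI", "PSI")


@dataclass
class CognitiveScores:
    """One subject's standardized cognitive index scores."""

    subject_id: str
    FSIQ: float
    VCI: float
    PRI: float
    WMI: float
    PSI: float

    def __post_init__(self) -> None:
        import warnings

        for f in SCORE_FIELDS:
            v = getattr(self, f)
            if v <= 0:
                raise ValueError(f"{f} must be positive, got {v}")
        if self.FSIQ < 80:
            warnings.warn(
                f"subject {self.subject_id}: FSIQ {self.FSIQ} below the usual "
                "80-point inclusion cutoff",
                stacklevel=2,
            )


def load_scores(path) -> pd.DataFrame:
    """Read a subject_id, FSIQ, VCI, PRI, WMI, PSI table from CSV (validated)."""
    df = pd.read_csv(path)
    missing = {"subject_id", *SCORE_FIELDS} - set(df.columns)
    if missing:
        raise ValueError(f"scores file missing columns: {sorted(missing)}")
    for _, row in df.iterrows():
        CognitiveScores(
            subject_id=str(row["subject_id"]),
            **{f: float(row[f]) for f in SCORE_FIELDS},
        )
    return df


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass
class GroupTestResult:
    metric: str
    band: str
    test_used: str  # "ANOVA" | "Kruskal-Wallis"
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    alpha: float = 0.05
    alpha_corrected: float = 0.05
    degenerate: bool = False


@dataclass
class CorrelationResult:
    R: float
    p: float
    method: str  # "pearson" | "spearman"
    n: int


def _is_degenerate(values: np.ndarray) -> bool:
    return np.ptp(values) == 0


def choose_test(
    samples: dict[str, np.ndarray] | list[np.ndarray], alpha_gate: float = 0.05
) -> str:
    """Return "ANOVA" when all groups pass normality and variance homogeneity
    at `alpha_gate`, else "Kruskal-Wallis".

    Zero-variance (constant) groups are degenerate: the Shapiro statistic is
    undefined for them, so the rank-based fallback is chosen.
    """
    groups = list(samples.values()) if isinstance(samples, dict) else list(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 3:
            raise ValueError("every group needs at least 3 values")
    if any(_is_degenerate(g) for g in arrays):
        return "Kruskal-Wallis"
    for g in arrays:
        if spstats.shapiro(g).pvalue <= alpha_gate:
            return "Kruskal-Wallis"
    if spstats.levene(*arrays, center="median").pvalue <= alpha_gate:
        return "Kruskal-Wallis"
    return "ANOVA"


def _pair_test(a: np.ndarray, b: np.ndarray, parametric: bool) -> tuple[float, float]:
    if _is_degenerate(np.concatenate([a, b])):
        return 0.0, 1.0  # identical constants: no evidence of a difference
    if parametric:
        res = spstats.ttest_ind(a, b)
    else:
        res = spstats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_samples(
    samples: dict[str, np.ndarray],
    alpha: float = 0.05,
    metric: str = "",
    band: str = "",
) -> GroupTestResult:
    """Omnibus test (per :func:`choose_test`) plus Bonferroni-corrected
    pairwise comparisons over all group pairs."""
    names = list(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    test = choose_test(arrays, alpha_gate=alpha)
    degenerate = _is_degenerate(np.concatenate(list(arrays.values())))
    if degenerate:
        stat, p = 0.0, 1.0
    elif test == "ANOVA":
        res = spstats.f_oneway(*arrays.values())
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        try:
            res = spstats.kruskal(*arrays.values())
            stat, p = float(res.statistic), float(res.pvalue)
        except ValueError:  # all values identical across groups
            stat, p = 0.0, 1.0
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    alpha_corr = alpha / n_pairs
    pairwise = []
    for a, b in pairs:
        s, praw = _pair_test(arrays[a], arrays[b], parametric=(test == "ANOVA"))
        pcorr = min(1.0, praw * n_pairs)
        pairwise.append(
            PairwiseResult(
                group_a=a,
                group_b=b,
                statistic=s,
                p_raw=praw,
                p_corrected=pcorr,
                significant=bool(praw < alpha_corr),
            )
        )
    return GroupTestResult(
        metric=metric,
        band=band,
        test_used=test,
        omnibus_statistic=stat,
        omnibus_p=p,
        pairwise=pairwise,
        alpha=alpha,
        alpha_corrected=alpha_corr,
        degenerate=degenerate,
    )


def compare_groups(
    metrics: pd.DataFrame,
    metric: str,
    band: str,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Group comparison of one network metric in one band.

    `metrics` is the tidy table the pipeline produces (columns: subject_id,
    group, band, metric, value).
    """
    sub = metrics[(metrics["metric"] == metric) & (metrics["band"] == band)]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, band={band!r}")
    samples = {
        g: grp["value"].to_numpy() for g, grp in sub.groupby("group", sort=False)
    }
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    return compare_samples(samples, alpha=alpha, metric=metric, band=band)


def correlate(x, y, method: str = "auto") -> CorrelationResult:
    """Correlation of paired observations with automatic method selection.

    ``method='auto'`` picks Pearson iff both variables pass Shapiro–Wilk at
    .05, Spearman otherwise; 'pearson' / 'spearman' force the choice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 5:
        raise ValueError("need at least 5 paired values")
    if _is_degenerate(x) or _is_degenerate(y):
        # a constant variable carries no association either way
        return CorrelationResult(
            R=0.0, p=1.0, method="spearman" if method == "auto" else method,
            n=int(x.size),
        )
    if method == "auto":
        normal = (
            spstats.shapiro(x).pvalue > 0.05
            and spstats.shapiro(y).pvalue > 0.05
        )
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        res = spstats.pearsonr(x, y)
    elif method == "spearman":
        res = spstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(r):  # constant input
        r, p = 0.0, 1.0
    return CorrelationResult(R=r, p=p, method=method, n=int(x.size))


def compare_regional_counts(
    counts_a: dict[str, int], counts_b: dict[str, int]
) -> tuple[float, float]:
    """Fisher exact test on anterior–posterior vs other edges of two networks
    (or two groups' aggregated counts).  Returns (odds_ratio, p)."""
    ap_a = counts_a["anterior-posterior"]
    other_a = sum(counts_a.values()) - ap_a
    ap_b = counts_b["anterior-posterior"]
    other_b = sum(counts_b.values()) - ap_b
    odds, p = spstats.fisher_exact([[ap_a, other_a], [ap_b, other_b]])
    return float(odds), float(p)
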