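"""Statistical layer: exact 2x2 tests, BH correction, rank tests, and the
gene-presence / COG-enrichment wrappers used throughout the pipeline.

The 2x2 and rank tests delegate to ``scipy.stats`` (``fisher_exact``,
``mannwhitneyu``); this module fixes the conventions used everywhere else in
the package — sidedness names, odds-ratio definition (sample odds ratio
``ad/bc`` with infinity on a zero denominator), the exact/approximate
switch-over of the Mann-Whitney test, and order-preserving Benjamini-
Hochberg adjustment.

The gene-presence association is a *naive GWAS*: per-gene Fisher tests with
FDR control, with no correction for population structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

_SIDE_MAP = {"two_sided": "two-sided", "greater": "greater", "less": "less"}

#: Mann-Whitney exact enumeration is used up to this product of sample sizes
#: (and only without ties); beyond it the tie- and continuity-corrected
#: normal approximation takes over.
MW_EXACT_LIMIT = 400


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"counts must be nonnegative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class TestResult:
    p: float
    statistic: float | None = None
    odds_ratio: float | None = None
    adjusted_p: float | None = None
    side: str = "two_sided"
    flag: str = ""


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def odds_ratio(table) -> float:
    """Sample odds ratio ad/bc; infinity when bc == 0 and ad > 0, nan for 0/0."""
    t = _as_table(table)
    num, den = t.a * t.d, t.b * t.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def fisher_exact(table, side: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables with the same margins
    whose point probability does not exceed the observed one (the standard
    point-probability rule).
    """
    t = _as_table(table)
    if side not in _SIDE_MAP:
        raise ValueError(f"side must be one of {sorted(_SIDE_MAP)}")
    res = sps.fisher_exact(t.rows, alternative=_SIDE_MAP[side])
    return TestResult(p=float(res.pvalue), statistic=float(res.statistic),
                      odds_ratio=odds_ratio(t), side=side)


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    adjusted p_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.tolist()


def mann_whitney_u(x, y, side: str = "two_sided") -> TestResult:
    """Mann-Whitney U test with an explicit exact/approximate policy.

    Exact enumeration of the rank distribution when ``len(x)*len(y) <=
    MW_EXACT_LIMIT`` and there are no ties across the pooled sample;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if side not in _SIDE_MAP:
        raise ValueError(f"side must be one of {sorted(_SIDE_MAP)}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= MW_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_SIDE_MAP[side], method=method)
    return TestResult(p=float(res.pvalue), statistic=float(res.statistic),
                      side=side, flag=method)


def gene_presence_association(
    presence: np.ndarray | "pd.DataFrame",
    group_labels,
    alpha: float = 0.05,
) -> "pd.DataFrame":
    """Naive pan-GWAS: per-gene Fisher test of presence vs group, BH across genes.

    Parameters
    ----------
    presence
        Binary genes x replicons matrix (rows = genes).  A DataFrame index
        provides gene names.
    group_labels
        Boolean/0-1 vector over replicons (True = T6SS-positive group).

    Constant genes (present or absent everywhere) get p = 1 by convention
    and are flagged.
    """
    import pandas as pd

    if isinstance(presence, pd.DataFrame):
        genes = list(presence.index)
        mat = presence.to_numpy(dtype=int)
    else:
        mat = np.asarray(presence, dtype=int)
        genes = [f"gene{i}" for i in range(mat.shape[0])]
    labels = np.asarray(list(group_labels), dtype=bool)
    if mat.shape[1] != labels.size:
        raise ValueError("group_labels length must match the number of replicons")
    if labels.all() or not labels.any():
        raise ValueError("both groups must be non-empty")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")

    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    rows = []
    for gene, row in zip(genes, mat):
        a = int(row[labels].sum())          # present in positives
        c = int(row[~labels].sum())         # present in negatives
        if (a + c == 0) or (a + c == n_pos + n_neg):
            rows.append({"gene": gene, "present_pos": a, "present_neg": c,
                         "odds_ratio": math.nan, "p": 1.0, "flag": "constant"})
            continue
        table = [[a, n_pos - a], [c, n_neg - c]]
        result = fisher_exact(table, side="two_sided")
        rows.append({"gene": gene, "present_pos": a, "present_neg": c,
                     "odds_ratio": result.odds_ratio, "p": result.p, "flag": ""})
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["p"].tolist())
    df["significant"] = df["adjusted_p"] < alpha
    return df


def cog_enrichment(
    positive_counts: dict[str, int],
    negative_counts: dict[str, int],
    alpha: float = 0.05,
) -> "pd.DataFrame":
    """COG-category enrichment in a positive vs a negative annotation set.

    Each category is tested category-vs-rest x positive/negative with a
    two-sided Fisher test; categories with BH-adjusted p < ``alpha`` AND
    odds ratio > 1 are called enriched (depletion never qualifies).
    """
    import pandas as pd

    categories = sorted(set(positive_counts) | set(negative_counts))
    total_pos = sum(positive_counts.values())
    total_neg = sum(negative_counts.values())
    rows = []
    for cat in categories:
        a = int(positive_counts.get(cat, 0))
        c = int(negative_counts.get(cat, 0))
        table = [[a, total_pos - a], [c, total_neg - c]]
        result = fisher_exact(table, side="two_sided")
        rows.append({"category": cat, "count_pos": a, "count_neg": c,
                     "odds_ratio": result.odds_ratio, "p": result.p})
    df = pd.DataFrame(rows)
    if len(df):
        df["adjusted_p"] = bh_adjust(df["p"].tolist())
        df["enriched"] = (df["adjusted_p"] < alpha) & (df["odds_ratio"] > 1)
    return df
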