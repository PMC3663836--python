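"""Rank-sum differential miRNA expression over the ten class comparisons.

Each comparison contrasts two disjoint groups of cases (e.g. adult mutant
vs. pediatric, SDHB-immunopositive vs. -immunonegative). Per miRNA a
two-sided Wilcoxon rank-sum (Mann-Whitney) test is run; the family-wise
error is controlled with Bonferroni, where the family is the set of miRNAs
actually tested *within* that comparison (the eligible feature sets differ
between comparisons). Being a rank test, the p-values are identical on Ct
(sign-flipped) and on relative expression.

``mode="auto"`` uses the exact null distribution when the smaller group has
<= 8 observations and there are no ties, otherwise the normal approximation
with tie correction and continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CaseRecord
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

Mode = Literal["exact", "normal_approx", "auto"]

#: smaller-group size at or below which auto mode uses the exact distribution
EXACT_MAX_N = 8

Selector = Callable[[CaseRecord, str | None], bool]


@dataclass(frozen=True)
class ComparisonSpec:
    """A named two-group contrast defined by case-level predicates.

    Selectors take ``(case, cluster_label_or_None)`` and must be disjoint on
    any case table.
    """

    name: str
    label_a: str
    label_b: str
    selector_a: Selector
    selector_b: Selector
    needs_labels: bool = False


@dataclass(frozen=True)
class DEResult:
    """Per-feature outcome of one comparison."""

    feature_id: str
    direction: Literal["higher_in_a", "higher_in_b"]
    p_raw: float
    p_adjusted: float
    significant: bool
    n_a: int
    n_b: int


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], mode: Mode = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of a, p).

    Exact enumeration is used in auto mode when ``min(|a|, |b|) <= 8`` and
    the pooled values contain no ties; otherwise the normal approximation
    with average-rank tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 observations per group, got {len(a)} and {len(b)}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        method = "exact" if (min(len(a), len(b)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def rank_sum_table(
    values: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    alpha: float = 0.05,
    mode: Mode = "auto",
) -> list[DEResult]:
    """Feature-wise rank-sum tests between two sample groups + Bonferroni.

    Features with fewer than 2 present values in either group are dropped
    from the family (and logged); ``m`` is the number of features actually
    tested. Direction is assigned from the comparison of group mean ranks.
    """
    sub_a = values[list(samples_a)].to_numpy(dtype=float)
    sub_b = values[list(samples_b)].to_numpy(dtype=float)
    tested: list[tuple[str, float, str, int, int]] = []
    n_dropped = 0
    for idx, feature in enumerate(values.index):
        xa = sub_a[idx][np.isfinite(sub_a[idx])]
        xb = sub_b[idx][np.isfinite(sub_b[idx])]
        if len(xa) < 2 or len(xb) < 2:
            n_dropped += 1
            continue
        _, p = wilcoxon_rank_sum(xa, xb, mode=mode)
        ranks = stats.rankdata(np.concatenate([xa, xb]))
        direction = "higher_in_a" if ranks[: len(xa)].mean() > ranks[len(xa):].mean() else "higher_in_b"
        tested.append((feature, p, direction, len(xa), len(xb)))
    if n_dropped:
        logger.info("dropped %d feature(s) lacking >= 2 present values per group", n_dropped)
    m = len(tested)
    out = []
    for feature, p, direction, n_a, n_b in tested:
        p_adj = min(1.0, p * m)
        out.append(DEResult(feature, direction, p, p_adj, p_adj < alpha, n_a, n_b))
    return out


# ---------------------------------------------------------------------------
# the ten enumerated comparisons


def _spec(name, label_a, label_b, sel_a, sel_b, needs_labels=False) -> ComparisonSpec:
    return ComparisonSpec(name, label_a, label_b, sel_a, sel_b, needs_labels)


def _adult(c: CaseRecord) -> bool:
    return c.age_class == "adult"


ALL_COMPARISONS: list[ComparisonSpec] = [
    _spec(
        "adult_mutant_vs_pediatric", "adult mutant", "pediatric",
        lambda c, l: _adult(c) and c.is_mutant,
        lambda c, l: c.age_class == "pediatric",
    ),
    _spec(
        "adult_wt_vs_pediatric_wt", "adult WT", "pediatric WT",
        lambda c, l: _adult(c) and not c.is_mutant,
        lambda c, l: c.age_class == "pediatric" and not c.is_mutant,
    ),
    _spec(
        "adult_vs_pediatric", "adult", "pediatric",
        lambda c, l: _adult(c),
        lambda c, l: c.age_class == "pediatric",
    ),
    _spec(
        "adult_wt_vs_adult_mutant", "adult WT", "adult mutant",
        lambda c, l: _adult(c) and not c.is_mutant,
        lambda c, l: _adult(c) and c.is_mutant,
    ),
    _spec(
        "all_wt_vs_all_mutant", "all WT", "all mutant",
        lambda c, l: not c.is_mutant,
        lambda c, l: c.is_mutant,
    ),
    _spec(
        "b2a_vs_b2b", "cluster B2a", "cluster B2b",
        lambda c, l: l == "B2a",
        lambda c, l: l == "B2b",
        needs_labels=True,
    ),
    _spec(
        "sdhb_pos_vs_sdhb_neg", "SDHB positive", "SDHB negative",
        lambda c, l: c.sdhb_ihc == "positive",
        lambda c, l: c.sdhb_ihc == "negative",
    ),
    _spec(
        "fish_loss_vs_no_loss", "14q32 loss", "no 14q32 loss",
        lambda c, l: c.fish_14q == "loss",
        lambda c, l: c.fish_14q in ("diploid", "trisomy"),
    ),
    _spec(
        "adult_high_vs_low_risk", "adult high risk", "adult low risk",
        lambda c, l: _adult(c) and c.risk == "H",
        lambda c, l: _adult(c) and c.risk == "L",
    ),
    _spec(
        "adult_dod_awd_vs_wd", "adult DOD/AWD", "adult no evidence of disease",
        lambda c, l: _adult(c) and c.followup in ("DOD", "AWD"),
        lambda c, l: _adult(c) and c.followup == "WD",
    ),
]


def enumerate_comparisons(
    cases: Sequence[CaseRecord],
    labels: Mapping[str, str] | None = None,
) -> list[ComparisonSpec]:
    """The ten class comparisons that are possible on this case table.

    A comparison with an empty group (missing metadata, no pediatric cases,
    no cluster labels for the B2a/B2b contrast, ...) is skipped with a
    logged reason — skipping is not an error.
    """
    get_label = (labels or {}).get
    out = []
    for spec in ALL_COMPARISONS:
        if spec.needs_labels and labels is None:
            logger.info("skipping %s: no cluster labels provided", spec.name)
            continue
        n_a = sum(1 for c in cases if spec.selector_a(c, get_label(c.case_id)))
        n_b = sum(1 for c in cases if spec.selector_b(c, get_label(c.case_id)))
        if n_a == 0 or n_b == 0:
            logger.info("skipping %s: group sizes %d vs %d", spec.name, n_a, n_b)
            continue
        out.append(spec)
    return out


def compare_classes(
    expr: ExpressionMatrix,
    cases: Sequence[CaseRecord],
    spec: ComparisonSpec,
    alpha: float = 0.05,
    *,
    labels: Mapping[str, str] | None = None,
    mode: Mode = "auto",
) -> list[DEResult]:
    """Run one comparison on an expression matrix.

    Only samples present both in ``expr`` and the case table participate.
    Bonferroni family size is the number of features actually tested in this
    comparison.
    """
    get_label = (labels or {}).get
    by_id = {c.case_id: c for c in cases}
    in_expr = [s for s in expr.samples if s in by_id]
    group_a = [s for s in in_expr if spec.selector_a(by_id[s], get_label(s))]
    group_b = [s for s in in_expr if spec.selector_b(by_id[s], get_label(s))]
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"{spec.name}: selectors overlap on {sorted(overlap)[:5]}")
    if not group_a or not group_b:
        raise ValueError(
            f"{spec.name}: selector matched no samples "
            f"({spec.label_a}: {len(group_a)}, {spec.label_b}: {len(group_b)})"
        )
    return rank_sum_table(expr.values, group_a, group_b, alpha=alpha, mode=mode)


def results_to_frame(results: Sequence[DEResult], comparison: str) -> pd.DataFrame:
    """Tabulate DE results with a comparison-name column."""
    return pd.DataFrame(
        {
            "comparison": comparison,
            "feature_id": [r.feature_id for r in results],
            "direction": [r.direction for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
        }
    )
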