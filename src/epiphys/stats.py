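"""Normality-gated group comparisons with Bonferroni correction.

The gating rule is the one ubiquitous in slice-physiology papers: test
each sample for normality (Shapiro-Wilk, with Kolmogorov-Smirnov reported
alongside; Shapiro-Wilk governs when they disagree), then run Student's
two-tailed t-test when every sample passes and the Mann-Whitney U test
otherwise (paired variants: paired t / Wilcoxon signed-rank). Three or
more groups go through one-way ANOVA or Kruskal-Wallis, followed by
Bonferroni-adjusted pairwise tests (``adjusted_p = min(1, m * p)`` over
the m pairwise comparisons).

Every result records which test ran and why, so the decision path is
auditable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GateResult",
    "ComparisonResult",
    "MultiComparisonResult",
    "normality_gate",
    "compare_two",
    "compare_multi",
]

ALPHA_DEFAULT = 0.05


@dataclass
class GateResult:
    verdict: str  # "normal" | "non_normal"
    shapiro_p: float
    ks_p: float


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float
    group_means: tuple[float, ...]
    group_medians: tuple[float, ...]
    n_per_group: tuple[int, ...]
    normality_p: tuple[float, ...]
    decision_path: str

    @property
    def significant(self) -> bool:
        return self.adjusted_p < ALPHA_DEFAULT


@dataclass
class MultiComparisonResult:
    omnibus: ComparisonResult
    pairwise: list[tuple[tuple[int, int], ComparisonResult]] = field(
        default_factory=list
    )


def normality_gate(sample: Sequence[float], alpha: float = ALPHA_DEFAULT) -> GateResult:
    """Shapiro-Wilk gate (KS reported alongside; Shapiro-Wilk governs).

    A sample is "normal" iff the Shapiro-Wilk p-value is >= alpha.
    Degenerate (constant) samples are reported non-normal. Requires
    n >= 3.
    """
    x = np.asarray(list(sample), dtype=float)
    if len(x) < 3:
        raise ValueError(f"normality test needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        return GateResult("non_normal", float("nan"), float("nan"))
    sw_p = float(sps.shapiro(x).pvalue)
    z = (x - x.mean()) / x.std(ddof=1)
    ks_p = float(sps.kstest(z, "norm").pvalue)
    return GateResult("normal" if sw_p >= alpha else "non_normal", sw_p, ks_p)


def _summaries(samples) -> tuple[tuple, tuple, tuple]:
    means = tuple(float(np.mean(s)) for s in samples)
    medians = tuple(float(np.median(s)) for s in samples)
    ns = tuple(len(s) for s in samples)
    return means, medians, ns


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonResult:
    """Two-group comparison behind the normality gate.

    Both samples normal -> two-tailed Student's t (paired t when
    ``paired``); otherwise Mann-Whitney U (Wilcoxon signed-rank when
    paired). Paired samples with no non-zero differences short-circuit to
    a "no difference" result with p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    means, medians, ns = _summaries((a, b))
    gate_a, gate_b = normality_gate(a, alpha), normality_gate(b, alpha)
    norm_ps = (gate_a.shapiro_p, gate_b.shapiro_p)
    both_normal = gate_a.verdict == "normal" and gate_b.verdict == "normal"

    if paired and np.all(a == b):
        return ComparisonResult(
            "no_difference", 0.0, 1.0, 1.0, means, medians, ns, norm_ps,
            "paired samples identical: no non-zero differences",
        )

    if both_normal:
        if paired:
            res = sps.ttest_rel(a, b)
            name, path = "paired_t", "both samples normal (Shapiro-Wilk); paired t-test"
        else:
            res = sps.ttest_ind(a, b)
            name, path = "student_t", "both samples normal (Shapiro-Wilk); Student's t-test"
    else:
        if paired:
            res = sps.wilcoxon(a, b, zero_method="wilcox")
            name = "wilcoxon_signed_rank"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "mann_whitney_u"
        path = (
            f"non-normal sample (Shapiro-Wilk p = {min(norm_ps):.3g} < {alpha}); "
            f"{name.replace('_', ' ')}"
        )
    return ComparisonResult(
        name, float(res.statistic), float(res.pvalue), float(res.pvalue),
        means, medians, ns, norm_ps, path,
    )


def compare_multi(
    groups: Sequence[Sequence[float]], alpha: float = ALPHA_DEFAULT
) -> MultiComparisonResult:
    """Multi-group comparison: ANOVA or Kruskal-Wallis plus Bonferroni post hoc.

    All groups normal -> one-way ANOVA with pairwise t-tests; any
    non-normal group -> Kruskal-Wallis with pairwise Mann-Whitney tests.
    Pairwise p-values are Bonferroni-adjusted over the number of pairs.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("compare_multi needs at least three groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    means, medians, ns = _summaries(groups)
    gates = [normality_gate(g, alpha) for g in groups]
    norm_ps = tuple(g.shapiro_p for g in gates)
    all_normal = all(g.verdict == "normal" for g in gates)

    if all_normal:
        omni = sps.f_oneway(*groups)
        omni_name, path = "anova", "all groups normal; one-way ANOVA"
    else:
        omni = sps.kruskal(*groups)
        omni_name, path = "kruskal_wallis", "non-normal group present; Kruskal-Wallis"
    omnibus = ComparisonResult(
        omni_name, float(omni.statistic), float(omni.pvalue), float(omni.pvalue),
        means, medians, ns, norm_ps, path,
    )

    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    pairwise = []
    for (i, j) in pairs:
        if all_normal:
            res = sps.ttest_ind(groups[i], groups[j])
            name = "student_t"
        else:
            res = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            name = "mann_whitney_u"
        p = float(res.pvalue)
        pairwise.append((
            (i, j),
            ComparisonResult(
                name, float(res.statistic), p, min(1.0, m * p),
                (means[i], means[j]), (medians[i], medians[j]),
                (ns[i], ns[j]), (norm_ps[i], norm_ps[j]),
                f"{path}; Bonferroni over {m} pairs",
            ),
        ))
    return MultiComparisonResult(omnibus, pairwise)
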