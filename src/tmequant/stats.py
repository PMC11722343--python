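"""Paired and unpaired group comparisons used throughout the pipeline.

Matched compartments of the same patient (normal lung vs non-solid vs
solid) are compared with the Wilcoxon matched-pairs signed-rank test (exact
null distribution up to n = 25 after dropping zero differences, normal
approximation with continuity correction above). Unpaired comparisons run
through a variance-based gate: Levene's test at alpha = 0.05 routes the
comparison to the Mann-Whitney U test when significant and to Student's
t-test otherwise; both branch p-values are always retained in the result.
(Using Levene's statistic as the normality gate is a questionable but
deliberate convention here — see the methods note; a Shapiro-Wilk gate is
available behind a flag.) Three or more groups use the Kruskal-Wallis H
test with tie correction. Two-sided p < 0.05 is the significance
convention, annotated with the usual star ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def significance_stars(p: float) -> str:
    """Star annotation: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not np.isfinite(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    groups: tuple
    design: str  # 'paired' | 'unpaired' | 'multigroup'
    statistic: float
    p_value: float
    n: tuple
    gate: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def paired_signed_rank(x, y, groups=("x", "y")) -> ComparisonResult:
    """Wilcoxon matched-pairs signed-rank test on patient-matched vectors.

    Zero differences are dropped (classical convention). All-zero
    differences return p = 1 (no evidence of a shift). Requires >= 3
    non-zero differences. Exact two-sided p for n <= 25, normal
    approximation with continuity correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired design requires equal-length matched vectors")
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        return ComparisonResult(tuple(groups), "paired", 0.0, 1.0, (len(x), len(y)))
    if nz.size < 3:
        raise ValidationError(
            f"only {nz.size} non-zero difference(s); >= 3 required for the signed-rank test"
        )
    method = "exact" if nz.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return ComparisonResult(
        tuple(groups), "paired", float(res.statistic), float(res.pvalue),
        (len(x), len(y)), gate={"method": method, "n_nonzero": int(nz.size)},
    )


def gated_unpaired_compare(x, y, groups=("x", "y"), gate: str = "levene") -> ComparisonResult:
    """Two-sample comparison routed through a variance gate.

    ``gate='levene'`` (default): Levene p < 0.05 selects the Mann-Whitney U
    branch, otherwise Student's t-test (equal variances). ``gate='shapiro'``
    replaces the gate with a Shapiro-Wilk normality test on each sample
    (non-normality in either selects Mann-Whitney). Both branch p-values
    are always computed and stored under ``gate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if gate not in ("levene", "shapiro"):
        raise ValueError(f"unknown gate {gate!r}")
    degenerate = np.ptp(np.concatenate([x, y])) == 0
    if degenerate:
        # constant data: no variance information, parametric branch by default
        gate_stat, gate_p = 0.0, 1.0
        nonparametric = False
    elif gate == "levene":
        gate_stat, gate_p = scipy.stats.levene(x, y)
        nonparametric = gate_p < 0.05
    elif gate == "shapiro":
        p1 = scipy.stats.shapiro(x).pvalue
        p2 = scipy.stats.shapiro(y).pvalue
        gate_stat, gate_p = float("nan"), min(p1, p2)
        nonparametric = gate_p < 0.05
    if degenerate or np.array_equal(x, y):
        # identical constant samples: no evidence either way
        t_res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
        mw_res = type("R", (), {"statistic": len(x) * len(y) / 2.0, "pvalue": 1.0})
    else:
        t_res = scipy.stats.ttest_ind(x, y, equal_var=True)
        mw_res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    branch = "mannwhitney" if nonparametric else "ttest"
    chosen = mw_res if nonparametric else t_res
    return ComparisonResult(
        tuple(groups), "unpaired", float(chosen.statistic), float(chosen.pvalue),
        (len(x), len(y)),
        gate={
            "gate": gate, "gate_statistic": float(gate_stat), "gate_p": float(gate_p),
            "branch": branch, "ttest_p": float(t_res.pvalue),
            "mannwhitney_p": float(mw_res.pvalue),
        },
    )


def multigroup_compare(*samples, groups=None) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square approximation)."""
    if len(samples) < 2:
        raise ValidationError("multigroup comparison needs >= 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            tuple(groups or range(len(arrays))), "multigroup", 0.0, 1.0,
            tuple(len(a) for a in arrays),
        )
    h, p = scipy.stats.kruskal(*arrays)
    return ComparisonResult(
        tuple(groups or range(len(arrays))), "multigroup", float(h), float(p),
        tuple(len(a) for a in arrays),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in the pipeline:
    per-comparison p-values are reported unadjusted unless requested)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
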