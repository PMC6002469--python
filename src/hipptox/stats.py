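"""Significance statistics for treatment effects.

Changes are assessed on the log2 scale: the log2-ratio of treated to
control means equals the difference of log2-transformed group means, so
a two-sample t-test on log2-transformed values tests the null Δ = 0 and
yields the effect's 95% confidence interval. Families of p-values are
corrected with the Benjamini–Hochberg step-up procedure. A small helper
aggregates comet-assay replicate medians (mean of per-replicate median
% tail DNA) with per-condition tests against the matched control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectTest",
    "CometSummary",
    "log2_ratio_ttest",
    "bh_adjust",
    "summarize_comet",
]


@dataclass
class EffectTest:
    condition_id: str
    mean_log2_ratio: float
    ci95: tuple[float, float]
    p: float
    p_adjusted: float = float("nan")


@dataclass
class CometSummary:
    condition_id: str
    replicate_medians: list[float]
    mean_of_medians: float
    excluded_replicates: list[tuple[int, str]] = field(default_factory=list)
    effect: EffectTest | None = None
    significance: str = ""  # "***" adj p<=0.01, "**" <=0.05, "*" <=0.10


def log2_ratio_ttest(
    treated, control, condition_id: str = "", welch: bool = False
) -> EffectTest:
    """Two-sided two-sample t-test on log2-transformed values.

    The effect is the difference of log2 group means (a log2 fold
    change); the 95% CI comes from the t distribution. Pooled-variance by
    default; ``welch=True`` drops the equal-variance assumption.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.any(treated <= 0) or np.any(control <= 0):
        raise ValueError("all values must be positive before the log2 transform")
    lt, lc = np.log2(treated), np.log2(control)
    res = sps.ttest_ind(lt, lc, equal_var=not welch)
    effect = float(lt.mean() - lc.mean())
    ci = res.confidence_interval(0.95)
    return EffectTest(
        condition_id=condition_id,
        mean_log2_ratio=effect,
        ci95=(float(ci.low), float(ci.high)),
        p=float(res.pvalue),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    The family is exactly the p-values passed in one call.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stars(p_adj: float) -> str:
    if p_adj <= 0.01:
        return "***"
    if p_adj <= 0.05:
        return "**"
    if p_adj <= 0.10:
        return "*"
    return ""


def summarize_comet(
    replicate_medians: dict[str, list[float] | np.ndarray],
    control_condition: str,
    exclusions: list[tuple[str, int, str]] | None = None,
    welch: bool = False,
) -> dict[str, CometSummary]:
    """Aggregate comet-assay replicate medians and test against control.

    ``replicate_medians`` maps condition id to per-replicate median
    % tail DNA. ``exclusions`` lists (condition, replicate index, reason)
    to drop — outlier removal is an explicit input, never automatic. Each
    treated condition is compared to ``control_condition`` with a
    log2-ratio t-test; BH adjustment runs across all treated conditions
    in the call. Significance tiers: *** adj p ≤ 0.01, ** ≤ 0.05,
    * ≤ 0.10.
    """
    exclusions = exclusions or []
    excl_by_cond: dict[str, list[tuple[int, str]]] = {}
    for cond, idx, reason in exclusions:
        excl_by_cond.setdefault(cond, []).append((idx, reason))

    summaries: dict[str, CometSummary] = {}
    kept: dict[str, np.ndarray] = {}
    for cond, meds in replicate_medians.items():
        meds = np.asarray(meds, dtype=float)
        if np.any((meds < 0) | (meds > 100)):
            raise ValueError(f"{cond}: replicate medians must lie in [0, 100]")
        drop = {i for i, _ in excl_by_cond.get(cond, [])}
        keep = np.array([i not in drop for i in range(len(meds))])
        if keep.sum() < 3:
            raise ValueError(f"{cond}: fewer than 3 replicates after exclusion")
        kept[cond] = meds[keep]
        summaries[cond] = CometSummary(
            condition_id=cond,
            replicate_medians=[float(v) for v in meds[keep]],
            mean_of_medians=float(np.mean(meds[keep])),
            excluded_replicates=excl_by_cond.get(cond, []),
        )
    if control_condition not in kept:
        raise ValueError(f"control condition {control_condition!r} absent")
    treated_conditions = [c for c in replicate_medians if c != control_condition]
    tests = []
    for cond in treated_conditions:
        # % tail DNA at or near 0 is below the assay's quantitation floor;
        # floor at 0.1% before the log transform
        t = np.maximum(kept[cond], 0.1)
        c = np.maximum(kept[control_condition], 0.1)
        tests.append(log2_ratio_ttest(t, c, condition_id=cond, welch=welch))
    adj = bh_adjust([t.p for t in tests]) if tests else np.array([])
    for test, pa in zip(tests, adj):
        test.p_adjusted = float(pa)
        summaries[test.condition_id].effect = test
        summaries[test.condition_id].significance = _stars(float(pa))
    return summaries
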