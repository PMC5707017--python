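"""Group summaries and hypothesis tests for per-cell Ca2+ metrics.

Pooled data are summarised as mean +/- SE; two conditions are compared with
the unpaired pooled-variance Student's t test, and multi-group expression
data (qRT-PCR delta-Ct) with one-way ANOVA followed by the Newman-Keuls
(student-Newman-Keuls, SNK) stepwise studentized-range post-hoc procedure.
Responder fractions are compared at the recording level: each microscopic
field / donor contributes one percentage, and conditions are compared by an
unpaired t on those percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "CtRecord",
    "summarize",
    "student_t_unpaired",
    "one_way_anova",
    "newman_keuls",
    "responder_fraction",
    "delta_ct",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SE of one group; SE uses the n-1 sample SD (0 when n = 1)."""

    label: str
    n: int
    mean: float
    se: float


@dataclass
class GroupComparison:
    """Result of a between-group test."""

    summaries: list[GroupSummary]
    statistic: float | None      # t or F
    df: float | tuple[float, float] | None
    p_value: float | None
    method: str
    pairwise: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CtRecord:
    """qRT-PCR threshold cycles normalised to the housekeeping gene.

    delta_ct = gene_ct - reference_ct; a high delta-Ct means the transcript
    needed more amplification cycles than the reference, i.e. LOW expression.
    """

    gene_ct: float
    actin_ct: float
    delta_ct: float

    interpretation = "high delta_ct = low expression"


def summarize(values: Sequence[float], label: str = "group") -> GroupSummary:
    """Mean +/- SE of a sample. Errors on empty input; SE = 0 for n = 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"group {label!r}: cannot summarise an empty sample")
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()), se=se)


def student_t_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Pooled-variance two-sample Student's t test, two-tailed.

    df = n_a + n_b - 2. Degenerate samples with zero pooled variance give
    t = 0, p = 1 when the means agree and an infinite-t guard (p = 0,
    flagged in ``notes``) when they do not.
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("Student's t needs at least 2 observations per group")
    df = xa.size + xb.size - 2
    sp2 = ((xa.size - 1) * xa.var(ddof=1) + (xb.size - 1) * xb.var(ddof=1)) / df
    diff = xa.mean() - xb.mean()
    notes: list[str] = []
    if sp2 == 0.0:
        if diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t = float(np.inf) if diff > 0 else float(-np.inf)
            p = 0.0
            notes.append("zero pooled variance with unequal means; |t| unbounded")
    else:
        t = float(diff / np.sqrt(sp2 * (1.0 / xa.size + 1.0 / xb.size)))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(
        summaries=[summarize(xa, labels[0]), summarize(xb, labels[1])],
        statistic=t, df=float(df), p_value=p,
        method="Student's t (unpaired, pooled variance, two-tailed)",
        notes=notes,
    )


def _anova_pieces(groups: list[np.ndarray]):
    k = len(groups)
    ns = np.array([g.size for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, int(ns.sum()) - k
    return ssb, ssw, df_b, df_w


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> GroupComparison:
    """One-way fixed-effects ANOVA: F = MSB/MSW with df (k-1, N-k)."""
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    labels = [f"g{i}" for i in range(len(gs))] if labels is None else list(labels)
    ssb, ssw, df_b, df_w = _anova_pieces(gs)
    notes: list[str] = []
    if ssw == 0.0:
        if ssb == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = float(np.inf), 0.0
            notes.append("zero within-group variance with unequal means; F unbounded")
    else:
        F = float((ssb / df_b) / (ssw / df_w))
        p = float(sps.f.sf(F, df_b, df_w))
    return GroupComparison(
        summaries=[summarize(g, lbl) for g, lbl in zip(gs, labels)],
        statistic=F, df=(float(df_b), float(df_w)), p_value=p,
        method="one-way ANOVA", notes=notes,
    )


def newman_keuls(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Student-Newman-Keuls stepwise studentized-range post-hoc test.

    Group means are ranked (ties broken by input order) and each pair is
    compared with q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))
    against the studentized-range critical value for the pair's span p (the
    number of ordered means it encloses) at level ``alpha``. The stepwise
    stopping rule is honoured: a non-significant span blocks every pair
    nested inside it, regardless of its own q.

    Returns a table with one row per pair: labels, mean difference, span,
    q, critical q, p-value, and the final significance flag.
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("Newman-Keuls needs >= 2 groups with >= 2 observations each")
    labels = [f"g{i}" for i in range(len(gs))] if labels is None else list(labels)
    _, ssw, _, df_w = _anova_pieces(gs)
    msw = ssw / df_w

    order = sorted(range(len(gs)), key=lambda i: (gs[i].mean(), i))  # stable in input order
    means = [gs[i].mean() for i in order]
    ns = [gs[i].size for i in order]
    k = len(order)

    rows = {}
    significant = {}
    # largest spans first so the stopping rule can block nested pairs
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            blocked = any(
                (LO <= lo and hi <= HI) and not significant[(LO, HI)]
                for (LO, HI) in significant
            )
            diff = means[hi] - means[lo]
            if msw > 0:
                q = diff / np.sqrt(msw / 2.0 * (1.0 / ns[lo] + 1.0 / ns[hi]))
                q_crit = float(sps.studentized_range.ppf(1 - alpha, span, df_w))
                p = float(sps.studentized_range.sf(q, span, df_w))
            else:
                q = float(np.inf) if diff > 0 else 0.0
                q_crit, p = float("nan"), (0.0 if diff > 0 else 1.0)
            sig = (not blocked) and (q > q_crit if np.isfinite(q_crit) else diff > 0)
            significant[(lo, hi)] = sig
            rows[(lo, hi)] = {
                "group_a": labels[order[lo]],
                "group_b": labels[order[hi]],
                "diff": float(diff),
                "span": span,
                "q": float(q),
                "q_crit": q_crit,
                "p_value": p,
                "significant": bool(sig),
                "blocked": bool(blocked),
            }
    table = pd.DataFrame([rows[key] for key in sorted(rows)])
    return table.reset_index(drop=True)


def responder_fraction(
    recordings_by_condition: Mapping[str, Sequence[Sequence[bool]]],
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare responder percentages between conditions at recording level.

    Each condition maps to its recordings (microscopic fields / donors), each
    recording being the per-cell responder flags. A recording's responder
    percentage is 100 * mean(flags); empty recordings are excluded with a
    warning. Conditions are summarised as mean +/- SE over recordings and,
    with exactly two conditions each having >= 2 recordings, compared by an
    unpaired Student's t on the per-recording percentages. The total cell
    count per condition is appended to ``notes``.
    """
    pct: dict[str, list[float]] = {}
    cells: dict[str, int] = {}
    for cond, recs in recordings_by_condition.items():
        pct[cond], cells[cond] = [], 0
        for i, rec in enumerate(recs):
            flags = np.asarray(list(rec), dtype=bool)
            if flags.size == 0:
                warnings.warn(f"condition {cond!r}: recording {i} has 0 cells; excluded",
                              stacklevel=2)
                continue
            pct[cond].append(100.0 * float(flags.mean()))
            cells[cond] += int(flags.size)
    summaries = [summarize(v, lbl) for lbl, v in pct.items() if v]
    notes = [f"{lbl}: n={cells[lbl]} cells in {len(pct[lbl])} recordings" for lbl in pct]

    conds = [lbl for lbl, v in pct.items() if v]
    if len(conds) == 2 and all(len(pct[c]) >= 2 for c in conds):
        cmp_ = student_t_unpaired(pct[conds[0]], pct[conds[1]], labels=tuple(conds))
        return GroupComparison(summaries=summaries, statistic=cmp_.statistic,
                               df=cmp_.df, p_value=cmp_.p_value,
                               method="responder fraction, recording-level t",
                               notes=notes + cmp_.notes)
    if len(conds) > 2 and all(len(pct[c]) >= 2 for c in conds):
        cmp_ = one_way_anova([pct[c] for c in conds], labels=conds)
        return GroupComparison(summaries=summaries, statistic=cmp_.statistic,
                               df=cmp_.df, p_value=cmp_.p_value,
                               method="responder fraction, recording-level ANOVA",
                               notes=notes + cmp_.notes)
    warnings.warn("responder_fraction: a condition has < 2 recordings; "
                  "test skipped, summaries only", stacklevel=2)
    return GroupComparison(summaries=summaries, statistic=None, df=None,
                           p_value=None, method="responder fraction (no test)",
                           notes=notes)


def delta_ct(gene_ct: float, actin_ct: float) -> CtRecord:
    """qRT-PCR delta-Ct = Ct[gene] - Ct[reference] (high value = low expression)."""
    if not (np.isfinite(gene_ct) and np.isfinite(actin_ct)):
        raise ValueError("delta_ct requires finite cycle values")
    return CtRecord(gene_ct=float(gene_ct), actin_ct=float(actin_ct),
                    delta_ct=float(gene_ct) - float(actin_ct))
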