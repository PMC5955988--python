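"""Repeated-measures statistics for tidy endpoint tables.

Implements the analysis chain used for within-subject ocular studies: a
fully within-subject repeated-measures ANOVA (up to three crossed factors,
subject as the blocking stratum, each effect tested against its
subject-by-effect interaction), Greenhouse-Geisser sphericity correction
applied when epsilon < 0.75, Bonferroni-corrected paired post hocs, and
mean ± SD / SE cell summaries.

The ANOVA is computed by direct sums-of-squares partition on the balanced
cell-mean array rather than through a general model fitter, so every number
it produces can be checked against explicit-loop arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "AnovaEffect",
    "gg_epsilon",
    "rm_anova",
    "rm_anova_array",
    "bonferroni_adjust",
    "pairwise_posthoc",
    "group_summary",
]

GG_THRESHOLD_DEFAULT = 0.75


@dataclass(frozen=True)
class AnovaEffect:
    """One within-subject effect from the repeated-measures ANOVA."""

    effect: str
    ss: float
    ss_error: float
    df: int
    df_error: int
    f_value: float
    epsilon: float
    df_corrected: float
    df_error_corrected: float
    p_uncorrected: float
    p_value: float
    gg_applied: bool


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x levels data matrix.

    Computed from the double-centered sample covariance of the k repeated
    levels: epsilon = tr(D)^2 / ((k-1) tr(D^2)), clamped to the theoretical
    range [1/(k-1), 1].  Equals 1 exactly under compound symmetry.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D subjects x levels matrix")
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if n < 2:
        raise ValueError("need at least 2 subjects to estimate a covariance")
    cov = np.cov(data, rowvar=False)
    return _epsilon_from_cov(cov, helmert(k, full=False))


def _epsilon_from_cov(cov: np.ndarray, contrasts: np.ndarray) -> float:
    d = contrasts @ cov @ contrasts.T
    df = d.shape[0]
    denom = df * float(np.sum(d * d))
    if denom <= 0:
        raise ValueError("degenerate covariance (no within-subject variance)")
    eps = float(np.trace(d)) ** 2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def _subsets(items):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def rm_anova_array(
    y: np.ndarray,
    factor_names: tuple[str, ...] | None = None,
    gg_rule: str = "threshold",
    gg_threshold: float = GG_THRESHOLD_DEFAULT,
) -> list[AnovaEffect]:
    """Within-subject ANOVA on a balanced (subjects, k1[, k2[, k3]]) array.

    Sums of squares come from inclusion-exclusion over marginal means of the
    complete array; each within effect is tested against its interaction
    with subjects.  ``gg_rule`` is "threshold" (correct when epsilon <
    ``gg_threshold``, the conventional rule), "always" or "never".
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 2 or y.ndim > 4:
        raise ValueError("expected subjects x (1..3 within factors)")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the design")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if gg_rule not in ("threshold", "always", "never"):
        raise ValueError("gg_rule must be 'threshold', 'always' or 'never'")
    m = y.ndim - 1
    if factor_names is None:
        factor_names = tuple(f"F{i + 1}" for i in range(m))
    if len(factor_names) != m:
        raise ValueError("factor_names length mismatch")

    axes = tuple(range(y.ndim))  # 0 = subject
    # marginal means, keepdims so they broadcast against the full array
    marg = {
        kept: y.mean(axis=tuple(a for a in axes if a not in kept), keepdims=True)
        for kept in _subsets(axes)
    }

    def ss_term(term: tuple[int, ...]) -> float:
        adj = np.zeros(y.shape)
        for sub in _subsets(term):
            adj = adj + (-1) ** (len(term) - len(sub)) * marg[tuple(sub)]
        return float(np.sum(adj**2))

    results: list[AnovaEffect] = []
    n = y.shape[0]
    for r in range(1, m + 1):
        for eff in combinations(range(1, m + 1), r):
            ss_e = ss_term(eff)
            ss_err = ss_term((0,) + eff)
            df_e = int(np.prod([y.shape[a] - 1 for a in eff]))
            df_err = (n - 1) * df_e
            if ss_err <= 1e-12 * max(1.0, float(np.sum(y**2))):
                raise ValueError(
                    f"degenerate design: zero residual variance for effect "
                    f"{'*'.join(factor_names[a - 1] for a in eff)}"
                )
            f_val = (ss_e / df_e) / (ss_err / df_err)

            # epsilon from the effect's contrast covariance, collapsing the
            # factors not involved in the effect
            collapse = tuple(a for a in range(1, m + 1) if a not in eff)
            y_c = y.mean(axis=collapse) if collapse else y
            y_flat = y_c.reshape(n, -1)
            contr = helmert(y_c.shape[1], full=False)
            for a in range(2, y_c.ndim):
                contr = np.kron(contr, helmert(y_c.shape[a], full=False))
            eps = _epsilon_from_cov(np.cov(y_flat, rowvar=False), contr)

            apply_gg = gg_rule == "always" or (gg_rule == "threshold" and eps < gg_threshold)
            df1c = df_e * eps if apply_gg else float(df_e)
            df2c = df_err * eps if apply_gg else float(df_err)
            p_unc = float(f_dist.sf(f_val, df_e, df_err))
            p = float(f_dist.sf(f_val, df1c, df2c))
            results.append(
                AnovaEffect(
                    effect="*".join(factor_names[a - 1] for a in eff),
                    ss=ss_e,
                    ss_error=ss_err,
                    df=df_e,
                    df_error=df_err,
                    f_value=f_val,
                    epsilon=eps,
                    df_corrected=df1c,
                    df_error_corrected=df2c,
                    p_uncorrected=p_unc,
                    p_value=p,
                    gg_applied=bool(apply_gg),
                )
            )
    return results


def _pivot_balanced(
    table: pd.DataFrame, dv: str, within: list[str], subject: str
) -> tuple[np.ndarray, list[list]]:
    levels = [sorted(table[f].unique().tolist()) for f in within]
    subjects = sorted(table[subject].unique().tolist())
    shape = (len(subjects), *[len(lv) for lv in levels])
    counts = table.groupby([subject] + within, observed=True)[dv].count()
    expected = pd.MultiIndex.from_product([subjects] + levels, names=[subject] + within)
    missing = expected.difference(counts.index)
    if len(missing) > 0:
        cells = ", ".join(map(str, missing[:10].tolist()))
        raise ValueError(f"incomplete within-subject design; missing cells: {cells}")
    mean_cells = table.groupby([subject] + within, observed=True)[dv].mean()
    y = mean_cells.reindex(expected).to_numpy().reshape(shape)
    return y, levels


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
    gg_rule: str = "threshold",
    gg_threshold: float = GG_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Repeated-measures ANOVA on a tidy long-format table.

    ``within`` names up to three within-subject factor columns; every
    subject must contribute every factor-level combination (replicates
    within a cell are averaged first).  Returns one row per main effect and
    interaction.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("supports 1 to 3 within-subject factors")
    y, _ = _pivot_balanced(table, dv, within, subject)
    effects = rm_anova_array(
        y, tuple(within), gg_rule=gg_rule, gg_threshold=gg_threshold
    )
    return pd.DataFrame([e.__dict__ for e in effects])


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: multiply by the family size, cap at 1.0."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(p * m, 1.0)


def pairwise_posthoc(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "subject",
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests between levels of one factor.

    Values are first averaged within subject x level (collapsing any other
    factors), and every level pair is compared with a paired t-test; the
    family is the set of pairs of this factor.
    """
    cell = table.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    if cell.isna().any().any():
        raise ValueError("incomplete design: some subject/level cells are empty")
    levels = list(cell.columns)
    rows = []
    pairs = list(combinations(levels, 2))
    for a, b in pairs:
        d = cell[a].to_numpy() - cell[b].to_numpy()
        n = len(d)
        if n < 2:
            raise ValueError("need >= 2 subjects for a paired comparison")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate comparison {a} vs {b}: zero variance")
        t_val = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * float(t_dist.sf(abs(t_val), n - 1))
        rows.append({"level_a": a, "level_b": b, "mean_diff": d.mean(), "t": t_val, "df": n - 1, "p_uncorrected": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p_uncorrected"].to_numpy(), len(pairs))
    return out


def group_summary(
    table: pd.DataFrame, by: list[str], dv: str = "value"
) -> pd.DataFrame:
    """Per-cell mean, sample SD (n-1), SE and n for a tidy table.

    Cells with a single observation keep their mean but carry NaN SD/SE and
    are flagged rather than silently dropped.
    """
    g = table.groupby(by, observed=True)[dv]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["flag"] = np.where(out["n"] < 2, "sd undefined (n=1)", "")
    return out
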