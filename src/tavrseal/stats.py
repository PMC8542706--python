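"""Cohort statistics for the sealing comparison.

Two-sample comparisons between bicuspid (BAV, pooling Sievers type 0 and
type 1) and tricuspid (TAV) groups: pooled two-sample t-test (computable
directly from printed summary statistics), exact Mann-Whitney U for small
samples, Fisher's exact test for 2x2 tables (two-sided by the
probability-ordering convention), plus a univariate screen at p < 0.1
feeding a forward/backward stepwise linear regression, and group summary
tables with a normality-gated test selection.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    name: str
    statistic: float
    p_value: float
    summary: dict = field(default_factory=dict)
    reason: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> StatResult:
    """Pooled two-sample t-test from group summary statistics.

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = (mean1-mean2) / (sp sqrt(1/n1 + 1/n2)); two-sided p on n1+n2-2 df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if mean1 == mean2 else np.inf * np.sign(mean1 - mean2)
        p = 1.0 if mean1 == mean2 else 0.0
    else:
        t = (mean1 - mean2) / se
        p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(
        "pooled_t",
        float(t),
        float(min(p, 1.0)),
        summary={"mean1": mean1, "sd1": sd1, "n1": n1,
                 "mean2": mean2, "sd2": sd2, "n2": n2, "df": df},
    )


def pooled_t(x, y) -> StatResult:
    """Pooled two-sample t-test from raw samples (summary-form consistency)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return pooled_t_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def mann_whitney(x, y, exact_limit: int = 20) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of the U distribution when the combined
    sample size is at most ``exact_limit`` and there are no ties; otherwise
    a tie-corrected normal approximation with continuity correction.  The
    path taken is recorded in ``reason``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_limit and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        reason = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        reason = "normal_approximation_tie_corrected" if ties else "normal_approximation"
    return StatResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      reason=reason)


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    p is the sum of hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed that of the observed
    table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0 or t.sum() == 0:
        return StatResult("fisher_exact", np.nan, 1.0, reason="degenerate margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher_exact", float(odds), float(p))


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between paired lists."""
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if len(o) != len(p):
        raise ValueError("paired lists must have equal length")
    if len(o) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(o) == 0 or np.std(p) == 0:
        raise ValueError("zero variance in one of the lists")
    return float(sps.pearsonr(o, p).statistic ** 2)


def univariate_screen(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    alpha_in: float = 0.1,
) -> tuple[list[str], dict[str, float], dict[str, str]]:
    """Simple-regression screen: retain candidates with slope p < alpha_in.

    Returns (retained candidates, per-candidate p, exclusion reasons).
    """
    y = table[outcome].to_numpy(float)
    retained: list[str] = []
    pvals: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for cand in candidates:
        x = table[cand].to_numpy(float)
        if np.std(x) == 0:
            reasons[cand] = "constant candidate"
            continue
        res = sps.linregress(x, y)
        pvals[cand] = float(res.pvalue)
        if res.pvalue < alpha_in:
            retained.append(cand)
    return retained, pvals, reasons


@dataclass
class StepwiseModel:
    terms: list[str]
    coefficients: dict[str, float]  # original scale, includes 'intercept'
    p_values: dict[str, float]


def _ols_term_pvalues(y: np.ndarray, X: pd.DataFrame) -> dict[str, float]:
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return {c: float(model.pvalues[c]) for c in X.columns}


def stepwise_lm(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_steps: int = 50,
) -> StepwiseModel:
    """Forward-selection / backward-elimination linear regression.

    Candidates are standardized internally (the procedure is therefore
    invariant to their scaling); the returned coefficients are refit on the
    original scale.  Deterministic given column order: entry ties are broken
    by smallest p then candidate order; near-perfectly collinear candidates
    are skipped (later-ordered column dropped) with a recorded reason.
    """
    import statsmodels.api as sm

    if not candidates:
        raise ValueError("need at least one candidate")
    y = table[outcome].to_numpy(float)
    Z = pd.DataFrame(index=table.index)
    usable: list[str] = []
    for cand in candidates:
        x = table[cand].to_numpy(float)
        if np.std(x) == 0:
            continue
        Z[cand] = (x - x.mean()) / x.std()
        usable.append(cand)

    selected: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward step
        best_p, best_c = None, None
        for cand in usable:
            if cand in selected:
                continue
            if selected:
                r2 = sm.OLS(
                    Z[cand].to_numpy(),
                    sm.add_constant(Z[selected], has_constant="add"),
                ).fit().rsquared
                if r2 > 0.999:  # collinear with current terms
                    continue
            pv = _ols_term_pvalues(y, Z[selected + [cand]])[cand]
            if pv < alpha_enter and (best_p is None or pv < best_p):
                best_p, best_c = pv, cand
        if best_c is not None:
            selected.append(best_c)
            changed = True
        # backward step
        if selected:
            pvs = _ols_term_pvalues(y, Z[selected])
            worst = max(selected, key=lambda c: pvs[c])
            if pvs[worst] > alpha_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    if not selected:
        return StepwiseModel([], {"intercept": float(np.mean(y))}, {})
    X = sm.add_constant(table[selected].astype(float), has_constant="add")
    fit = sm.OLS(y, X).fit()
    coefs = {"intercept": float(fit.params["const"])}
    pvals = {}
    for c in selected:
        coefs[c] = float(fit.params[c])
        pvals[c] = float(fit.pvalues[c])
    return StepwiseModel(selected, coefs, pvals)


# ---------------------------------------------------------------------------
# group summary tables
# ---------------------------------------------------------------------------


def _select_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> str:
    """Normality gate: pooled t if both groups pass Shapiro-Wilk, else MWU."""
    if len(x) < 3 or len(y) < 3:
        return "mann_whitney"
    if np.std(x) == 0 or np.std(y) == 0:
        return "mann_whitney"
    px = sps.shapiro(x).pvalue
    py = sps.shapiro(y).pvalue
    return "t" if (px > alpha and py > alpha) else "mann_whitney"


def group_summary(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group_col: str = "morphology",
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Sealing-table-shaped report: BAV0 / BAV1 / pooled BAV / TAV columns
    with mean +/- SD per group and a BAV-vs-TAV p-value per row.

    Continuous rows use the pooled t-test when both groups pass a
    Shapiro-Wilk normality check at alpha = 0.05 and the Mann-Whitney U test
    otherwise (flagged in the ``test`` column); categorical rows use
    Fisher's exact test on the 2x2 morphology-by-level table.
    """
    morph = table[group_col]
    groups = {
        "BAV0": table[morph == "BAV0"],
        "BAV1": table[morph == "BAV1"],
        "BAV": table[morph.isin(["BAV0", "BAV1"])],
        "TAV": table[morph == "TAV"],
    }
    categorical = categorical or []
    if variables is None:
        variables = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for var in variables:
        row: dict[str, object] = {"variable": var}
        for gname, g in groups.items():
            if var in categorical:
                n_pos = int((g[var] != 0).sum())
                row[f"{gname}"] = (
                    f"{n_pos} ({100.0 * n_pos / len(g):.1f})" if len(g) else "NA"
                )
            else:
                row[f"{gname}"] = (
                    f"{g[var].mean():.1f} ± {g[var].std(ddof=1):.1f}"
                    if len(g) >= 2 else "NA"
                )
        bav = groups["BAV"][var].dropna().to_numpy(float)
        tav = groups["TAV"][var].dropna().to_numpy(float)
        if var in categorical:
            if len(bav) == 0 or len(tav) == 0:
                row["p_value"], row["test"] = np.nan, "not_computable"
            else:
                tab = [
                    [int((bav != 0).sum()), int((bav == 0).sum())],
                    [int((tav != 0).sum()), int((tav == 0).sum())],
                ]
                res = fisher_exact_2x2(tab)
                row["p_value"], row["test"] = res.p_value, "fisher_exact"
        elif len(bav) < 2 or len(tav) < 2:
            row["p_value"], row["test"] = np.nan, "not_computable"
        else:
            which = _select_test(bav, tav)
            if which == "t":
                res = pooled_t(bav, tav)
                row["p_value"], row["test"] = res.p_value, "pooled_t"
            else:
                res = mann_whitney(bav, tav)
                row["p_value"], row["test"] = res.p_value, "mann_whitney*"
        rows.append(row)
    return pd.DataFrame(rows)
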