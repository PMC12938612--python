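"""Cohort statistics: adjusted group comparison, normality-gated
correlation with Benjamini-Hochberg FDR, and the t-test sensitivity
(minimum-detectable-effect) computation.

The group comparison is an ANCOVA: a linear model of the outcome on a
group indicator plus age, sex and BMI, reading off the two-sided p-value
of the group coefficient. With covariate adjustment disabled it reduces
exactly to the pooled-variance unpaired t-test. Correlations choose
Pearson or Spearman per pair by a Shapiro-Wilk gate (both marginals
normal at alpha -> Pearson, otherwise Spearman) and are corrected as one
family by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthetic import (BSDM_REGIONS, CARTILAGE_COLUMNS, FUNCTIONAL_COLUMNS)

DEFAULT_COVARIATES = ("age", "sex", "bmi")


@dataclass(frozen=True)
class StatResult:
    """One test outcome: a contrast or a correlation pair."""

    name: str
    method: str  # 'adjusted-t' | 't' | 'pearson' | 'spearman'
    statistic: float
    p: float
    n: int
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def adjusted_group_compare(table: pd.DataFrame, outcome: str,
                           covariates: Sequence[str] | None = DEFAULT_COVARIATES,
                           group_col: str = "group") -> StatResult:
    """Linear-model group comparison of ``outcome``, adjusted for covariates.

    Fits outcome ~ group + covariates by OLS and reports the two-sided p of
    the group coefficient. With ``covariates=None`` this is algebraically
    identical to the pooled-variance unpaired t-test.
    """
    covariates = tuple(covariates) if covariates else ()
    cols = [outcome, group_col, *covariates]
    data = table[cols].dropna()
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if min((data[group_col] == g).sum() for g in groups) < 3:
        raise ValueError("each group needs at least 3 subjects")
    indicator = (data[group_col] == groups[1]).astype(float)
    design = pd.DataFrame({"group": indicator})
    for cov in covariates:
        col = data[cov].astype(float)
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant; design is singular")
        design[cov] = col
    x = sm.add_constant(design, has_constant="add")
    fit = sm.OLS(data[outcome].astype(float), x).fit()
    return StatResult(
        name=f"{outcome}: {groups[0]} vs {groups[1]}",
        method="adjusted-t" if covariates else "t",
        statistic=float(fit.tvalues["group"]),
        p=float(fit.pvalues["group"]),
        n=len(data),
    )


# ---------------------------------------------------------------------------
# correlation with normality gate
# ---------------------------------------------------------------------------


def shapiro_gate(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> str:
    """Choose 'pearson' if both samples pass Shapiro-Wilk, else 'spearman'.

    Constant samples (Shapiro-Wilk undefined) fall back to Spearman with a
    warning — the conservative choice when normality cannot be assessed.
    """
    for sample in (np.asarray(x, float), np.asarray(y, float)):
        if sample.size < 4:
            raise ValueError("Shapiro-Wilk needs n >= 4")
        if np.ptp(sample) == 0:
            warnings.warn("constant sample: Shapiro-Wilk undefined, "
                          "using Spearman", stacklevel=2)
            return "spearman"
        if sps.shapiro(sample).pvalue <= alpha:
            return "spearman"
    return "pearson"


def correlate(table: pd.DataFrame, pairs: Sequence[tuple[str, str]],
              alpha: float = 0.05, fdr: bool = True) -> list[StatResult]:
    """Gated correlations over the listed column pairs, BH-corrected as
    one family."""
    results: list[StatResult] = []
    for a, b in pairs:
        data = table[[a, b]].dropna()
        name = f"{a} vs {b}"
        if len(data) < 4:
            results.append(StatResult(name, "missing", np.nan, np.nan,
                                      len(data)))
            continue
        x, y = data[a].to_numpy(float), data[b].to_numpy(float)
        method = shapiro_gate(x, y, alpha)
        if method == "pearson":
            r, p = sps.pearsonr(x, y)
        else:
            r, p = sps.spearmanr(x, y)
        results.append(StatResult(name, method, float(r), float(p), len(data)))
    if fdr:
        tested = [i for i, r in enumerate(results) if np.isfinite(r.p)]
        adjusted = bh_fdr([results[i].p for i in tested])
        for i, padj in zip(tested, adjusted):
            r = results[i]
            results[i] = StatResult(r.name, r.method, r.statistic, r.p, r.n,
                                    p_adjusted=float(padj))
    return results


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up), input order kept.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


def two_sample_t_power(d: float, n1: int, n2: int,
                       alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at standardized effect d."""
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sensitivity_effect_size(n1: int, n2: int, alpha: float = 0.05,
                            power: float = 0.80, tol: float = 1e-6) -> float:
    """Minimum detectable Cohen's d for a two-sided two-sample t-test.

    Solves power(d) = ``power`` via the noncentral t distribution
    (noncentrality d * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2) by
    bisection to ``tol``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError(f"power ({power}) must exceed alpha ({alpha})")
    lo, hi = 0.0, 1.0
    while two_sample_t_power(hi, n1, n2, alpha) < power:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("no solution found")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if two_sample_t_power(mid, n1, n2, alpha) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# end-to-end cohort analysis
# ---------------------------------------------------------------------------

BSDM_COLS = tuple(f"bsdm_{r}" for r in BSDM_REGIONS)


def select_worst_hip(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-hip ``<name>_left``/``<name>_right`` column pairs.

    Per-hip measures (cartilage relaxation means) are taken from the hip
    with the higher Kellgren-Lawrence grade; ties resolve to the left hip.
    Tables without per-hip columns pass through unchanged.
    """
    out = table.copy()
    paired = sorted(
        c[:-5] for c in table.columns
        if c.endswith("_left") and f"{c[:-5]}_right" in table.columns
        and c not in ("kl_left",)
    )
    paired = [p for p in paired if p != "kl"]
    if not paired:
        return out
    use_right = table["kl_right"] > table["kl_left"]
    for stem in paired:
        out[stem] = np.where(use_right, table[f"{stem}_right"],
                             table[f"{stem}_left"])
        out = out.drop(columns=[f"{stem}_left", f"{stem}_right"])
    return out


def run_paper_analysis(table: pd.DataFrame,
                       covariates: Sequence[str] | None = DEFAULT_COVARIATES,
                       alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """The full cohort analysis: group comparisons plus a correlation family.

    * group comparison (control vs OA) of each BSDM region, covariate
      adjusted, raw p-values;
    * one BH-corrected correlation family of every BSDM region against
      every cartilage subregion mean and the three functional scores,
      method gated per pair by Shapiro-Wilk.

    Returns ``{"group_comparison": ..., "correlations": ...}`` frames.
    """
    required = {"group", *BSDM_COLS}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    data = select_worst_hip(table)

    comp_rows = []
    for col in BSDM_COLS:
        res = adjusted_group_compare(data, col, covariates)
        comp_rows.append((col.removeprefix("bsdm_"), res.method,
                          res.statistic, res.p, res.n))
    comparison = pd.DataFrame(
        comp_rows, columns=["region", "method", "statistic", "p", "n"]
    ).set_index("region")

    partners = [c for c in (*CARTILAGE_COLUMNS, *FUNCTIONAL_COLUMNS)
                if c in data.columns]
    pairs = [(b, o) for b in BSDM_COLS for o in partners]
    corr = correlate(data, pairs, alpha=alpha, fdr=True)
    correlations = pd.DataFrame(
        [(r.name, r.method, r.statistic, r.p, r.p_adjusted, r.n)
         for r in corr],
        columns=["pair", "method", "statistic", "p", "p_adjusted", "n"],
    ).set_index("pair")
    return {"group_comparison": comparison, "correlations": correlations}
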