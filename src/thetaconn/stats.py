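"""Inferential layer: repeated-measures ANOVA, Holm-corrected post-hocs, and
bootstrap-corrected correlations.

The ANOVA is the classical sums-of-squares decomposition with
Greenhouse-Geisser correction when sphericity is violated (delegated to
pingouin).  Post-hoc comparisons use the paired t-test, falling back to the
Wilcoxon signed-rank test when a Shapiro-Wilk check on the paired
differences rejects normality at alpha = 0.05; p-values are Holm-Bonferroni
adjusted within the comparison family.  Correlations are Spearman by default
with a percentile bootstrap confidence interval and a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["AnovaResult", "CorrelationResult", "rm_anova", "posthoc", "bootstrap_correlation"]

SHAPIRO_ALPHA = 0.05


@dataclass
class AnovaResult:
    """Per-effect F statistics with sphericity handling.

    ``table`` has one row per effect with columns effect, F, df1, df2, p,
    p_corrected (Greenhouse-Geisser, when applicable) and sphericity.
    """

    table: pd.DataFrame
    n_subjects: int
    dropped_subjects: list = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"].str.lower() == name.lower()]
        if hit.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return hit.iloc[0]

    def p(self, name: str) -> float:
        row = self.effect(name)
        pc = row.get("p_corrected")
        return float(pc) if pc == pc and pc is not None else float(row["p"])


@dataclass
class CorrelationResult:
    rho: float
    p: float
    ci: tuple[float, float]
    ci_level: float
    n: int
    n_boot: int
    method: str
    seed: int | None = None


def _drop_incomplete(data: pd.DataFrame, dv: str, within: str, subject: str) -> tuple[pd.DataFrame, list]:
    """Listwise-drop subjects with any missing cell of the within factor."""
    levels = data[within].unique()
    ok_subjects, dropped = [], []
    for subj, sub in data.groupby(subject):
        complete = set(sub.dropna(subset=[dv])[within]) >= set(levels)
        (ok_subjects if complete else dropped).append(subj)
    return data[data[subject].isin(ok_subjects)].dropna(subset=[dv]), dropped


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "session",
    subject: str = "subject",
    between: str | None = None,
) -> AnovaResult:
    """Repeated-measures (or mixed) ANOVA on a tidy table.

    ``within`` is the repeated factor (e.g. session); an optional ``between``
    factor (e.g. cued hand as a group variable) turns this into a mixed
    design.  Subjects with missing cells are dropped listwise and reported.
    """
    import pingouin as pg

    data, dropped = _drop_incomplete(data, dv, within, subject)
    n_subjects = data[subject].nunique()
    if between is not None:
        counts = data.groupby(between)[subject].nunique()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need >= 2 subjects in each between-subjects group")
        aov = pg.mixed_anova(
            data=data, dv=dv, within=within, between=between, subject=subject, correction=True
        )
    else:
        if n_subjects < 2:
            raise ValueError("need >= 2 subjects for a repeated-measures ANOVA")
        # sphericity needs more subjects than within levels to be estimable
        correction = n_subjects > data[within].nunique()
        aov = pg.rm_anova(
            data=data, dv=dv, within=within, subject=subject,
            correction=correction, detailed=True,
        )
    err_df = np.nan
    if "DF" in aov.columns:
        err_rows = aov[aov["Source"].str.lower().isin(["error", "residual"])]
        if not err_rows.empty:
            err_df = float(err_rows.iloc[0]["DF"])
    rows = []
    for _, r in aov.iterrows():
        effect = str(r["Source"])
        if effect.lower() in ("error", "residual", "within"):
            continue
        gg = r.get("p_GG_corr", np.nan)
        spher = r.get("sphericity", True)
        rows.append(
            {
                "effect": effect,
                "F": float(r["F"]),
                "df1": float(r["DF1"]) if "DF1" in r else float(r["DF"]),
                "df2": float(r["DF2"]) if "DF2" in r else err_df,
                "p": float(r["p_unc"]),
                "p_corrected": float(gg) if gg == gg else np.nan,
                "sphericity": bool(spher) if spher == spher and spher is not None else True,
            }
        )
    return AnovaResult(table=pd.DataFrame(rows), n_subjects=n_subjects, dropped_subjects=dropped)


def posthoc(
    data: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    dv: str = "value",
    factor: str = "session",
    subject: str = "subject",
) -> pd.DataFrame:
    """Paired post-hoc tests with Holm-Bonferroni adjustment.

    For each (level_a, level_b) pair of ``factor``, computes the paired
    differences across subjects and applies a paired t-test, or a Wilcoxon
    signed-rank test when Shapiro-Wilk rejects normality of the differences.
    Returns one row per comparison with test, statistic, p_raw, p_holm and
    the mean difference (a - b).
    """
    rows = []
    for a, b in comparisons:
        pivot = (
            data[data[factor].isin([a, b])]
            .pivot_table(index=subject, columns=factor, values=dv, observed=True)
        )
        if a not in pivot.columns or b not in pivot.columns:
            missing = [lvl for lvl in (a, b) if lvl not in pivot.columns]
            raise ValueError(f"no observations for level(s) {missing} of {factor}")
        pivot = pivot.dropna()
        if len(pivot) < 3:
            raise ValueError(f"fewer than 3 paired observations for {a} vs {b}")
        diff = (pivot[a] - pivot[b]).to_numpy()
        if np.allclose(diff, diff[0]):
            normal = True  # constant differences: Shapiro undefined, t-test handles
        else:
            normal = sps.shapiro(diff).pvalue >= SHAPIRO_ALPHA
        if normal:
            if np.allclose(diff, 0):
                test, stat, p = "t", 0.0, 1.0
            else:
                res = sps.ttest_rel(pivot[a], pivot[b])
                test, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = sps.wilcoxon(diff, zero_method="wilcox")
            test, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "a": a,
                "b": b,
                "test": test,
                "statistic": stat,
                "mean_diff": float(diff.mean()),
                "n": len(pivot),
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def _rank_corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two (m, n) matrices."""
    xr = sps.rankdata(x, axis=-1)
    yr = sps.rankdata(y, axis=-1)
    xc = xr - xr.mean(axis=-1, keepdims=True)
    yc = yr - yr.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, (xc * yc).sum(axis=-1) / np.maximum(denom, 1e-300), np.nan)


def bootstrap_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 50_000,
    rng: np.random.Generator | int | None = None,
    ci_level: float = 0.95,
    method: str = "spearman",
    chunk: int = 20_000,
) -> CorrelationResult:
    """Correlation with percentile-bootstrap CI and permutation p-value.

    Pairs (x_i, y_i) are resampled with replacement ``n_boot`` times for the
    CI; the two-sided p-value comes from ``n_boot`` permutations of y with
    the +1 correction.  Spearman's rho by default; Pearson via ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    if method == "spearman":
        rho = float(sps.spearmanr(x, y).statistic)
        corr_rows = _rank_corr_rows
    else:
        rho = float(sps.pearsonr(x, y).statistic)

        def corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            ac = a - a.mean(axis=-1, keepdims=True)
            bc = b - b.mean(axis=-1, keepdims=True)
            denom = np.sqrt((ac**2).sum(-1) * (bc**2).sum(-1))
            with np.errstate(invalid="ignore"):
                return np.where(denom > 0, (ac * bc).sum(-1) / np.maximum(denom, 1e-300), np.nan)

    boots = np.empty(n_boot)
    for c0 in range(0, n_boot, chunk):
        m = min(chunk, n_boot - c0)
        idx = rng.integers(0, n, size=(m, n))
        boots[c0 : c0 + m] = corr_rows(x[idx], y[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.quantile(boots, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])

    exceed = 0
    for c0 in range(0, n_boot, chunk):
        m = min(chunk, n_boot - c0)
        perm = rng.permuted(np.broadcast_to(y, (m, n)).copy(), axis=-1)
        rp = corr_rows(np.broadcast_to(x, (m, n)), perm)
        exceed += int((np.abs(rp) >= abs(rho) - 1e-12).sum())
    p = (1 + exceed) / (n_boot + 1)

    return CorrelationResult(
        rho=rho, p=float(p), ci=(float(lo), float(hi)), ci_level=ci_level,
        n=n, n_boot=n_boot, method=method, seed=seed,
    )
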