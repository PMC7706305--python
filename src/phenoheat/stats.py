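"""Temporal group comparisons, interaction models and correlation analyses.

Implements the statistical layer of the heat-stress phenotyping analysis:

* two-sample Student's t-tests (equal-variance by default, Welch behind a
  flag) comparing treated vs. control groups per trait and day;
* the significance-star notation (* p<0.05 .. **** p<0.0001);
* the genotype x treatment interaction model ``trait ~ genotype + treatment
  + genotype:treatment`` fitted by ordinary least squares for each heat
  level against control, with treatment (reference-level) contrasts —
  reference = WT, control;
* Pearson correlation matrices with t-distribution p-values;
* the cross-time correlation analysis relating a trait at one day to a
  trait at another day per genotype x treatment stratum (e.g. photochemical
  quenching right after stress vs. rosette area a week later).

No multiple-testing correction is applied by default (per-day starring);
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class StatResult:
    """One estimated contrast with its test."""

    estimate: float
    se: float
    statistic: float
    df: float
    p: float
    stars: str


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two (trait, day) variables."""

    trait_a: str
    das_a: int
    trait_b: str
    das_b: int
    stratum: str
    r: float
    p: float
    n: int


class DegenerateVarianceError(ValueError):
    """Zero pooled variance with unequal means: the t-test is undefined."""


def significance_stars(p: float) -> str:
    """Map a p-value to the star notation used in figure legends.

    '' for p >= 0.05, then '*', '**', '***', '****' below 0.05, 0.01,
    0.001 and 0.0001 respectively.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    return "*" * sum(p < t for t in STAR_THRESHOLDS)


def students_ttest(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> StatResult:
    """Two-sided two-sample t-test on the difference of means (x - y).

    Classic pooled-variance Student's test by default; ``equal_var=False``
    switches to Welch's test with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = x.mean() - y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if equal_var:
        df = nx + ny - 2
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        if pooled == 0.0:
            if diff == 0.0:
                return StatResult(0.0, 0.0, 0.0, float(df), 1.0, "")
            raise DegenerateVarianceError(
                "zero pooled variance with unequal means"
            )
        se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    else:
        if vx == 0.0 and vy == 0.0:
            if diff == 0.0:
                return StatResult(0.0, 0.0, 0.0, float(nx + ny - 2), 1.0, "")
            raise DegenerateVarianceError(
                "zero variances with unequal means"
            )
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(float(diff), float(se), float(t), float(df), float(p), significance_stars(p))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """OLS via normal equations; returns (beta, se, sigma2, df_resid)."""
    n, p = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise np.linalg.LinAlgError("singular design matrix (rank-deficient)")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, sigma2, df


def fit_interaction_model(
    table: pd.DataFrame,
    trait: str,
    hs_level: str,
    control_level: str = "control",
    reference_genotype: str = "WT",
    das: int | None = None,
) -> dict[str, StatResult]:
    """Fit ``trait ~ genotype + treatment + genotype:treatment`` by OLS.

    The model compares one heat-stress level against control with
    reference-level (treatment-contrast) coding: the reference cell is
    (reference genotype, control).  Days are pooled unless ``das`` is given.

    Returns a dict with keys ``intercept``, ``genotype``, ``treatment``,
    ``genotype:treatment`` mapping to coefficient tests with residual df.
    """
    sub = table[(table["trait"] == trait) & table["treatment"].isin([control_level, hs_level])]
    if das is not None:
        sub = sub[sub["das"] == das]
    if sub.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    genotypes = sorted(sub["genotype"].unique(), key=lambda g: g != reference_genotype)
    if len(genotypes) != 2 or len(sub["treatment"].unique()) != 2:
        raise ValueError("need both genotypes and both treatment levels present")
    g = (sub["genotype"] != reference_genotype).to_numpy(dtype=float)
    t = (sub["treatment"] == hs_level).to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(g), g, t, g * t])
    beta, se, _, df = _ols(X, y)
    out: dict[str, StatResult] = {}
    for name, b, s in zip(("intercept", "genotype", "treatment", "genotype:treatment"), beta, se):
        tstat = b / s if s > 0 else np.inf * np.sign(b)
        p = float(2.0 * sps.t.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
        out[name] = StatResult(float(b), float(s), float(tstat), float(df), p, significance_stars(p))
    return out


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0.0:
        raise ValueError("zero-variance column")
    r = float(np.clip((dx @ dy) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p, n


def pearson_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlations of a wide plants x traits frame.

    Uses pairwise-complete rows.  Zero-variance columns are flagged and
    their pairs skipped.  Returns a tidy frame with columns ``col_a, col_b,
    r, p, n``; the matrix form can be recovered by pivoting.
    """
    cols = list(df.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            try:
                r, p, n = pearson_r_p(df[a].to_numpy(), df[b].to_numpy())
            except ValueError as err:
                warnings.warn(f"skipping pair ({a}, {b}): {err}", stacklevel=2)
                continue
            rows.append((a, b, r, p, n))
            if a != b:
                rows.append((b, a, r, p, n))
    return pd.DataFrame(rows, columns=["col_a", "col_b", "r", "p", "n"])


def _wide_trait_day(table: pd.DataFrame, trait: str, das: int) -> pd.Series:
    sub = table[(table["trait"] == trait) & (table["das"] == das)]
    return sub.set_index("plant_id")["value"]


def cross_time_correlation(
    table: pd.DataFrame,
    trait_a: tuple[str, int],
    trait_b: tuple[str, int],
    stratify: Sequence[str] = ("genotype", "treatment"),
) -> list[CorrelationResult]:
    """Per-stratum Pearson correlation between trait A at day a and trait B at day b.

    Plants present at both days are paired by id; strata (default genotype x
    treatment cells) with fewer than 3 complete plants are omitted with a
    warning.
    """
    name_a, das_a = trait_a
    name_b, das_b = trait_b
    meta = table[["plant_id", *stratify]].drop_duplicates().set_index("plant_id")
    va = _wide_trait_day(table, name_a, das_a)
    vb = _wide_trait_day(table, name_b, das_b)
    paired = pd.DataFrame({"a": va, "b": vb}).dropna().join(meta)
    results: list[CorrelationResult] = []
    for keys, grp in paired.groupby(list(stratify), sort=True):
        label = ":".join(map(str, keys if isinstance(keys, tuple) else (keys,)))
        if len(grp) < 3:
            warnings.warn(f"stratum {label}: fewer than 3 paired plants, omitted", stacklevel=2)
            continue
        try:
            r, p, n = pearson_r_p(grp["a"].to_numpy(), grp["b"].to_numpy())
        except ValueError as err:
            warnings.warn(f"stratum {label}: {err}", stacklevel=2)
            continue
        results.append(CorrelationResult(name_a, das_a, name_b, das_b, label, r, p, n))
    return results


def cross_time_grid(
    table: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    days: Sequence[int],
    stratify: Sequence[str] = ("treatment",),
) -> pd.DataFrame:
    """Full day x day correlogram between two traits, per stratum.

    Returns a tidy frame (trait_a, das_a, trait_b, das_b, stratum, r, p, n)
    covering every day pair — the correlogram relating e.g. photochemical
    quenching at each day to rosette area at each day.
    """
    rows = []
    for da, db in product(days, days):
        for res in cross_time_correlation(table, (trait_a, da), (trait_b, db), stratify):
            rows.append(
                (res.trait_a, res.das_a, res.trait_b, res.das_b, res.stratum, res.r, res.p, res.n)
            )
    return pd.DataFrame(
        rows, columns=["trait_a", "das_a", "trait_b", "das_b", "stratum", "r", "p", "n"]
    )


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def treated_vs_control_tests(
    table: pd.DataFrame,
    traits: Sequence[str] | None = None,
    genotype: str = "WT",
    control_level: str = "control",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-trait, per-day t-tests of each heat level against control.

    Mirrors the daily starring of the time-course figures: within one
    genotype, each stressed group is compared with the control group for
    every trait and imaging day.  Returns a tidy frame (trait, das,
    treatment, estimate, se, t, df, p, stars).
    """
    sub = table[table["genotype"] == genotype]
    if traits is not None:
        sub = sub[sub["trait"].isin(traits)]
    rows = []
    treatments = [t for t in sub["treatment"].unique() if t != control_level]
    for (trait, das), grp in sub.groupby(["trait", "das"], sort=True):
        ctrl = grp.loc[grp["treatment"] == control_level, "value"].to_numpy()
        for treat in treatments:
            trt = grp.loc[grp["treatment"] == treat, "value"].to_numpy()
            if ctrl.size < 2 or trt.size < 2:
                continue
            try:
                res = students_ttest(trt, ctrl, equal_var=equal_var)
            except DegenerateVarianceError:
                continue
            rows.append(
                (trait, das, treat, res.estimate, res.se, res.statistic, res.df, res.p, res.stars)
            )
    return pd.DataFrame(
        rows, columns=["trait", "das", "treatment", "estimate", "se", "t", "df", "p", "stars"]
    )


def genotype_tests(
    table: pd.DataFrame,
    traits: Sequence[str] | None = None,
    reference_genotype: str = "WT",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-trait, per-day, per-treatment t-tests of mutant vs. reference genotype."""
    sub = table if traits is None else table[table["trait"].isin(traits)]
    rows = []
    for (trait, das, treat), grp in sub.groupby(["trait", "das", "treatment"], sort=True):
        ref = grp.loc[grp["genotype"] == reference_genotype, "value"].to_numpy()
        alt = grp.loc[grp["genotype"] != reference_genotype, "value"].to_numpy()
        if ref.size < 2 or alt.size < 2:
            continue
        try:
            res = students_ttest(alt, ref, equal_var=equal_var)
        except DegenerateVarianceError:
            continue
        rows.append(
            (trait, das, treat, res.estimate, res.se, res.statistic, res.df, res.p, res.stars)
        )
    return pd.DataFrame(
        rows, columns=["trait", "das", "treatment", "estimate", "se", "t", "df", "p", "stars"]
    )
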