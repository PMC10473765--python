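"""Standardized sex-effect estimation on regional brain volumes.

The central quantity is the coefficient of sex from an ordinary least-squares
fit to a z-scored volume::

    z(volume) ~ intercept + b1*sex + b2*(age - mean age) + b3*TTV + b4*QC

where TTV is total tissue volume and the QC covariate is either a numeric
surface-reconstruction quality index (human-style) or a categorical
background-strain label (mouse-style). Because the response is z-scored, b1
is a unitless standardized effect size; sex is coded female = 0 / male = 1,
so positive values are male-biased.

The module also provides the surrounding machinery: QC exclusions,
Benjamini-Hochberg FDR, Levene variance tests on residualized volumes,
subject subsampling for family structure, and empirical-Bayes location-scale
batch harmonization of multi-cohort data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import (
    DegenerateInputError,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "ModelSpec",
    "EffectSizeResult",
    "VarianceTestResult",
    "SexBiasSummary",
    "apply_qc_exclusions",
    "zscore_response",
    "fit_sex_effect",
    "fit_sex_effects_table",
    "fdr_adjust",
    "residualize",
    "levene_variance_test",
    "harmonize_batches",
    "summarize_sex_bias",
    "subset_one_per_family",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Column names and options for the sex-effect model.

    ``qc_categorical`` switches the QC covariate between a numeric column
    (human-style quality index) and a treatment-coded categorical (mouse-style
    background strain). ``include_ttv`` drops the TTV covariate for the
    no-global-scaling sensitivity analysis; it is forced off when the response
    is TTV itself. ``zscore_ttv`` optionally standardizes the TTV covariate
    (the fitted sex coefficient is invariant to this choice).
    """

    response: str
    sex_col: str = "sex"
    age_col: str = "age"
    ttv_col: str = "ttv"
    qc_col: str | None = None
    qc_categorical: bool = False
    include_ttv: bool = True
    zscore_ttv: bool = False
    male_level: str = "M"

    def covariate_columns(self) -> list[str]:
        cols = [self.sex_col, self.age_col]
        if self.include_ttv and self.response != self.ttv_col:
            cols.append(self.ttv_col)
        if self.qc_col is not None:
            cols.append(self.qc_col)
        return cols


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardized sex effect for one region, with OLS inference."""

    region: str
    beta_sex: float
    t: float
    p: float
    n: int
    q: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class VarianceTestResult:
    """Levene's test of equal residual variance between sexes."""

    region: str
    F: float
    p: float
    group_variances: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SexBiasSummary:
    """Share of significant regions and effect-size summaries by direction."""

    n_regions: int
    pct_significant: float
    pct_female_biased_of_sig: float
    pct_male_biased_of_sig: float
    female_median: float
    female_sd: float
    female_range: tuple[float, float]
    male_median: float
    male_sd: float
    male_range: tuple[float, float]


def apply_qc_exclusions(table: pd.DataFrame, euler_threshold: int = -200,
                        euler_col: str = "euler") -> pd.DataFrame:
    """Drop subjects whose surface-quality index falls below the threshold."""
    if euler_col not in table.columns:
        raise ValidationError(f"missing QC column {euler_col!r}")
    keep = ~(table[euler_col] < euler_threshold)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("QC exclusion: removed %d of %d subjects (%s < %d)",
                    n_drop, len(table), euler_col, euler_threshold)
    return table[keep]


def zscore_response(values: Sequence[float]) -> np.ndarray:
    """z-score with the sample (ddof=1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values to z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant response cannot be z-scored")
    return (v - v.mean()) / sd


def _design_matrix(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept, male indicator, centered age, optional TTV, optional QC term."""
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]

    sex = table[spec.sex_col]
    if sex.isna().any():
        raise ValidationError("sex must be non-missing")
    male = (sex == spec.male_level).to_numpy(dtype=float)
    if male.min() == male.max():
        raise ValidationError("both sexes must be present")
    cols.append(male)
    names.append("sex")

    age = table[spec.age_col].to_numpy(dtype=float)
    cols.append(age - age.mean())
    names.append("age_centered")

    if spec.include_ttv and spec.response != spec.ttv_col:
        ttv = table[spec.ttv_col].to_numpy(dtype=float)
        if spec.zscore_ttv:
            ttv = zscore_response(ttv)
        cols.append(ttv)
        names.append("ttv")

    if spec.qc_col is not None:
        qc = table[spec.qc_col]
        if spec.qc_categorical:
            levels = sorted(qc.astype(str).unique())
            for lev in levels[1:]:  # treatment coding, first level = reference
                cols.append((qc.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{spec.qc_col}[{lev}]")
        else:
            cols.append(qc.to_numpy(dtype=float))
            names.append(spec.qc_col)

    return np.column_stack(cols), names


def _ols(X: np.ndarray, y: np.ndarray):
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"n={n} subjects for k={k} coefficients")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise SingularDesignError("rank-deficient design matrix")
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    df_resid = n - k
    s2 = resid @ resid / df_resid
    cov = s2 * np.linalg.inv(XtX)
    return coef, np.sqrt(np.diag(cov)), df_resid, resid


def fit_sex_effect(table: pd.DataFrame, spec: ModelSpec) -> EffectSizeResult:
    """OLS fit of the z-scored response; returns the standardized sex effect."""
    if spec.response not in table.columns:
        raise ValidationError(f"response column {spec.response!r} not in table")
    y = zscore_response(table[spec.response].to_numpy(dtype=float))
    X, names = _design_matrix(table, spec)
    coef, se, df_resid, _ = _ols(X, y)
    i = names.index("sex")
    t = coef[i] / se[i]
    p = 2.0 * stats.t.sf(abs(t), df_resid)
    return EffectSizeResult(region=spec.response, beta_sex=float(coef[i]),
                            t=float(t), p=float(p), n=len(table))


def fit_sex_effects_table(table: pd.DataFrame, regions: Sequence[str],
                          spec: ModelSpec, q_level: float = 0.05) -> pd.DataFrame:
    """Fit every region with the same covariate structure and apply BH-FDR."""
    results = [fit_sex_effect(table, _respec(spec, r)) for r in regions]
    df = pd.DataFrame(
        {
            "region": [r.region for r in results],
            "beta_sex": [r.beta_sex for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
        }
    )
    q, sig = fdr_adjust(df["p"].to_numpy(), q_level=q_level)
    df["q"] = q
    df["significant"] = sig
    return df


def _respec(spec: ModelSpec, response: str) -> ModelSpec:
    from dataclasses import replace

    return replace(spec, response=response)


def fdr_adjust(pvalues: Sequence[float], q_level: float = 0.05):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def residualize(table: pd.DataFrame, covariates: Sequence[str],
                regions: Sequence[str]) -> pd.DataFrame:
    """OLS residuals of each region volume on the covariates (plus intercept).

    Sex must not be among the covariates: the residuals are meant to retain
    the sex signal (e.g., for variance tests between sexes).
    """
    for c in covariates:
        if c not in table.columns:
            raise ValidationError(f"covariate column {c!r} not in table")
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("rank-deficient covariate matrix")
    out = {}
    proj = np.linalg.solve(X.T @ X, X.T)
    for r in regions:
        y = table[r].to_numpy(dtype=float)
        out[r] = y - X @ (proj @ y)
    return pd.DataFrame(out, index=table.index)


def levene_variance_test(residuals: Sequence[float], sex: Sequence[str],
                         region: str = "", center: str = "mean") -> VarianceTestResult:
    """Classic Levene test (ANOVA on absolute deviations from group means)."""
    residuals = np.asarray(residuals, dtype=float)
    sex = np.asarray(sex)
    groups = [residuals[sex == g] for g in pd.unique(sex)]
    if len(groups) < 2:
        raise ValidationError("need both sexes for a variance test")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each sex needs at least 2 subjects")
    F, p = stats.levene(*groups, center=center)
    gv = {str(g): float(residuals[sex == g].var(ddof=1)) for g in pd.unique(sex)}
    return VarianceTestResult(region=region, F=float(F), p=float(p), group_variances=gv)


# ---------------------------------------------------------------------------
# Batch harmonization (parametric empirical-Bayes location-scale adjustment)
# ---------------------------------------------------------------------------

def _eb_fit(z_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat_sq: np.ndarray,
            gamma_bar: float, tau_sq: float, a_prior: float, b_prior: float,
            conv: float = 1e-4, max_iter: int = 500):
    """Iterative joint solution of the location/scale posterior modes."""
    n = z_batch.shape[0]
    gamma = gamma_hat.copy()
    delta_sq = delta_hat_sq.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau_sq * gamma_hat + delta_sq * gamma_bar) / (n * tau_sq + delta_sq)
        ssq = np.sum((z_batch - gamma_new[None, :]) ** 2, axis=0)
        delta_new = (0.5 * ssq + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(gamma_new - gamma) / np.maximum(np.abs(gamma), 1e-12)),
                     np.max(np.abs(delta_new - delta_sq) / np.maximum(delta_sq, 1e-12)))
        gamma, delta_sq = gamma_new, delta_new
        if change < conv:
            break
    return gamma, delta_sq


def harmonize_batches(table: pd.DataFrame, batch_col: str, regions: Sequence[str],
                      preserve: Sequence[str] = (), sex_col: str = "sex",
                      male_level: str = "M") -> pd.DataFrame:
    """Remove batch location/scale effects while preserving covariate signal.

    Parametric empirical-Bayes harmonization in the ComBat family: each region
    is standardized on a fit that retains the preserved covariates (sex coded
    as a male indicator, other columns numeric), per-batch means and variances
    are shrunk toward their across-region empirical priors (normal prior on
    locations, inverse-gamma on scales, moment-matched), the shrunken batch
    effects are removed and the preserved effects restored.

    A single batch is returned unchanged. Every batch needs >= 2 subjects.
    """
    if batch_col not in table.columns:
        raise ValidationError(f"missing batch column {batch_col!r}")
    batches = pd.unique(table[batch_col])
    counts = table[batch_col].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"batches with fewer than 2 subjects: {small}")
    if len(batches) == 1:
        return table.copy()

    Y = table[list(regions)].to_numpy(dtype=float)  # n x G
    n, G = Y.shape
    B = np.column_stack([(table[batch_col] == b).to_numpy(dtype=float) for b in batches])
    n_per = B.sum(axis=0)

    cov_cols: list[np.ndarray] = []
    for c in preserve:
        if c == sex_col:
            cov_cols.append((table[c] == male_level).to_numpy(dtype=float))
        else:
            v = table[c].to_numpy(dtype=float)
            cov_cols.append(v - v.mean())
    X = np.column_stack([B] + cov_cols) if cov_cols else B

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("batch/covariate design is rank-deficient")
    beta = np.linalg.solve(X.T @ X, X.T @ Y)  # (I + p) x G
    I = len(batches)
    grand = (n_per / n) @ beta[:I]  # precision-weighted grand mean per region
    stand_mean = np.tile(grand, (n, 1))
    if cov_cols:
        stand_mean = stand_mean + np.column_stack(cov_cols) @ beta[I:]
    var_pooled = np.mean((Y - X @ beta) ** 2, axis=0)
    if np.any(var_pooled == 0):
        var_pooled = np.where(var_pooled == 0, 1.0, var_pooled)
    Z = (Y - stand_mean) / np.sqrt(var_pooled)

    Y_adj = np.empty_like(Y)
    for i, b in enumerate(batches):
        rows = (table[batch_col] == b).to_numpy()
        Zi = Z[rows]
        gamma_hat = Zi.mean(axis=0)
        delta_hat_sq = Zi.var(axis=0, ddof=1)
        # a batch that is exactly constant in a region carries no scale
        # information; leave its scale untouched
        delta_hat_sq = np.where(delta_hat_sq == 0, 1.0, delta_hat_sq)
        if G >= 2:
            gamma_bar = float(gamma_hat.mean())
            tau_sq = float(gamma_hat.var(ddof=1))
            m, s2 = float(delta_hat_sq.mean()), float(delta_hat_sq.var(ddof=1))
            if tau_sq > 0 and s2 > 0:
                a_prior = (2.0 * s2 + m * m) / s2
                b_prior = (m * s2 + m**3) / s2
                gamma_star, delta_sq_star = _eb_fit(
                    Zi, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, a_prior, b_prior
                )
            else:
                gamma_star, delta_sq_star = gamma_hat, delta_hat_sq
        else:
            gamma_star, delta_sq_star = gamma_hat, delta_hat_sq
        Y_adj[rows] = (
            (Zi - gamma_star[None, :]) / np.sqrt(delta_sq_star)[None, :]
        ) * np.sqrt(var_pooled)[None, :] + stand_mean[rows]

    out = table.copy()
    out[list(regions)] = Y_adj
    return out


def summarize_sex_bias(results: pd.DataFrame) -> SexBiasSummary:
    """Proportions of significant regions and beta summaries split by sign.

    Sign statistics are computed over the *significant* regions: negative
    betas are female-biased, positive male-biased, under the female-reference
    coding.
    """
    if len(results) == 0:
        raise ValidationError("empty results table")
    sig = results[results["significant"].astype(bool)]
    pct_sig = 100.0 * len(sig) / len(results)
    fem = sig[sig["beta_sex"] < 0]["beta_sex"]
    mal = sig[sig["beta_sex"] > 0]["beta_sex"]
    if len(sig) == 0:
        logger.warning("no significant regions; sex-bias proportions reported as 0")
        pf = pm = 0.0
    else:
        pf = 100.0 * len(fem) / len(sig)
        pm = 100.0 * len(mal) / len(sig)

    def _stats(v: pd.Series):
        if len(v) == 0:
            return float("nan"), float("nan"), (float("nan"), float("nan"))
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return float(v.median()), sd, (float(v.min()), float(v.max()))

    f_med, f_sd, f_rng = _stats(fem)
    m_med, m_sd, m_rng = _stats(mal)
    return SexBiasSummary(
        n_regions=len(results), pct_significant=pct_sig,
        pct_female_biased_of_sig=pf, pct_male_biased_of_sig=pm,
        female_median=f_med, female_sd=f_sd, female_range=f_rng,
        male_median=m_med, male_sd=m_sd, male_range=m_rng,
    )


def subset_one_per_family(table: pd.DataFrame, seed: int,
                          family_col: str = "family_id") -> pd.DataFrame:
    """Keep one randomly chosen subject per family (deterministic in the seed)."""
    if family_col not in table.columns:
        raise ValidationError(f"missing family column {family_col!r}")
    rng = np.random.default_rng(seed)
    keep_positions = []
    for _, idx in table.groupby(family_col, sort=True).indices.items():
        keep_positions.append(idx[rng.integers(len(idx))])
    keep_positions.sort()
    return table.iloc[keep_positions]
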