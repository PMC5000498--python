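"""Contingency tests, FDR control, and AICc multi-model inference.

These are the statistics behind functional-enrichment testing (two-tailed
Fisher's exact test with Benjamini-Hochberg FDR) and the alternative-
splicing factor analysis: a complete-case factor table with log/z
transforms, logistic regressions over every factor subset, AICc-based
Akaike weights, model-averaged coefficients and per-factor relative
importance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


def fisher_exact(
    table: Sequence[Sequence[int]], alternative: str = "two_sided"
) -> float:
    """Fisher's exact test p-value for a 2x2 table.

    Two-sided p-values follow the point-probability convention: the sum of
    hypergeometric outcomes whose probability does not exceed that of the
    observed table.  A zero margin carries no information and returns
    p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1")
        return 1.0
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[
        alternative
    ]
    return float(scipy.stats.fisher_exact(t, alternative=alt).pvalue)


def bh_fdr(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control at level *q*.

    Returns (reject flags, adjusted p-values) in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


# ---------------------------------------------------------------------------
# Factor table
# ---------------------------------------------------------------------------

LOG_Z_COLUMNS = (
    "broad_paralog_count",
    "intron_count",
    "transcript_length",
    "divergence_ratio",
)
LOG_ONLY_COLUMNS = ("cds_transcript_ratio",)


def _log_z(col: pd.Series, z: bool = True) -> pd.Series:
    logged = np.log(col.astype(float))
    if not z:
        return logged - logged.mean()
    sd = logged.std(ddof=1)
    return (logged - logged.mean()) / sd


def build_factor_table(
    annotations: pd.DataFrame,
    expression_tier: pd.Series,
    intron_tier: pd.Series,
    strong_only: bool = True,
) -> pd.DataFrame:
    """Assemble the complete-case, transformed table for the splicing model.

    *annotations* is indexed by gene_id with the response ``has_isoform``
    plus the factor columns (counts and lengths untransformed; counts of
    zero are shifted by +1 before the log, as is conventional for
    "plus-one" paralog counts).  Genes missing any factor are dropped;
    when *strong_only* is set, only genes whose expression and intron
    support tiers are both ``strong`` are retained — detection of isoforms
    scales with coverage, so weakly covered genes would bias every factor.
    Numeric factors are log-transformed then z-scored on the analysis
    subset (the CDS/transcript ratio is log-transformed and centered only).
    """
    required = ["has_isoform"]
    missing_cols = [c for c in required if c not in annotations.columns]
    if missing_cols:
        raise ValueError(f"factor column(s) entirely missing: {missing_cols}")
    df = annotations.copy()
    if strong_only:
        keep = (expression_tier.reindex(df.index) == "strong") & (
            intron_tier.reindex(df.index) == "strong"
        )
        df = df[keep.fillna(False)]
    df = df.dropna()
    out = pd.DataFrame(index=df.index)
    out["has_isoform"] = df["has_isoform"].astype(int)
    for col in df.columns:
        if col == "has_isoform":
            continue
        if col in LOG_Z_COLUMNS:
            shifted = df[col].astype(float)
            if (shifted <= 0).any():
                shifted = shifted + 1.0
            out[col] = _log_z(shifted, z=True)
        elif col in LOG_ONLY_COLUMNS:
            out[col] = _log_z(df[col], z=False)
        else:
            out[col] = df[col]
    return out


# ---------------------------------------------------------------------------
# AICc model averaging
# ---------------------------------------------------------------------------


@dataclass
class ModelAveragingResult:
    models: pd.DataFrame  # one row per candidate: factors, k, aicc, weight
    importance: dict[str, float]
    averaged_coefficients: dict[str, float]
    coefficient_se: dict[str, float] = field(default_factory=dict)
    excluded: list[tuple[str, ...]] = field(default_factory=list)
    c_hat: float = float("nan")


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_model_average(
    factor_table: pd.DataFrame,
    factors: Sequence[str],
    response: str = "has_isoform",
    max_factors: int = 12,
) -> ModelAveragingResult:
    """Fit logistic regressions for every factor subset and average by AICc.

    Akaike weights are exp(-dAICc/2) normalized over the candidate set; a
    factor's relative importance is the summed weight of the models that
    contain it.  Model-averaged coefficients weight each model's estimate
    (zero where the factor is absent).  Models whose IRLS fit diverges
    (separation) are excluded with a warning.  Overdispersion (Pearson
    chi^2 / df of the full model) is reported but not acted on.
    """
    import statsmodels.api as sm

    if len(factors) > max_factors:
        raise ValueError(f"more than {max_factors} factors")
    y = factor_table[response].astype(float)
    n = len(factor_table)
    rows = []
    fitted = {}
    excluded: list[tuple[str, ...]] = []
    for r in range(len(factors) + 1):
        for subset in itertools.combinations(factors, r):
            X = sm.add_constant(
                factor_table[list(subset)].astype(float), has_constant="add"
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                        maxiter=100
                    )
                if not np.all(np.isfinite(fit.params)) or np.any(
                    np.abs(fit.params) > 1e4
                ):
                    raise ValueError("separation")
            except Exception:
                warnings.warn(f"model {subset} excluded (separation/divergence)")
                excluded.append(subset)
                continue
            k = len(subset) + 1
            rows.append(
                {
                    "factors": subset,
                    "k": k,
                    "loglik": float(fit.llf),
                    "aicc": _aicc(float(fit.llf), k, n),
                }
            )
            fitted[subset] = fit
    models = pd.DataFrame(rows)
    delta = models["aicc"] - models["aicc"].min()
    w = np.exp(-delta / 2.0)
    models["weight"] = w / w.sum()

    importance = {
        f: float(
            models.loc[
                models["factors"].map(lambda s: f in s), "weight"
            ].sum()
        )
        for f in factors
    }
    averaged: dict[str, float] = {}
    se: dict[str, float] = {}
    for term in ["const", *factors]:
        est = 0.0
        var = 0.0
        for _, row in models.iterrows():
            fit = fitted[row["factors"]]
            beta = float(fit.params.get(term, 0.0))
            bse = float(fit.bse.get(term, 0.0))
            est += row["weight"] * beta
        for _, row in models.iterrows():
            fit = fitted[row["factors"]]
            beta = float(fit.params.get(term, 0.0))
            bse = float(fit.bse.get(term, 0.0))
            var += row["weight"] * np.sqrt(bse**2 + (beta - est) ** 2)
        averaged[term] = est
        se[term] = var
    full = fitted.get(tuple(factors))
    c_hat = float("nan")
    if full is not None:
        c_hat = float(full.pearson_chi2 / full.df_resid)
    return ModelAveragingResult(
        models=models,
        importance=importance,
        averaged_coefficients=averaged,
        coefficient_se=se,
        excluded=excluded,
        c_hat=c_hat,
    )
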