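"""Protein divergence analysis between a focal lineage and two outgroup clades.

Pairwise amino-acid distances are maximum-likelihood estimates under the
JTT empirical substitution model (expected substitutions per site).  For
every focal gene inside an ortholog group that also contains at least one
ant and one bee gene, the clade medians AN (focal vs ant), BN (focal vs
bee) and AB (ant vs bee, one median per group) give the compound ratio

    R = (AN + BN) / (AN + BN + AB)

which is 2/3 when all three clades diverge at equal rates.  R is logit
transformed and regressed on nuisance covariates (group median
divergence, paralog presence, transposon-associated expression) with an
ortholog-group effect; genes in the extreme tails of the residual
distribution are reported as fast or slow diverging.  Lineage-specific
family expansions are detected from an ortholog-group copy-number table.

Amino-acid level distances are used throughout: at the divergence depths
involved, synonymous sites are saturated, so dN/dS-style statistics are
deliberately not offered.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from ._jtt_data import AA_ORDER, JTT_FREQUENCIES, JTT_LOWER_TRIANGLE

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class SubstitutionModel:
    """A time-reversible empirical amino-acid model (default JTT).

    The rate matrix is Q = S.diag(pi) with zeroed diagonal replaced so rows
    sum to 0, scaled so the expected substitution rate at stationarity is 1
    — branch lengths are then expected substitutions per site.  The
    symmetric parameterization pi^1/2 Q pi^-1/2 is eigendecomposed once,
    giving P(t) = exp(Qt) in a single matrix triple-product per t.
    """

    def __init__(
        self,
        exchangeabilities: Sequence[float] = JTT_LOWER_TRIANGLE,
        frequencies: Sequence[float] = JTT_FREQUENCIES,
        name: str = "JTT",
    ) -> None:
        self.name = name
        pi = np.asarray(frequencies, dtype=float)
        pi = pi / pi.sum()
        n = len(pi)
        S = np.zeros((n, n))
        k = 0
        for i in range(1, n):
            for j in range(i):
                S[i, j] = S[j, i] = exchangeabilities[k]
                k += 1
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        Q /= rate
        self.pi = pi
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        sym = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        sym = (sym + sym.T) / 2.0  # enforce symmetry against rounding
        self._eigval, self._eigvec = eigh(sym)
        self._left = self._eigvec / sqrt_pi[:, None]
        self._right = self._eigvec * sqrt_pi[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("t must be >= 0")
        return (self._left * np.exp(self._eigval * t)) @ self._right.T


DEFAULT_MODEL_CACHE: dict[str, SubstitutionModel] = {}


def jtt_model() -> SubstitutionModel:
    if "JTT" not in DEFAULT_MODEL_CACHE:
        DEFAULT_MODEL_CACHE["JTT"] = SubstitutionModel()
    return DEFAULT_MODEL_CACHE["JTT"]


class AlignmentError(ValueError):
    pass


def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences must be aligned to equal length")
    counts = np.zeros((20, 20))
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        ia = AA_INDEX.get(ca)
        ib = AA_INDEX.get(cb)
        if ia is None or ib is None:  # gap or ambiguous: pairwise deletion
            continue
        counts[ia, ib] += 1
    return counts


@dataclass(frozen=True)
class DistanceEstimate:
    t: float
    n_sites: int
    saturated: bool = False


def ml_pairwise_distance(
    seq_a: str,
    seq_b: str,
    model: SubstitutionModel | None = None,
    t_max: float = 10.0,
    min_sites: int = 10,
) -> DistanceEstimate:
    """ML distance between two aligned amino-acid sequences.

    Columns with a gap or ambiguity in either sequence are excluded
    (pairwise deletion).  The likelihood sum_ij c_ij log(pi_i P_ij(t)) is
    maximized by bounded 1-D optimization on [0, t_max]; estimates pinned
    at the cap are flagged saturated.  Identical sequences return exactly
    0; fewer than *min_sites* comparable columns is an error.
    """
    model = model or jtt_model()
    counts = _pair_counts(seq_a, seq_b)
    n_sites = int(counts.sum())
    if n_sites < min_sites:
        raise AlignmentError(
            f"only {n_sites} comparable columns (< {min_sites})"
        )
    if counts.trace() == n_sites:
        return DistanceEstimate(0.0, n_sites)
    log_pi = np.log(model.pi)

    def neg_loglik(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            logP = np.log(np.maximum(P, 1e-300))
        return -float(np.sum(counts * (log_pi[:, None] + logP)))

    res = minimize_scalar(
        neg_loglik, bounds=(1e-8, t_max), method="bounded",
        options={"xatol": 1e-8},
    )
    t_hat = float(res.x)
    saturated = t_hat > 0.999 * t_max
    return DistanceEstimate(min(t_hat, t_max), n_sites, saturated)


# ---------------------------------------------------------------------------
# Divergence ratios
# ---------------------------------------------------------------------------

CLADE_FOCAL = "focal"
CLADE_ANT = "ant"
CLADE_BEE = "bee"


@dataclass(frozen=True)
class DivergenceRatios:
    gene_id: str
    group: str
    an: float
    bn: float
    ab: float

    @property
    def denominator(self) -> float:
        return self.an + self.bn + self.ab

    @property
    def ratio(self) -> float:
        """Compound ratio R = (AN + BN) / (AN + BN + AB)."""
        return (self.an + self.bn) / self.denominator

    @property
    def ratio_ant(self) -> float:
        return self.an / self.denominator

    @property
    def ratio_bee(self) -> float:
        return self.bn / self.denominator


def divergence_ratios(
    alignment: Mapping[str, str],
    clade_labels: Mapping[str, str],
    model: SubstitutionModel | None = None,
    group: str = "",
    t_max: float = 10.0,
) -> list[DivergenceRatios]:
    """Clade-median divergence ratios for every focal gene of one group.

    Requires at least one focal, one ant and one bee sequence; AB is the
    median over all ant-vs-bee pairs and is computed once per group.
    Focal genes whose three medians are all zero have an undefined ratio
    and are skipped.
    """
    model = model or jtt_model()
    by_clade: dict[str, list[str]] = {}
    for gid in alignment:
        clade = clade_labels.get(gid)
        if clade not in (CLADE_FOCAL, CLADE_ANT, CLADE_BEE):
            raise ValueError(f"unknown clade for {gid}: {clade!r}")
        by_clade.setdefault(clade, []).append(gid)
    if not all(
        by_clade.get(c) for c in (CLADE_FOCAL, CLADE_ANT, CLADE_BEE)
    ):
        return []

    dist_cache: dict[tuple[str, str], float] = {}

    def dist(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in dist_cache:
            dist_cache[key] = ml_pairwise_distance(
                alignment[key[0]], alignment[key[1]], model, t_max
            ).t
        return dist_cache[key]

    ab = statistics.median(
        dist(a, b)
        for a in by_clade[CLADE_ANT]
        for b in by_clade[CLADE_BEE]
    )
    out = []
    for gid in sorted(by_clade[CLADE_FOCAL]):
        an = statistics.median(dist(gid, a) for a in by_clade[CLADE_ANT])
        bn = statistics.median(dist(gid, b) for b in by_clade[CLADE_BEE])
        dr = DivergenceRatios(gid, group, an, bn, ab)
        if dr.denominator == 0:
            continue
        out.append(dr)
    return out


# ---------------------------------------------------------------------------
# Residual regression
# ---------------------------------------------------------------------------


@dataclass
class ResidualFit:
    coefficients: dict[str, float]
    residuals: pd.Series
    group_effects: dict[str, float] = field(default_factory=dict)
    group_variance: float = 0.0


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def fit_residual_model(
    ratios: pd.Series,
    covariates: pd.DataFrame,
    groups: pd.Series,
    eps: float = 1e-6,
    singleton_fraction: float = 0.9,
) -> ResidualFit:
    """Regress logit-transformed divergence ratios on nuisance covariates
    with an ortholog-group effect, returning per-gene residuals.

    The group ("random") effect is a two-stage approximation to a mixed
    model: a method-of-moments variance partition shrinks group mean
    residuals toward zero before they are removed.  When at least
    *singleton_fraction* of groups hold a single gene — the typical case
    of one focal gene per group — the group effect is unidentifiable and
    the fit falls back to fixed effects only.  An exact mixed-model fitter
    can be substituted via the ``fitter`` hook on this module.
    """
    import statsmodels.api as sm

    if ratios.nunique() <= 1:
        raise ValueError("constant response; nothing to fit")
    y = _logit(np.clip(ratios.to_numpy(dtype=float), eps, 1.0 - eps))
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    fit = sm.OLS(y, X).fit()
    resid = pd.Series(fit.resid, index=ratios.index)

    counts = groups.groupby(groups).transform("size")
    frac_singleton = (groups.value_counts() == 1).mean()
    group_effects: dict[str, float] = {}
    group_var = 0.0
    if frac_singleton < singleton_fraction:
        # method-of-moments: between-group variance of group mean residuals
        gmeans = resid.groupby(groups).mean()
        gsizes = resid.groupby(groups).size()
        within = resid.groupby(groups).var(ddof=1).fillna(0.0)
        sigma_e = float(np.average(within, weights=np.maximum(gsizes - 1, 0)))
        var_means = float(gmeans.var(ddof=1))
        group_var = max(var_means - sigma_e / float(gsizes.mean()), 0.0)
        if group_var > 0:
            shrink = group_var / (group_var + sigma_e / gsizes)
            effects = gmeans * shrink
            group_effects = effects.to_dict()
            resid = resid - groups.map(effects).astype(float)
    resid = resid - resid.mean()
    coefs = dict(zip(X.columns, fit.params))
    return ResidualFit(coefs, resid, group_effects, group_var)


def select_divergent(
    residuals: pd.Series,
    mode: str = "compound",
    residuals_b: pd.Series | None = None,
    compound_pct: float = 95.0,
    intersection_pct: float = 80.0,
) -> tuple[set, set]:
    """Return (fast, slow) gene-id sets from regression residuals.

    ``compound`` mode takes genes strictly above the 95th / below the 5th
    percentile of one residual vector.  ``intersection`` mode applies the
    80/20 rule to two residual vectors (focal-vs-ant and focal-vs-bee
    models) and intersects the selections, trading recall for confidence.
    Percentiles are linear-interpolation empirical percentiles and the
    inequality is strict, so an all-ties vector selects nothing.
    """
    if len(residuals) < 20:
        raise ValueError("need at least 20 genes for percentile selection")
    if mode == "compound":
        hi = float(np.percentile(residuals, compound_pct))
        lo = float(np.percentile(residuals, 100.0 - compound_pct))
        fast = set(residuals.index[residuals > hi])
        slow = set(residuals.index[residuals < lo])
        return fast, slow
    if mode == "intersection":
        if residuals_b is None:
            raise ValueError("intersection mode needs two residual vectors")
        fast_sets, slow_sets = [], []
        for r in (residuals, residuals_b):
            hi = float(np.percentile(r, intersection_pct))
            lo = float(np.percentile(r, 100.0 - intersection_pct))
            fast_sets.append(set(r.index[r > hi]))
            slow_sets.append(set(r.index[r < lo]))
        return fast_sets[0] & fast_sets[1], slow_sets[0] & slow_sets[1]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Expansion detection
# ---------------------------------------------------------------------------

TAX_FOCAL = "focal"
TAX_OTHER_HYM = "other_hymenoptera"
TAX_OTHER_ARTH = "other_arthropod"


@dataclass(frozen=True)
class ExpansionCriteria:
    """Lineage-specific expansion rule: >= 2 focal copies, presence in
    > 80 % of the other arthropod species, and no duplicate (>= 2 copies)
    in any other hymenopteran."""

    min_focal_copies: int = 2
    min_arthropod_presence: float = 0.8
    max_other_hymenoptera_copies: int = 1


def detect_expansions(
    copy_table: pd.DataFrame,
    taxonomy: Mapping[str, str],
    criteria: ExpansionCriteria | None = None,
) -> list[str]:
    """Ortholog groups expanded specifically in the focal lineage.

    *copy_table*: groups x species copy counts (non-negative integers).
    *taxonomy* labels every species column as ``focal``,
    ``other_hymenoptera`` or ``other_arthropod``.
    """
    crit = criteria or ExpansionCriteria()
    focal_cols, hym_cols, arth_cols = [], [], []
    for sp in copy_table.columns:
        label = taxonomy.get(sp)
        if label == TAX_FOCAL:
            focal_cols.append(sp)
        elif label == TAX_OTHER_HYM:
            hym_cols.append(sp)
        elif label == TAX_OTHER_ARTH:
            arth_cols.append(sp)
        else:
            raise ValueError(f"unknown species label for {sp!r}")
    if (copy_table.to_numpy() < 0).any():
        raise ValueError("copy counts must be non-negative")
    expanded = []
    for group, row in copy_table.iterrows():
        focal = int(row[focal_cols].sum())
        if focal < crit.min_focal_copies:
            continue
        others = hym_cols + arth_cols
        if others:
            present = sum(1 for sp in others if row[sp] >= 1)
            if present / len(others) <= crit.min_arthropod_presence:
                continue
        if any(
            row[sp] > crit.max_other_hymenoptera_copies for sp in hym_cols
        ):
            continue
        expanded.append(group)
    return expanded
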