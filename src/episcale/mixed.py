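"""Trial-level inference: mixed linear models, AIC term selection,
collinearity diagnostics, causal mediation, and rank correlations.

All models are Gaussian linear mixed models with a random intercept per
participant, estimated by maximum likelihood (statsmodels ``MixedLM``).
Explanatory variables are chosen by forward selection on AIC; collinearity
among the selected fixed effects is checked with variance inflation
factors.  Mediation follows the product-of-coefficients / quasi-Bayesian
Monte Carlo approach: coefficient vectors are drawn from the asymptotic
normal of the mediator and outcome models, the average causal mediation
effect (ACME) per draw is the product of the treatment->mediator and
mediator->outcome coefficients, and percentile intervals over the draws
give the confidence bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .nulls import fdr_adjust

__all__ = ["ModelSpec", "ModelFit", "MediationResult", "fit_lmm",
           "stepwise_aic", "vif", "mediate", "spearman_matrix",
           "pooled_term_fdr"]


@dataclass
class ModelSpec:
    """Specification of one trial-level mixed model."""

    response: str
    candidate_terms: list[str]
    quadratic_terms: list[str] = field(default_factory=list)
    random_intercept: str = "participant"

    def __post_init__(self) -> None:
        if self.response in self.candidate_terms:
            raise ValueError("response variable cannot be a candidate term")


@dataclass
class ModelFit:
    """Fitted mixed model: estimates, diagnostics and the selection path."""

    response: str
    included_terms: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    aic: float
    vif: pd.Series
    n_obs: int
    n_groups: int
    n_dropped: int
    singular: bool = False
    selection_path: list[tuple[str, float]] = field(default_factory=list)
    fdr_q: pd.Series | None = None

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "coef": self.coefficients,
            "se": self.std_errors,
            "p": self.p_values,
        })
        out["vif"] = self.vif.reindex(out.index)
        if self.fdr_q is not None:
            out["q"] = self.fdr_q.reindex(out.index)
        return out


@dataclass
class MediationResult:
    """Quasi-Bayesian mediation estimate (indirect/direct effects)."""

    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    proportion_mediated: float
    n_draws: int
    assessed: bool = True
    reason: str = ""


def _design(table: pd.DataFrame, terms: list[str],
            quadratic: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    X["Intercept"] = 1.0
    for term in terms:
        X[term] = pd.to_numeric(table[term], errors="coerce")
        if term in quadratic:
            X[term + "^2"] = X[term] ** 2
    return X


def fit_lmm(table: pd.DataFrame, response: str, terms: list[str],
            group: str = "participant",
            quadratic: list[str] | None = None) -> ModelFit:
    """Fit a random-intercept linear mixed model by maximum likelihood.

    Rows with missing values in the used columns are dropped (the count is
    reported in ``n_dropped``), never silently imputed.  A singular or
    boundary fit is flagged, not hidden.
    """
    quadratic = quadratic or []
    cols = [response] + list(terms)
    sub = table[cols + [group]].apply(
        lambda c: pd.to_numeric(c, errors="coerce") if c.name != group else c)
    mask = sub[cols].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    sub = sub[mask]
    if sub[group].nunique() < 2:
        raise ValueError("need at least two groups for a random intercept")
    X = _design(sub, list(terms), quadratic)
    y = sub[response].to_numpy(dtype=float)

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X.to_numpy(), groups=sub[group].to_numpy())
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell")
        if getattr(res, "converged", True) is False:
            singular = True
        # boundary variance estimate counts as singular
        if float(np.asarray(res.cov_re)[0, 0]) < 1e-10:
            singular = True

    names = list(X.columns)
    k_fe = len(names)
    # free parameters: fixed effects + random-intercept variance + residual
    aic = float(-2.0 * res.llf + 2.0 * (k_fe + 2))
    coefs = pd.Series(res.fe_params, index=names)
    ses = pd.Series(res.bse_fe, index=names)
    pvals = pd.Series(
        2.0 * stats.norm.sf(np.abs(coefs / ses)), index=names)
    fit_terms = [n for n in names if n != "Intercept"]
    vifs = vif(X[fit_terms]) if len(fit_terms) >= 2 else pd.Series(
        1.0, index=fit_terms)
    fit = ModelFit(
        response=response, included_terms=fit_terms,
        coefficients=coefs, std_errors=ses, p_values=pvals, aic=aic,
        vif=vifs, n_obs=len(sub), n_groups=int(sub[group].nunique()),
        n_dropped=n_dropped, singular=singular)
    fit._result = res  # stash for mediation draws
    return fit


def stepwise_aic(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Forward AIC selection of fixed effects for a random-intercept model.

    Starting from the intercept-only model, at each step the candidate whose
    inclusion most improves (lowers) the AIC is added; selection stops when
    no candidate improves it.  Quadratic companions listed in
    ``spec.quadratic_terms`` enter together with their linear term.  The
    selection path (term, AIC after adding) is logged on the returned fit.
    """
    included: list[str] = []
    path: list[tuple[str, float]] = []
    current = fit_lmm(table, spec.response, included, spec.random_intercept)
    best_aic = current.aic
    remaining = list(spec.candidate_terms)
    while remaining:
        trials = []
        for term in remaining:
            try:
                cand = fit_lmm(table, spec.response, included + [term],
                               spec.random_intercept,
                               quadratic=[t for t in spec.quadratic_terms
                                          if t in included + [term]])
            except (ValueError, np.linalg.LinAlgError):
                continue
            trials.append((cand.aic, term, cand))
        if not trials:
            break
        trials.sort(key=lambda x: x[0])
        aic, term, cand = trials[0]
        if aic >= best_aic - 1e-9:
            break
        included.append(term)
        remaining.remove(term)
        best_aic = aic
        current = cand
        path.append((term, aic))
    current.selection_path = path
    return current


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per column of a design frame."""
    X = X.astype(float)
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0 or np.allclose(X[col].var(), 0):
            out[col] = 1.0
            continue
        r2 = sm.OLS(X[col], sm.add_constant(others)).fit().rsquared
        out[col] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out)


def _draw_fe(fit: ModelFit, n_draws: int, rng: np.random.Generator) -> pd.DataFrame:
    res = fit._result
    names = list(fit.coefficients.index)
    k = len(names)
    mean = np.asarray(res.fe_params, dtype=float)
    cov = np.asarray(res.cov_params())[:k, :k]
    draws = rng.multivariate_normal(mean, cov, size=n_draws,
                                    method="svd")
    return pd.DataFrame(draws, columns=names)


def mediate(table: pd.DataFrame, treatment: str, mediator: str, outcome: str,
            n_draws: int = 5000, seed=None, group: str = "participant",
            alpha_gate: float = 0.05) -> MediationResult:
    """Quasi-Bayesian causal mediation through random-intercept mixed models.

    Fits the mediator model (mediator ~ treatment) and the outcome model
    (outcome ~ treatment + mediator); mediation is only assessed when the
    treatment->mediator and mediator->outcome coefficients are both
    significant at ``alpha_gate``.  ACME draws are products of coefficient
    draws a*b; ADE draws are the direct-effect draws c'; 95% intervals are
    percentile intervals over ``n_draws``.
    """
    rng = np.random.default_rng(seed)
    m2 = fit_lmm(table, mediator, [treatment], group)
    m3 = fit_lmm(table, outcome, [treatment, mediator], group)
    gate_ok = (m2.p_values[treatment] < alpha_gate
               and m3.p_values[mediator] < alpha_gate)
    a_draws = _draw_fe(m2, n_draws, rng)[treatment].to_numpy()
    out_draws = _draw_fe(m3, n_draws, rng)
    b_draws = out_draws[mediator].to_numpy()
    c_draws = out_draws[treatment].to_numpy()
    acme = a_draws * b_draws
    total = acme + c_draws
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(total != 0, acme / total, np.nan)
    lo, hi = np.percentile(acme, [2.5, 97.5])
    dlo, dhi = np.percentile(c_draws, [2.5, 97.5])
    return MediationResult(
        acme=float(np.mean(acme)), acme_ci=(float(lo), float(hi)),
        ade=float(np.mean(c_draws)), ade_ci=(float(dlo), float(dhi)),
        proportion_mediated=float(np.nanmedian(prop)),
        n_draws=n_draws, assessed=bool(gate_ok),
        reason="" if gate_ok else "gating models not significant")


def spearman_matrix(participant_means: pd.DataFrame,
                    columns: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho on per-participant averages, with BH-FDR q.

    Returns (rho matrix, q matrix); the diagonal q is NaN.
    """
    cols = columns or [c for c in participant_means.columns
                       if pd.api.types.is_numeric_dtype(participant_means[c])]
    data = participant_means[cols].astype(float)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    ps, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            sub = data[[cols[i], cols[j]]].dropna()
            r, p = stats.spearmanr(sub[cols[i]], sub[cols[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            ps.append(p)
            pairs.append((i, j))
    if ps:
        qs = fdr_adjust(ps)
        for (i, j), q in zip(pairs, qs):
            pmat.iloc[i, j] = pmat.iloc[j, i] = q
    return rho, pmat


def pooled_term_fdr(fits: list[ModelFit]) -> list[ModelFit]:
    """BH-FDR across all fixed-effect p-values of all models (one family)."""
    keys, ps = [], []
    for fi, fit in enumerate(fits):
        for term in fit.included_terms:
            keys.append((fi, term))
            ps.append(fit.p_values[term])
    if not ps:
        return fits
    qs = fdr_adjust(ps)
    for fit in fits:
        fit.fdr_q = pd.Series(np.nan, index=fit.coefficients.index)
    for (fi, term), q in zip(keys, qs):
        fits[fi].fdr_q[term] = q
    return fits
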