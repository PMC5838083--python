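"""Binomial additive mixed habitat model and the replicate ensemble.

The probability that a position is an observed presence rather than a CRW
pseudoabsence is modelled on the logit scale as a sum of penalized
cubic B-spline smooths of the environmental covariates plus an
individual-level random intercept, realized as a ridge-penalized group
indicator term (identity penalty), which is the classical random-intercept
shrinkage estimator. Smoothing weights, including the group ridge weight,
are chosen by the fitter's penalty-weight selection (AIC-based).

To avoid pseudoreplication only one trip per individual enters a model fit
(the trip with the most daily locations) paired with one randomly selected
retained CRW, giving a 1:1 presence:pseudoabsence design. The final model
is refit many times (default 40) with the CRW re-drawn per trip to tally
how often each covariate is significant at p < .001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.gam.smooth_basis import (GenericSmoothers,
                                          UnivariateGenericSmoother)

logger = logging.getLogger(__name__)

DEFAULT_BASIS_DF = 4
DEFAULT_ALPHA_SIG = 0.001

#: covariate set of the reference best model plus its main competitor
DEFAULT_MODEL_COVARIATES = ["sst", "chl", "eke", "sla", "sla_sd", "bathymetry"]
DISTANCE_COMPETITOR_COVARIATES = ["sst", "chl", "eke", "sla", "sla_sd",
                                  "dist_colony"]


@dataclass
class ModelSpec:
    """Specification of one candidate binomial additive mixed model."""

    covariates: list[str]
    basis_df: int = DEFAULT_BASIS_DF
    group_col: str = "animal_id"
    shrink: float = 0.0   # >0 adds a term-selection ridge (double penalty)
    name: str = ""

    def __post_init__(self):
        if self.basis_df < 3:
            raise ValueError("basis dimension must be >= 3")
        if not self.name:
            self.name = "+".join(self.covariates)


@dataclass
class SmoothSummary:
    covariate: str
    edf: float
    chi_sq: float
    p_value: float


@dataclass
class FitResult:
    spec: ModelSpec
    smooths: list[SmoothSummary]
    aic: float
    auc: float
    deviance_explained: float
    random_intercept_var: float
    partial_responses: dict  # covariate -> DataFrame(x, fit, se)
    n_obs: int
    alphas: list[float] = field(default_factory=list)
    fitted: np.ndarray = None  # in-sample probabilities incl. group effects
    # internals needed for prediction
    _params: np.ndarray = None
    _cov_params: np.ndarray = None
    _smoother: object = None
    _cov_ranges: dict = None
    _n_groups: int = 0

    def linear_predictor(self, newdata: pd.DataFrame) -> np.ndarray:
        """Population-level eta (group effect at its mean, i.e. zero)."""
        cols = [np.ones((len(newdata), 1))]
        for i, cov in enumerate(self.spec.covariates):
            x = newdata[cov].to_numpy(float)
            lo, hi = self._cov_ranges[cov]
            x = np.clip(x, lo, hi)
            cols.append(self._smoother.smoothers[i].transform(x))
        basis = np.column_stack(cols)
        k = basis.shape[1]
        return basis @ self._params[:k]

    def predict_probability(self, newdata: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(newdata))


@dataclass
class EnsembleResult:
    n_runs: int
    alpha: float
    n_significant: dict        # covariate -> count
    edf: dict                  # covariate -> (mean, min, max)
    chi_sq: dict               # covariate -> (mean, min, max)
    aic: tuple
    auc: tuple
    deviance_explained: tuple

    def report(self) -> str:
        """Plain-text model card in the mean (min-max) layout."""
        lines = [f"Ensemble of {self.n_runs} refits, significance at "
                 f"p < {self.alpha}",
                 f"{'Variable':<14}{'edf':<18}{'Chi-squared':<22}"
                 f"n-significant (n/{self.n_runs})"]
        for cov in self.n_significant:
            e = self.edf[cov]
            c = self.chi_sq[cov]
            lines.append(f"{cov:<14}{e[0]:.1f} ({e[1]:.1f}-{e[2]:.1f})"
                         f"{'':<6}{c[0]:.1f} ({c[1]:.1f}-{c[2]:.1f})"
                         f"{'':<6}{self.n_significant[cov]}")
        d = self.deviance_explained
        lines.append(f"Deviance explained = {d[0]:.2f} ({d[1]:.2f}-{d[2]:.2f})")
        lines.append(f"AIC = {self.aic[0]:.2f} ({self.aic[1]:.2f}-{self.aic[2]:.2f})")
        lines.append(f"AUC = {self.auc[0]:.2f} ({self.auc[1]:.2f}-{self.auc[2]:.2f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _pick_trip(rows: pd.DataFrame) -> str:
    """Trip with most daily locations; ties broken by duration then trip id."""
    pres = rows[rows["source"] == "presence"]
    stats = pres.groupby("trip_id").agg(
        n=("date", "size"),
        dur=("date", lambda d: (d.max() - d.min()).days))
    stats = stats.sort_values(["n", "dur", "trip_id"],
                              ascending=[False, False, True],
                              kind="stable")
    return stats.index[0]


def assemble_dataset(matchups: pd.DataFrame,
                     seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """One trip per individual, one CRW per trip, 1:1 class balance.

    ``matchups`` is the transformed matchup table with presence rows and
    pseudoabsence rows for every retained CRW (distinguished by sim_id).
    The per-trip pseudoabsence is drawn uniformly among that trip's
    available sim_ids; any residual class imbalance from matchup
    exclusions is removed by seeded downsampling of the larger class.
    """
    if matchups["animal_id"].nunique() < 2:
        raise ValueError("need at least 2 individuals with complete trips")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    parts = []
    animals = sorted(matchups["animal_id"].unique())
    children = ss.spawn(len(animals))
    for animal, child in zip(animals, children):
        rng = np.random.default_rng(child)
        rows = matchups[matchups["animal_id"] == animal]
        if not (rows["source"] == "presence").any():
            continue
        trip = _pick_trip(rows)
        trows = rows[rows["trip_id"] == trip]
        pres = trows[trows["source"] == "presence"]
        absn = trows[trows["source"] == "pseudoabsence"]
        if absn.empty:
            logger.warning("individual %s has no retained CRW records; excluded",
                           animal)
            continue
        # one CRW per trip covering both the outgoing and the return phase
        sim_ids = sorted(absn["sim_id"].unique())
        chosen = []
        for prefix in ("o", "i"):
            ids = [s for s in sim_ids if str(s).startswith(prefix)]
            if ids:
                chosen.append(ids[int(rng.integers(0, len(ids)))])
        if not chosen:  # unprefixed sim ids: draw one
            chosen = [sim_ids[int(rng.integers(0, len(sim_ids)))]]
        absn = absn[absn["sim_id"].isin(chosen)]
        n = min(len(pres), len(absn))
        if len(pres) > n:
            pres = pres.iloc[np.sort(rng.choice(len(pres), n, replace=False))]
        if len(absn) > n:
            absn = absn.iloc[np.sort(rng.choice(len(absn), n, replace=False))]
        parts.append(pres)
        parts.append(absn)
    if not parts:
        raise ValueError("no individuals left after assembly")
    out = pd.concat(parts, ignore_index=True)
    out["presence"] = (out["source"] == "presence").astype(int)
    return out


# ---------------------------------------------------------------------------
# Multicollinearity screening
# ---------------------------------------------------------------------------

def gvif_check(table: pd.DataFrame, covariates: list[str],
               threshold: float = 2.0) -> pd.DataFrame:
    """Generalized variance inflation factors from the linear design.

    For 1-df terms GVIF is the classical VIF (diagonal of the inverse
    correlation matrix); terms with GVIF^(1/(2 df)) > threshold are
    flagged. Raises on a rank-deficient design, naming aliased covariates.
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 covariates")
    X = table[covariates].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = np.corrcoef(X, rowvar=False)
    if np.linalg.matrix_rank(R, tol=1e-10) < len(covariates):
        aliased = []
        for j, cov in enumerate(covariates):
            others = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            if np.var(resid) < 1e-10:
                aliased.append(cov)
        raise ValueError(f"rank-deficient design; aliased covariates: {aliased}")
    detR = np.linalg.det(R)
    rows = []
    for j, cov in enumerate(covariates):
        keep = [k for k in range(len(covariates)) if k != j]
        gvif = (np.linalg.det(R[np.ix_(keep, keep)]) * np.linalg.det(R[np.ix_([j], [j])])
                / detR)
        df = 1
        crit = gvif ** (1.0 / (2 * df))
        rows.append({"covariate": cov, "gvif": float(gvif), "df": df,
                     "gvif_scaled": float(crit),
                     "flagged": bool(crit > threshold)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _build_smoother(table: pd.DataFrame, spec: ModelSpec):
    """B-spline smooths for the covariates plus the group ridge term.

    With ``spec.shrink > 0`` each curvature penalty is augmented with a
    small ridge (``shrink`` times its mean diagonal), so that a large
    penalty weight can shrink a term entirely to zero rather than only to
    a straight line — the double-penalty device used for term selection in
    additive models. The default keeps the linear null space unpenalized.
    """
    x = table[spec.covariates].to_numpy(float)
    bs = BSplines(x, df=[spec.basis_df] * len(spec.covariates),
                  degree=[3] * len(spec.covariates),
                  variable_names=spec.covariates)
    if spec.shrink > 0:
        for s in bs.smoothers:
            p = s.cov_der2
            s.cov_der2 = p + spec.shrink * (np.trace(p) / p.shape[0]) * np.eye(p.shape[0])
    groups, uniq = pd.factorize(table[spec.group_col], sort=True)
    Z = np.zeros((len(table), len(uniq)))
    Z[np.arange(len(table)), groups] = 1.0
    grp = UnivariateGenericSmoother(groups.astype(float), Z, np.zeros_like(Z),
                                    np.zeros_like(Z), np.eye(len(uniq)),
                                    spec.group_col)
    allx = np.column_stack([x, groups.astype(float)])
    return GenericSmoothers(allx, list(bs.smoothers) + [grp]), len(uniq)


def roc_auc(labels, scores) -> float:
    """ROC AUC via the Mann-Whitney U normalization (ties count half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def fit_binomial_gamm(table: pd.DataFrame, spec: ModelSpec,
                      alphas: list[float] | None = None,
                      response_col: str = "presence") -> FitResult:
    """Fit the binomial logit additive model with a group ridge intercept.

    Penalty weights (one per smooth plus one for the group term) are
    selected by the fitter when not supplied. Reports per-smooth effective
    degrees of freedom, Wald chi-square and p-value, AIC, in-sample AUC,
    deviance explained, partial-response curves and the empirical variance
    of the fitted group effects.
    """
    y = table[response_col].to_numpy(float)
    smoother, n_groups = _build_smoother(table, spec)
    k_terms = len(spec.covariates)
    exog = np.ones((len(table), 1))

    def _fit_with(alpha_list):
        m = GLMGam(y, exog=exog, smoother=smoother, alpha=list(alpha_list),
                   family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return m, m.fit()

    default_alphas = [1.0] * (k_terms + 1)
    if alphas is None:
        probe, base_res = _fit_with(default_alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cand = np.atleast_1d(probe.select_penweight(
                    method="nm", maxiter=500, maxfun=500, disp=False)[0])
                # smoothing floor: selection may stiffen a term but not
                # remove smoothing entirely (guards against boundary wiggle
                # at modest sample sizes); the group ridge is unrestricted
                cand[:-1] = np.clip(cand[:-1], 3.0, 1e8)
                cand[-1] = np.clip(cand[-1], 1e-3, 1e8)
                _, cand_res = _fit_with(cand)
                # the search can land in a degenerate optimum; keep the
                # better fit under the selection criterion itself
                cand_aic = cand_res.aic if np.isfinite(cand_res.aic) else np.inf
                base_aic = base_res.aic if np.isfinite(base_res.aic) else np.inf
                if (np.all(np.isfinite(cand_res.params))
                        and cand_aic <= base_aic):
                    alphas = list(cand)
                else:
                    alphas = default_alphas
            except Exception:  # noqa: BLE001 - selection is best-effort
                alphas = default_alphas
    model, res = _fit_with(alphas)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("model failed to converge: non-finite coefficients")
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        logger.warning("possible separation: fitted probabilities at the boundary")

    # per-term summaries; edf blocks follow [intercept, smooth bases..., group].
    # edf is computed directly from the penalized normal equations,
    # diag((X'WX + S)^-1 X'WX), which stays stable when a term's penalty
    # weight sits at the search boundary.
    mu = np.clip(fitted, 1e-10, 1 - 1e-10)
    w = mu * (1.0 - mu)
    X = np.column_stack([exog, smoother.basis])
    XtWX = X.T @ (X * w[:, None])
    S = model.penal.penalty_matrix(alpha=model.alpha)
    try:
        F = np.linalg.solve(XtWX + S, XtWX)
    except np.linalg.LinAlgError:
        F = np.linalg.pinv(XtWX + S) @ XtWX
    edf = np.clip(np.diag(F), 0.0, 1.0)
    sizes = [1] + [s.dim_basis for s in smoother.smoothers]
    starts = np.cumsum([0] + sizes)
    smooths = []
    for i, cov in enumerate(spec.covariates):
        blk = slice(starts[i + 1], starts[i + 2])
        term_edf = float(edf[blk].sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = res.test_significance(i)
        chi = float(np.squeeze(t.statistic))
        pval = float(np.squeeze(t.pvalue))
        if term_edf < 0.01 or chi < 1e-8:
            # term shrunk (essentially) to zero: the Wald reference
            # distribution degenerates, and the term is non-significant
            pval = 1.0
        smooths.append(SmoothSummary(covariate=cov, edf=term_edf,
                                     chi_sq=chi, p_value=pval))
    grp_params = res.params[starts[-2]:starts[-1]]
    ri_var = float(np.var(grp_params - grp_params.mean(), ddof=0))

    # deviance and AIC from clipped probabilities: the raw log-likelihood is
    # NaN under (near-)separation, while the clipped deviance stays finite.
    # AIC uses the conditional-GAM form, deviance + 2 * total edf.
    dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    p0 = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    dev_null = -2.0 * float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
    aic = dev + 2.0 * float(edf.sum())
    dev_expl = 1.0 - dev / dev_null
    auc = roc_auc(y, fitted)

    cov_ranges = {}
    partials = {}
    covp = np.asarray(res.cov_params())
    for i, cov in enumerate(spec.covariates):
        xv = table[cov].to_numpy(float)
        cov_ranges[cov] = (float(xv.min()), float(xv.max()))
        grid = np.linspace(xv.min(), xv.max(), 100)
        B = smoother.smoothers[i].transform(grid)
        blk = slice(starts[i + 1], starts[i + 2])
        contrib = B @ res.params[blk]
        contrib = contrib - contrib.mean()
        se = np.sqrt(np.einsum("ij,jk,ik->i", B, covp[blk, blk], B))
        partials[cov] = pd.DataFrame({"x": grid, "fit": contrib, "se": se})

    return FitResult(spec=spec, smooths=smooths, aic=float(aic), auc=auc,
                     deviance_explained=float(dev_expl),
                     random_intercept_var=ri_var,
                     partial_responses=partials, n_obs=len(table),
                     alphas=[float(a) for a in alphas], fitted=fitted,
                     _params=np.asarray(res.params),
                     _cov_params=covp, _smoother=smoother,
                     _cov_ranges=cov_ranges, _n_groups=n_groups)


# ---------------------------------------------------------------------------
# Selection and ensemble
# ---------------------------------------------------------------------------

def select_model(candidates: list[ModelSpec], table: pd.DataFrame
                 ) -> tuple[ModelSpec, pd.DataFrame]:
    """Rank candidates by AIC (ascending); log if the AUC ranking disagrees."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    rows = []
    for spec in candidates:
        fit = fit_binomial_gamm(table, spec)
        rows.append({"name": spec.name, "aic": fit.aic, "auc": fit.auc,
                     "spec": spec})
    ranking = pd.DataFrame(rows)
    ranking = ranking.sort_values("aic", kind="stable").reset_index(drop=True)
    best = ranking.iloc[0]
    auc_best = ranking.loc[ranking["auc"].idxmax()]
    if auc_best["name"] != best["name"]:
        logger.warning("AIC-best model (%s) is not AUC-best (%s); choosing by AIC",
                       best["name"], auc_best["name"])
    return best["spec"], ranking.drop(columns="spec")


def run_ensemble(spec: ModelSpec, matchups: pd.DataFrame, n_runs: int = 40,
                 alpha: float = DEFAULT_ALPHA_SIG, seed: int = 0,
                 reuse_penalties: bool = True) -> EnsembleResult:
    """Refit the model ``n_runs`` times with the CRW re-drawn per trip.

    Tallies how often each covariate is significant at ``alpha`` and the
    mean (min-max) of edf, chi-square, AIC, AUC and deviance explained.
    Penalty weights are selected on the first run and reused by default.
    """
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(n_runs)
    alphas = None
    per_cov: dict[str, dict] = {c: {"sig": 0, "edf": [], "chi": []}
                                for c in spec.covariates}
    aics, aucs, devs = [], [], []
    failures = 0
    for r in range(n_runs):
        try:
            table = assemble_dataset(matchups, seed=run_seeds[r])
            fit = fit_binomial_gamm(table, spec, alphas=alphas)
            if reuse_penalties and alphas is None:
                alphas = fit.alphas
        except Exception as exc:  # noqa: BLE001 - tallied and bounded below
            logger.warning("ensemble run %d failed: %s", r, exc)
            failures += 1
            continue
        for smo in fit.smooths:
            d = per_cov[smo.covariate]
            d["sig"] += int(smo.p_value < alpha)
            d["edf"].append(smo.edf)
            d["chi"].append(smo.chi_sq)
        aics.append(fit.aic)
        aucs.append(fit.auc)
        devs.append(fit.deviance_explained)
    if failures > 0.1 * n_runs:
        raise RuntimeError(f"{failures}/{n_runs} ensemble runs failed")

    def agg(v):
        v = np.asarray(v, dtype=float)
        return (float(v.mean()), float(v.min()), float(v.max()))

    return EnsembleResult(
        n_runs=n_runs - failures, alpha=alpha,
        n_significant={c: per_cov[c]["sig"] for c in spec.covariates},
        edf={c: agg(per_cov[c]["edf"]) for c in spec.covariates},
        chi_sq={c: agg(per_cov[c]["chi"]) for c in spec.covariates},
        aic=agg(aics), auc=agg(aucs), deviance_explained=agg(devs))
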