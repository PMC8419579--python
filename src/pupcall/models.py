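"""Mixed-model inference on match outcomes and similarity scores.

Two models mirror the study's analysis:

* a binomial (logistic) mixed-effects regression of the call-level match
  indicator on age, playback condition and their interaction, with a
  random intercept per pup to absorb repeated sampling of each animal; and
* a Gaussian linear mixed model of the per pup x age-bin Mantel r on the
  ordinal age bin, condition, sex and the age x condition interaction,
  again with a pup random intercept.

The logistic model is fit by maximum likelihood with the random intercept
integrated out by Gauss-Hermite quadrature; the Gaussian model uses
statsmodels' MixedLM (REML). Reported estimates are exponentiated, as in
the study's tables, with Wald confidence intervals on the link scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess

GLMM_TERMS = (
    "intercept",
    "age",
    "condition_feed",
    "condition_varied",
    "age_x_feed",
    "age_x_varied",
)


@dataclass
class MixedFit:
    """A fitted mixed model in the study's reporting shape.

    ``params`` has one row per fixed-effect term with columns
    (term, coef, estimate, ci_low, ci_high, p); ``estimate`` and the CI
    columns are exponentiated (odds ratios for the logistic model).
    """

    params: pd.DataFrame
    random_intercept_sd: float
    loglik: float
    n_obs: int
    n_groups: int
    model: str
    converged: bool = True

    def coef(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "coef"])

    def odds_ratio(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])


GlmmFit = MixedFit
LmmFit = MixedFit


def _glmm_design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    required = {"pup_id", "condition", "is_match"}
    if not required <= set(table.columns):
        raise ValueError(f"match table needs columns {sorted(required)} and an age column")
    age_col = "age" if "age" in table.columns else "age_days"
    if age_col not in table.columns:
        raise ValueError("match table needs an 'age' or 'age_days' column")
    age = table[age_col].to_numpy(float)
    feed = (table["condition"] == "feeding").to_numpy(float)
    varied = (table["condition"] == "varied").to_numpy(float)
    X = np.column_stack(
        [np.ones(len(table)), age, feed, varied, age * feed, age * varied]
    )
    y = table["is_match"].to_numpy(float)
    groups = pd.factorize(table["pup_id"])[0]
    return X, y, groups


def _gh_negloglik(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_slices: list[np.ndarray],
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    beta, log_sd = theta[:-1], theta[-1]
    sd = np.exp(log_sd)
    eta0 = X @ beta
    total = 0.0
    b = np.sqrt(2.0) * sd * nodes  # quadrature points on the intercept scale
    logw = np.log(weights / np.sqrt(np.pi))
    for idx in group_slices:
        eta = eta0[idx][:, None] + b[None, :]
        # Bernoulli log-likelihood, numerically stable form
        ll = y[idx][:, None] * eta - np.logaddexp(0.0, eta)
        total += np.logaddexp.reduce(ll.sum(axis=0) + logw)
    return -total


def fit_match_glmm(
    table: pd.DataFrame,
    n_quad: int = 25,
    max_abs_coef: float = 15.0,
) -> MixedFit:
    """Fit the logistic random-intercept model of call-level matches.

    Fixed effects: age (continuous), condition (reference control) and
    their interaction; random intercept per pup, integrated out with
    ``n_quad``-node Gauss-Hermite quadrature. Raises ``ValueError`` on
    inestimable designs (single pup, one outcome class, or apparent
    complete separation).
    """
    X, y, groups = _glmm_design(table)
    n_groups = int(groups.max()) + 1
    per_cond = table.groupby("condition")["pup_id"].nunique()
    if n_groups < 2:
        raise ValueError("random intercept inestimable with a single pup")
    if per_cond.min() < 2 or len(per_cond) < 2:
        raise ValueError("need at least 2 pups in each of at least 2 conditions")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    group_slices = [np.flatnonzero(groups == g) for g in range(n_groups)]
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    # pooled logistic start values
    start = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    theta0 = np.concatenate([start.params, [np.log(0.5)]])

    res = optimize.minimize(
        _gh_negloglik,
        theta0,
        args=(X, y, group_slices, nodes, weights),
        method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    beta, log_sd = res.x[:-1], res.x[-1]
    if np.any(np.abs(beta) > max_abs_coef):
        raise ValueError(
            "apparent complete separation: a coefficient diverged "
            f"(|beta| > {max_abs_coef}); the fit was aborted"
        )
    hess = approx_hess(res.x, _gh_negloglik, args=(X, y, group_slices, nodes, weights))
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    lo = beta - 1.959963984540054 * se
    hi = beta + 1.959963984540054 * se
    params = pd.DataFrame(
        {
            "term": GLMM_TERMS,
            "coef": beta,
            "estimate": np.exp(beta),
            "ci_low": np.exp(lo),
            "ci_high": np.exp(hi),
            "p": p,
        }
    )
    return MixedFit(
        params=params,
        random_intercept_sd=float(np.exp(log_sd)),
        loglik=float(-res.fun),
        n_obs=len(y),
        n_groups=n_groups,
        model="binomial-glmm",
        converged=bool(res.success),
    )


def fit_similarity_lmm(mantel_rows: pd.DataFrame) -> MixedFit:
    """Fit the Gaussian mixed model of Mantel r.

    ``mantel_rows`` needs columns (pup_id, sex, age_bin, condition, r);
    age enters as the ordinal bin code 0-3, condition with reference
    control, plus sex and the age x condition interaction; random
    intercept per pup (REML). Estimates are exponentiated for reporting
    parity with the study's table; on a Gaussian response this is a
    presentation convention, not an odds ratio.
    """
    required = {"pup_id", "sex", "age_bin", "condition", "r"}
    if not required <= set(mantel_rows.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if len(mantel_rows) < 3:
        raise ValueError("need at least 3 observations")
    if mantel_rows["pup_id"].nunique() < 2:
        raise ValueError("need at least 2 pups")
    if mantel_rows["age_bin"].nunique() < 2:
        raise ValueError("need at least 2 age bins")
    if np.isclose(mantel_rows["r"].std(ddof=0), 0.0):
        raise ValueError("all r values equal: model degenerate")
    df = mantel_rows.copy()
    df["age_bin"] = df["age_bin"].astype(float)
    df["feed"] = (df["condition"] == "feeding").astype(float)
    df["varied"] = (df["condition"] == "varied").astype(float)
    df["sex_m"] = (df["sex"] == "M").astype(float)
    exog_cols = ["age_bin", "feed", "varied", "age_x_feed", "age_x_varied", "sex_m"]
    df["age_x_feed"] = df["age_bin"] * df["feed"]
    df["age_x_varied"] = df["age_bin"] * df["varied"]
    exog = sm.add_constant(df[exog_cols])
    model = sm.MixedLM(df["r"], exog, groups=df["pup_id"])
    fit = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with np.errstate(all="ignore"):
                fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue  # boundary variance can upset gradient-based methods
    if fit is None:
        raise ValueError("similarity LMM failed to converge")
    terms = [
        "intercept",
        "age",
        "condition_feed",
        "condition_varied",
        "age_x_feed",
        "age_x_varied",
        "sex_m",
    ]
    k = len(terms)
    beta = fit.fe_params.to_numpy()[:k]
    se = fit.bse_fe.to_numpy()[:k]
    lo = beta - 1.959963984540054 * se
    hi = beta + 1.959963984540054 * se
    p = 2 * stats.norm.sf(np.abs(beta / se))
    params = pd.DataFrame(
        {
            "term": terms,
            "coef": beta,
            "estimate": np.exp(beta),
            "ci_low": np.exp(lo),
            "ci_high": np.exp(hi),
            "p": p,
        }
    )
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    return MixedFit(
        params=params,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        loglik=float(fit.llf),
        n_obs=len(df),
        n_groups=int(df["pup_id"].nunique()),
        model="gaussian-lmm",
        converged=bool(fit.converged),
    )


def summarize_fits(
    glmm: MixedFit | None = None, lmm: MixedFit | None = None
) -> dict[str, pd.DataFrame]:
    """Report tables shaped like the study's results tables.

    Returns a dict with keys ``match_model`` and/or ``similarity_model``;
    each value has columns (variable, estimate, ci_2.5, ci_97.5, p).
    """
    out: dict[str, pd.DataFrame] = {}
    for key, fit in (("match_model", glmm), ("similarity_model", lmm)):
        if fit is None:
            continue
        if not fit.converged:
            warnings_col = " (fit did not converge)"
        else:
            warnings_col = ""
        tab = fit.params.rename(
            columns={
                "term": "variable",
                "ci_low": "ci_2.5",
                "ci_high": "ci_97.5",
            }
        )[["variable", "estimate", "ci_2.5", "ci_97.5", "p"]].copy()
        tab.attrs["note"] = fit.model + warnings_col
        out[key] = tab
    return out
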