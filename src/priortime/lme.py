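"""Central-tendency slopes and the linear mixed-effects model ladder.

Central tendency — the pull of reproduced intervals toward the mean of the
prevailing stimulus distribution — is quantified as 1 minus the slope of
production on sample.  A ladder of Gaussian linear mixed models (random
intercept and random Sample slope per subject, unstructured 2x2 covariance,
maximum likelihood) tests how that slope is modulated by:

* the prior's mean interval ("length": dummies for medium and long vs the
  short reference) and range ("width": wide vs narrow) — the effects of
  interest are the Length x Sample and Width x Sample interactions;
* nonstationarity covariates: a session-start indicator, first-block
  indicators after length and width condition transitions, and a running
  global mean of preceding samples;
* per-subject traits: sensory resolution (WF, estimated from the
  categorization task) and hallucination proneness (CAPS), entering as
  three-way interactions with Length/Width x Sample.

Models along the ladder (levels 1-8) add nonstationarity terms cumulatively
— main effects first (Start; the three transition indicators; GlobalMean),
then their Sample interactions — ending at the full model
``Response ~ 1 + Sample*(Length + Width + Start + LengthTransition +
WidthTransitionNtoW + WidthTransitionWtoN) + GlobalMean``.  Nested models
are compared by AIC, BIC and likelihood-ratio tests, with a winner declared
only on consensus of all three.  Fixed-effect t statistics use Satterthwaite
degrees of freedom computed by numerical differentiation of the contrast
variance with respect to the variance components, falling back to the
residual df (n - p) when the variance-component information matrix is not
usable; the method actually used is recorded per coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "SlopeSummary",
    "DesignSpec",
    "LMEFit",
    "ModelComparison",
    "condition_slopes",
    "build_design",
    "fit_lme",
    "fit_ladder",
    "compare_models",
    "vif",
    "interindividual_model",
    "last_blocks_sensitivity",
]

ALPHA = 0.05

# nonstationarity terms added cumulatively along the ladder
_NS_MAIN = {
    2: ["start"],
    3: ["length_transition", "width_transition_ntow", "width_transition_wton"],
    4: ["global_mean_z"],
}
_NS_INTERACTION = {
    5: ["start"],
    6: ["length_transition"],
    7: ["width_transition_ntow"],
    8: ["width_transition_wton"],
}


@dataclass(frozen=True)
class SlopeSummary:
    subject_id: str
    condition: str
    slope: float
    central_tendency: float
    n_bins: int


def condition_slopes(trials: pd.DataFrame, min_bins: int = 5) -> pd.DataFrame:
    """Per subject x condition OLS slope of per-bin mean production on sample.

    Averaging productions within each stimulus bin first (the convention for
    slope summaries) removes within-bin noise; conditions observed with fewer
    than ``min_bins`` distinct bins are skipped with a warning.
    """
    rows = []
    for (sid, cond), grp in trials.groupby(["subject_id", "condition"], sort=True):
        per_bin = grp.groupby("sample_s")["production_s"].mean()
        if len(per_bin) < min_bins:
            warnings.warn(
                f"subject {sid}, condition {cond}: only {len(per_bin)} bins; skipped"
            )
            continue
        x = per_bin.index.to_numpy(dtype=float)
        y = per_bin.to_numpy(dtype=float)
        slope = float(np.polyfit(x, y, 1)[0])
        rows.append(
            {
                "subject_id": sid,
                "condition": cond,
                "slope": slope,
                "central_tendency": 1.0 - slope,
                "n_bins": len(per_bin),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    level: int
    formula: str
    terms: list[str]
    zscore_params: dict[str, tuple[float, float]]
    dropped: list[str] = field(default_factory=list)
    interindividual: bool = False


def _session_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Derive nonstationarity covariates for one subject's session.

    The condition order is recovered from first appearance in trial order.
    Start marks the session's first block; the transition indicators mark
    the first block after the respective condition change; GlobalMean is the
    running mean of all preceding sample intervals (the first trial uses its
    own sample, having no history).
    """
    df = df.sort_values("trial_index").copy()
    order = df["condition"].drop_duplicates().tolist()
    first_block = 1  # blocks are numbered from 1 within each condition

    start = (df["condition"] == order[0]) & (df["block"] == first_block)
    length_tr = np.zeros(len(df), dtype=bool)
    w_to_n = np.zeros(len(df), dtype=bool)
    n_to_w = np.zeros(len(df), dtype=bool)
    for prev, cur in zip(order[:-1], order[1:]):
        mask = ((df["condition"] == cur) & (df["block"] == first_block)).to_numpy()
        prev_wide, cur_wide = prev == "WM", cur == "WM"
        if prev_wide and not cur_wide:
            w_to_n |= mask
        elif not prev_wide and cur_wide:
            n_to_w |= mask
        else:
            length_tr |= mask

    s = df["sample_s"].to_numpy(dtype=float)
    run_mean = np.empty_like(s)
    run_mean[0] = s[0]
    if len(s) > 1:
        run_mean[1:] = np.cumsum(s)[:-1] / np.arange(1, len(s))

    df["start"] = start.to_numpy().astype(float)
    df["length_transition"] = length_tr.astype(float)
    df["width_transition_ntow"] = n_to_w.astype(float)
    df["width_transition_wton"] = w_to_n.astype(float)
    df["global_mean"] = run_mean
    return df


def _zscore(col: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    mu, sd = float(col.mean()), float(col.std(ddof=0))
    if sd == 0:
        return col * 0.0, (mu, sd)
    return (col - mu) / sd, (mu, sd)


def _base_terms(interindividual: bool) -> str:
    length_width = "length_medium + length_long + width_wide"
    if interindividual:
        return (
            "(length_medium + length_long + width_wide) * (caps_z + wf_z)"
        )
    return length_width


def _formula_for_level(level: int, interindividual: bool) -> str:
    if not 1 <= level <= 8:
        raise ValueError("level must lie in 1..8")
    inner = [_base_terms(interindividual)]
    extra_main: list[str] = []
    extra_int: list[str] = []
    for lvl, names in _NS_MAIN.items():
        if level >= lvl:
            extra_main += names
    for lvl, names in _NS_INTERACTION.items():
        if level >= lvl:
            extra_int += names
    rhs = f"sample_z * ({' + '.join(inner)})"
    for name in extra_main:
        rhs += f" + {name}"
    for name in extra_int:
        rhs += f" + sample_z:{name}"
    return f"production_s ~ {rhs}"


def build_design(
    trials: pd.DataFrame,
    level: int,
    covariates: pd.DataFrame | None = None,
) -> tuple[DesignSpec, pd.DataFrame]:
    """Assemble the analysis frame and formula for one ladder level.

    Adds condition dummies (medium/long vs short reference; wide vs narrow),
    per-session nonstationarity covariates, and z-scores every continuous
    predictor over the analysis rows (the response stays in seconds).  When
    a covariate table (subject_id, wf, caps) is supplied the design includes
    the six trait-modulation interaction terms.  Covariate columns that are
    constant on these rows (e.g. Start after dropping first blocks) are
    removed with a warning; an exactly rank-deficient fixed design raises.
    """
    if trials["subject_id"].nunique() < 2:
        raise ValueError("mixed-model designs require >= 2 subjects")
    df = pd.concat(
        [_session_covariates(grp) for _, grp in trials.groupby("subject_id", sort=True)],
        ignore_index=True,
    )

    df["length_medium"] = df["condition"].isin(["NM", "WM"]).astype(float)
    df["length_long"] = (df["condition"] == "NL").astype(float)
    df["width_wide"] = (df["condition"] == "WM").astype(float)

    zparams: dict[str, tuple[float, float]] = {}
    df["sample_z"], zparams["sample_s"] = _zscore(df["sample_s"])
    df["global_mean_z"], zparams["global_mean"] = _zscore(df["global_mean"])

    interindividual = covariates is not None
    if interindividual:
        cov = covariates.copy()
        missing = set(df["subject_id"].unique()) - set(cov["subject_id"])
        if missing:
            raise ValueError(f"missing covariates for subjects: {sorted(missing)}")
        df = df.merge(cov[["subject_id", "wf", "caps"]], on="subject_id", how="left")
        df["wf_z"], zparams["wf"] = _zscore(df["wf"])
        df["caps_z"], zparams["caps"] = _zscore(df["caps"])

    formula = _formula_for_level(level, interindividual)

    # drop covariates that are constant on these rows (with a warning)
    dropped = []
    for name in ["start", "length_transition", "width_transition_ntow",
                 "width_transition_wton", "global_mean_z"]:
        if name in formula and df[name].nunique() <= 1:
            dropped.append(name)
            # these names only ever occur as top-level "+ name" /
            # "+ sample_z:name" additions, so plain removal is safe
            formula = formula.replace(f" + sample_z:{name}", "")
            formula = formula.replace(f" + {name}", "")
            warnings.warn(f"covariate {name!r} is constant on these rows; dropped")

    import patsy

    fixed = patsy.dmatrix(formula.split("~", 1)[1], df, return_type="dataframe")
    rank = np.linalg.matrix_rank(fixed.to_numpy())
    if rank < fixed.shape[1]:
        u, s, vt = np.linalg.svd(fixed.to_numpy(), full_matrices=False)
        aliased = [
            fixed.columns[j]
            for j in np.argsort(np.abs(vt[rank:]).max(axis=0))[::-1][: fixed.shape[1] - rank]
        ]
        raise ValueError(f"rank-deficient fixed design; aliased columns: {aliased}")

    spec = DesignSpec(
        level=level,
        formula=formula,
        terms=list(fixed.columns),
        zscore_params=zparams,
        dropped=dropped,
        interindividual=interindividual,
    )
    return spec, df


# ---------------------------------------------------------------------------
# Mixed-model fitting and Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------


@dataclass
class LMEFit:
    level: int
    formula: str
    coefficients: pd.DataFrame  # term, estimate, se, t, df, p, df_method
    cov_re: np.ndarray
    scale: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    k_params: int
    converged: bool
    singular_re: bool = False

    def coef(self, term: str) -> pd.Series:
        match = self.coefficients[self.coefficients["term"] == term]
        if match.empty:
            raise KeyError(f"term {term!r} not in model; have {list(self.coefficients['term'])}")
        return match.iloc[0]

    def find_term(self, *factors: str) -> pd.Series:
        """Look up an interaction coefficient by its factor set, order-free."""
        want = set(factors)
        for _, row in self.coefficients.iterrows():
            if set(row["term"].split(":")) == want:
                return row
        raise KeyError(
            f"no term with factors {sorted(want)}; have {list(self.coefficients['term'])}"
        )


class _ProfiledML:
    """Profiled Gaussian mixed-model likelihood over variance components.

    Sufficient statistics (cross products) are cached per subject, so
    evaluating the log-likelihood or the fixed-effect covariance at any
    variance-component value theta = (g11, g12, g22, sigma2) is cheap.  Used
    for the Satterthwaite construction and as an internal consistency check
    of the fitted model's log-likelihood.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray, groups: np.ndarray):
        self.p = X.shape[1]
        self.N = len(y)
        self.stats = []
        for g in pd.unique(groups):
            idx = groups == g
            Xi, Zi, yi = X[idx], Z[idx], y[idx]
            self.stats.append(
                dict(
                    XtX=Xi.T @ Xi, ZtZ=Zi.T @ Zi, XtZ=Xi.T @ Zi,
                    Xty=Xi.T @ yi, Zty=Zi.T @ yi, yty=float(yi @ yi),
                    n=int(idx.sum()),
                )
            )

    def _components(self, theta: np.ndarray):
        g11, g12, g22, s2 = theta
        G = np.array([[g11, g12], [g12, g22]])
        Gj = G + 1e-12 * np.eye(2)
        Ginv = np.linalg.inv(Gj)
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        yViy = 0.0
        logdet = 0.0
        for st in self.stats:
            A = np.linalg.inv(s2 * Ginv + st["ZtZ"])
            XtViX += (st["XtX"] - st["XtZ"] @ A @ st["XtZ"].T) / s2
            XtViy += (st["Xty"] - st["XtZ"] @ A @ st["Zty"]) / s2
            yViy += (st["yty"] - st["Zty"] @ A @ st["Zty"]) / s2
            sign, ld = np.linalg.slogdet(np.eye(2) + Gj @ st["ZtZ"] / s2)
            logdet += st["n"] * np.log(s2) + ld
        return XtViX, XtViy, yViy, logdet

    def loglik(self, theta: np.ndarray) -> float:
        XtViX, XtViy, yViy, logdet = self._components(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        quad = yViy - beta @ XtViy
        return -0.5 * (self.N * np.log(2 * np.pi) + logdet + quad)

    def fixed_cov(self, theta: np.ndarray) -> np.ndarray:
        XtViX, *_ = self._components(theta)
        return np.linalg.inv(XtViX)


def _satterthwaite_dfs(
    prof: _ProfiledML, theta: np.ndarray, n_obs: int, p: int
) -> tuple[np.ndarray, str]:
    """Satterthwaite df per coefficient: 2 g^2 / (grad' Var(theta) grad)."""
    resid_df = float(n_obs - p)
    try:
        steps = np.maximum(np.abs(theta) * 1e-4, 1e-10)
        # observed information of the profiled log-likelihood
        H = np.zeros((4, 4))
        f0 = prof.loglik(theta)
        for i in range(4):
            for j in range(i, 4):
                ei = np.eye(4)[i] * steps[i]
                ej = np.eye(4)[j] * steps[j]
                if i == j:
                    H[i, i] = (
                        prof.loglik(theta + ei) - 2 * f0 + prof.loglik(theta - ei)
                    ) / steps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        prof.loglik(theta + ei + ej)
                        - prof.loglik(theta + ei - ej)
                        - prof.loglik(theta - ei + ej)
                        + prof.loglik(theta - ei - ej)
                    ) / (4 * steps[i] * steps[j])
        vtheta = np.linalg.inv(-H)
        if not np.all(np.isfinite(vtheta)):
            raise np.linalg.LinAlgError("non-finite variance of theta")

        # gradient of each diagonal contrast variance g_j(theta) = F_jj
        F_plus = [prof.fixed_cov(theta + np.eye(4)[i] * steps[i]) for i in range(4)]
        F_minus = [prof.fixed_cov(theta - np.eye(4)[i] * steps[i]) for i in range(4)]
        F0 = prof.fixed_cov(theta)
        dfs = np.empty(p)
        for j in range(p):
            grad = np.array(
                [
                    (F_plus[i][j, j] - F_minus[i][j, j]) / (2 * steps[i])
                    for i in range(4)
                ]
            )
            denom = grad @ vtheta @ grad
            if denom <= 0:
                dfs[j] = resid_df
            else:
                dfs[j] = 2 * F0[j, j] ** 2 / denom
        dfs = np.clip(dfs, 1.0, resid_df)
        if not np.all(np.isfinite(dfs)):
            raise FloatingPointError("non-finite dfs")
        return dfs, "satterthwaite"
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        return np.full(p, resid_df), "residual"


def fit_lme(spec: DesignSpec, data: pd.DataFrame) -> LMEFit:
    """Fit the mixed model by maximum likelihood and test fixed effects.

    Random structure: per-subject intercept and Sample slope with an
    unstructured 2x2 covariance.  t statistics use the model-based SE from
    the fixed-effect covariance at the estimated variance components;
    degrees of freedom are Satterthwaite (with residual-df fallback recorded
    in the ``df_method`` column).  A singular random-effects covariance is
    flagged but the fit is still returned; non-convergence raises.
    """
    model = smf.mixedlm(
        spec.formula, data, groups=data["subject_id"], re_formula="~sample_z"
    )
    res = None
    for method in ("cg", "powell", "lbfgs", "bfgs"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidate = model.fit(reml=False, method=method, maxiter=1000)
        if candidate.converged:
            res = candidate
            break
    if res is None:
        raise RuntimeError(
            f"mixed model did not converge for level {spec.level} "
            f"under any optimizer"
        )

    import patsy

    fixed = patsy.dmatrix(spec.formula.split("~", 1)[1], data, return_type="dataframe")
    X = fixed.to_numpy()
    Z = np.column_stack([np.ones(len(data)), data["sample_z"].to_numpy()])
    y = data["production_s"].to_numpy(dtype=float)
    groups = data["subject_id"].to_numpy()
    prof = _ProfiledML(y, X, Z, groups)

    G = np.asarray(res.cov_re)
    s2 = float(res.scale)
    theta = np.array([G[0, 0], G[0, 1], G[1, 1], s2])
    eigvals = np.linalg.eigvalsh(G)
    singular = bool(eigvals.min() < 1e-10 * max(eigvals.max(), 1.0))

    p = X.shape[1]
    F0 = prof.fixed_cov(theta)
    beta = np.asarray(res.fe_params)
    se = np.sqrt(np.diag(F0))
    tvals = beta / se
    dfs, df_method = _satterthwaite_dfs(prof, theta, len(y), p)
    pvals = 2 * stats.t.sf(np.abs(tvals), dfs)

    llf = float(res.llf)
    k = p + 3 + 1  # fixed effects + 2x2 RE covariance (3) + residual variance
    n_obs = len(y)
    coef = pd.DataFrame(
        {
            "term": list(fixed.columns),
            "estimate": beta,
            "se": se,
            "t": tvals,
            "df": dfs,
            "p": pvals,
            "df_method": df_method,
        }
    )
    return LMEFit(
        level=spec.level,
        formula=spec.formula,
        coefficients=coef,
        cov_re=G,
        scale=s2,
        loglik=llf,
        aic=2 * k - 2 * llf,
        bic=k * np.log(n_obs) - 2 * llf,
        n_obs=n_obs,
        n_subjects=int(pd.unique(groups).size),
        k_params=k,
        converged=bool(res.converged),
        singular_re=singular,
    )


def fit_ladder(
    trials: pd.DataFrame,
    levels=range(1, 9),
    covariates: pd.DataFrame | None = None,
) -> dict[int, LMEFit]:
    """Fit the requested ladder levels on identical rows."""
    fits = {}
    for level in levels:
        spec, data = build_design(trials, level, covariates=covariates)
        fits[level] = fit_lme(spec, data)
    return fits


@dataclass
class ModelComparison:
    table: pd.DataFrame
    winner: int | None
    consensus: bool


def compare_models(fits: dict[int, LMEFit]) -> ModelComparison:
    """AIC/BIC/LRT comparison across a nested ladder of fits.

    LRT compares each level against its immediate predecessor in the ladder
    (2 * delta logLik vs chi-square with delta-k df); the LRT winner is found
    by stepwise ascent, upgrading whenever the test against the current best
    is significant.  A winner is declared only when AIC, BIC and the LRT
    agree; otherwise all metrics are reported with no consensus.
    """
    levels = sorted(fits)
    n0 = fits[levels[0]].n_obs
    if any(fits[lv].n_obs != n0 for lv in levels):
        raise ValueError("model comparison requires fits on identical rows")
    rows = []
    for i, lv in enumerate(levels):
        f = fits[lv]
        row = {
            "level": lv, "k": f.k_params, "loglik": f.loglik,
            "aic": f.aic, "bic": f.bic,
            "lrt_stat": np.nan, "lrt_df": np.nan, "lrt_p": np.nan,
        }
        if i > 0:
            prev = fits[levels[i - 1]]
            dk = f.k_params - prev.k_params
            stat = 2 * (f.loglik - prev.loglik)
            if dk > 0:
                row.update(
                    lrt_stat=stat, lrt_df=dk,
                    lrt_p=float(stats.chi2.sf(max(stat, 0.0), dk)),
                )
        rows.append(row)
    table = pd.DataFrame(rows)

    aic_winner = int(table.loc[table["aic"].idxmin(), "level"])
    bic_winner = int(table.loc[table["bic"].idxmin(), "level"])
    current = levels[0]
    for lv in levels[1:]:
        dk = fits[lv].k_params - fits[current].k_params
        stat = 2 * (fits[lv].loglik - fits[current].loglik)
        if dk > 0 and stats.chi2.sf(max(stat, 0.0), dk) < ALPHA:
            current = lv
    lrt_winner = current

    consensus = aic_winner == bic_winner == lrt_winner
    return ModelComparison(
        table=table, winner=aic_winner if consensus else None, consensus=consensus
    )


def vif(design_matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per non-intercept column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on all other columns
    (intercept included as regressor); exactly collinear columns get +inf.
    """
    cols = [c for c in design_matrix.columns if c.lower() not in ("intercept", "const")]
    out = {}
    for c in cols:
        others = design_matrix.drop(columns=[c])
        if "Intercept" not in others.columns and "const" not in others.columns:
            others = sm.add_constant(others)
        res = sm.OLS(design_matrix[c], others).fit()
        r2 = min(res.rsquared, 1.0)
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def interindividual_model(
    trials: pd.DataFrame, covariates: pd.DataFrame, level: int = 8
) -> LMEFit:
    """Fit the trait-modulation model at one ladder level.

    The covariate table must give one row per subject with columns
    ``subject_id``, ``wf`` (estimated Weber fraction from the categorization
    task) and ``caps``.  The key outputs are the Sample x WF, Sample x CAPS
    and the Length/Width x Sample x trait interaction coefficients.
    """
    required = {"subject_id", "wf", "caps"}
    if not required <= set(covariates.columns):
        raise ValueError(f"covariate table needs columns {sorted(required)}")
    spec, data = build_design(trials, level, covariates=covariates)
    return fit_lme(spec, data)


def last_blocks_sensitivity(
    trials: pd.DataFrame,
    levels=(1,),
    covariates: pd.DataFrame | None = None,
) -> dict[int, LMEFit]:
    """Refit excluding each condition's first block (nonstationarity control).

    Start and transition covariates are constant (all zero) on this subset
    and are dropped by :func:`build_design` with a warning.
    """
    first_block = trials["block"].min()
    subset = trials[trials["block"] > first_block].copy()
    fits = {}
    for level in levels:
        spec, data = build_design(subset, level, covariates=covariates)
        fits[level] = fit_lme(spec, data)
    return fits
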