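"""Between-within generalized linear mixed model for twin-pair data.

The co-twin control design is operationalized as a mixed-effects regression in
which the exposure (3-category education score) is decomposed into a
between-pair term (the pair mean, pi_1) and a within-pair term (the member's
deviation from the pair mean, pi_2), with a pair random intercept whose
variance is estimated separately for MZ and DZ pairs.  The educ-within x
zygosity interaction (pi_4) tests whether the within-family effect differs by
genetic relatedness: under the MZ = 0 / DZ = 1 coding, pi_2 is the MZ
(fully familially controlled, "quasi-causal") within effect and pi_2 + pi_4
the DZ within effect, so a significant pi_4 indicates additive-genetic
confounding and a null pi_4 points to shared environment.

Estimation maximizes the exact marginal likelihood: the scalar pair random
effect is integrated out by adaptive Gauss-Hermite quadrature (AGHQ) centred
at each pair's conditional mode, with an analytic gradient obtained from
posterior expectations of the joint score.  Standard errors come from the
inverted observed information (central differences of the analytic gradient).

Model ladder (covariates age_centered + study indicators in every model;
study x female added alongside the female main effect):

1. educ3 only (total phenotypic effect)
2. educ_between + educ_within
3. + zygosity main effect + educ_within x zygosity
4. + female main effect (+ study x female)
5. + female x educ_within, female x zygosity, female x zygosity x educ_within
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "BWDesign",
    "GLMMFit",
    "GLMMError",
    "decompose_exposure",
    "build_design",
    "marginal_loglik",
    "BetweenWithinGLMM",
    "fit_bw_glmm",
    "wald_summary",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_SEPARATION_BOUND = 15.0


class GLMMError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which terms are active for a given model of the ladder."""

    model_id: int
    link: str = "logit"
    include_between_within: bool = True
    include_zyg_interaction: bool = False
    include_female_main: bool = False
    include_female_interactions: bool = False

    @classmethod
    def from_model_id(cls, model_id: int, link: str = "logit") -> "ModelSpec":
        if model_id not in (1, 2, 3, 4, 5):
            raise GLMMError(f"unknown model_id {model_id!r} (expected 1-5)")
        return cls(
            model_id=model_id,
            link=link,
            include_between_within=model_id >= 2,
            include_zyg_interaction=model_id >= 3,
            include_female_main=model_id >= 4,
            include_female_interactions=model_id >= 5,
        )


@dataclass
class BWDesign:
    """Assembled design for the between-within GLMM."""

    X: np.ndarray                 # (n_obs, p) fixed-effect design
    y: np.ndarray                 # (n_obs,) binary outcome
    names: list
    idx1: np.ndarray              # (n_pairs,) row index of member 1
    idx2: np.ndarray              # (n_pairs,) row index of member 2, -1 if singleton
    is_dz: np.ndarray             # (n_pairs,) bool, pair zygosity DZ
    pair_id: np.ndarray           # (n_pairs,) pair identifiers
    model_id: int = 2
    link: str = "logit"

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    @property
    def n_pairs(self) -> int:
        return int(self.idx1.size)


@dataclass
class GLMMFit:
    """Fixed effects, zygosity-specific variance components and diagnostics."""

    model_id: int
    link: str
    coef: pd.DataFrame            # index = names; estimate, se, z, p
    var_pair_MZ: float
    var_pair_MZ_se: float
    var_pair_DZ: float
    var_pair_DZ_se: float
    scale_MZ: float
    scale_DZ: float
    minus2ll: float
    n_obs: int
    n_pairs: int
    converged: bool
    n_quad: int
    grad_norm: float
    separation: bool
    message: str = ""
    params: np.ndarray = field(default=None, repr=False)

    def coefficient(self, name: str) -> tuple:
        row = self.coef.loc[name]
        return float(row["estimate"]), float(row["se"]), float(row["p"])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def decompose_exposure(df: pd.DataFrame, col: str = "educ3") -> pd.DataFrame:
    """Add between/within decomposition of an exposure column.

    ``educ_between`` is the pair mean over members with a known value (a
    singleton's own value); ``educ_within`` is the member's deviation from it
    (0 for singletons).  Records with missing exposure get NaN in both.
    """
    out = df.copy()
    grp = out.groupby("pair_id")[col].transform("mean")
    out["educ_between"] = grp
    out["educ_within"] = out[col] - grp
    return out


def _analytic_rows(df: pd.DataFrame) -> pd.DataFrame:
    if "valid" in df.columns:
        df = df[df["valid"] == 1]
    needed = ["educ3", "zyg_dz", "dementia", "age_centered"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise GLMMError(f"cohort not harmonized: missing columns {missing}")
    return df.reset_index(drop=True)


def build_design(
    df: pd.DataFrame,
    spec: ModelSpec,
    center_between: bool = False,
    extra_covariates: tuple = (),
) -> BWDesign:
    """Build the fixed-effect design and pair index structure for one model.

    Education enters as a numeric 1-3 score (one coefficient per term).  Age
    (centred at 60) and study indicators are included in every model;
    study x female indicators accompany the female main effect.
    """
    d = _analytic_rows(df)
    if d.empty:
        raise GLMMError("no valid records to fit")
    d = decompose_exposure(d)

    cols: dict = {"intercept": np.ones(len(d))}
    if spec.include_between_within:
        eb = d["educ_between"].to_numpy(dtype=float)
        if center_between:
            eb = eb - eb.mean()
        cols["educ_between"] = eb
        cols["educ_within"] = d["educ_within"].to_numpy(dtype=float)
    else:
        cols["educ3"] = d["educ3"].to_numpy(dtype=float)
    zyg = d["zyg_dz"].to_numpy(dtype=float)
    if spec.include_zyg_interaction:
        cols["zyg_dz"] = zyg
        cols["educ_within:zyg_dz"] = cols["educ_within"] * zyg
    fem = d["female"].to_numpy(dtype=float) if "female" in d.columns else None
    if spec.include_female_main:
        if fem is None:
            raise GLMMError("female column required for models 4-5")
        cols["female"] = fem
    if spec.include_female_interactions:
        cols["female:educ_within"] = fem * cols["educ_within"]
        cols["female:zyg_dz"] = fem * zyg
        cols["female:zyg_dz:educ_within"] = fem * zyg * cols["educ_within"]

    cols["age_c"] = d["age_centered"].to_numpy(dtype=float)
    studies = sorted(d["study"].astype(str).unique()) if "study" in d.columns else []
    for s in studies[1:]:
        ind = (d["study"].astype(str) == s).to_numpy(dtype=float)
        cols[f"study[{s}]"] = ind
        if spec.include_female_main:
            cols[f"study[{s}]:female"] = ind * fem
    for c in extra_covariates:
        cols[f"cov[{c}]"] = d[c].to_numpy(dtype=float)

    X = np.column_stack(list(cols.values()))
    y = d["dementia"].to_numpy(dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        bad = int(np.argwhere(~np.isfinite(X).all(axis=1) | ~np.isfinite(y))[0])
        raise GLMMError(f"non-finite design value at record {bad}")

    # pair index structure
    pid = d["pair_id"].to_numpy()
    order = np.argsort(pid, kind="stable")
    idx1, idx2, is_dz, pids = [], [], [], []
    i = 0
    while i < len(order):
        j = i + 1
        if j < len(order) and pid[order[j]] == pid[order[i]]:
            idx1.append(order[i]); idx2.append(order[j]); j += 1
        else:
            idx1.append(order[i]); idx2.append(-1)
        is_dz.append(zyg[order[i]] == 1.0)
        pids.append(pid[order[i]])
        i = j
    return BWDesign(
        X=X, y=y, names=list(cols), idx1=np.asarray(idx1), idx2=np.asarray(idx2),
        is_dz=np.asarray(is_dz, dtype=bool), pair_id=np.asarray(pids),
        model_id=spec.model_id, link=spec.link,
    )


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------

def _kernel(link: str):
    """Per-observation log-density and its first two eta-derivatives."""
    if link == "logit":
        def logp(eta, y):
            return -np.logaddexp(0.0, np.where(y == 1.0, -eta, eta))

        def d1(eta, y):
            return y - special.expit(eta)

        def d2(eta, y):
            mu = special.expit(eta)
            return -mu * (1.0 - mu)
    elif link == "log":
        def _mu(eta):
            return np.exp(np.minimum(eta, -1e-9))

        def logp(eta, y):
            mu = _mu(eta)
            return np.where(y == 1.0, np.log(mu), np.log1p(-mu))

        def d1(eta, y):
            mu = _mu(eta)
            return np.where(y == 1.0, 1.0, -mu / (1.0 - mu))

        def d2(eta, y):
            mu = _mu(eta)
            return np.where(y == 1.0, 0.0, -mu / (1.0 - mu) ** 2)
    elif link == "gaussian":
        def logp(eta, y):
            return -0.5 * (y - eta) ** 2 - _LOG_SQRT_2PI

        def d1(eta, y):
            return y - eta

        def d2(eta, y):
            return -np.ones_like(eta)
    else:
        raise GLMMError(f"unknown link {link!r}")
    return logp, d1, d2


class _MarginalLikelihood:
    """AGHQ marginal log-likelihood and analytic gradient for one design."""

    def __init__(self, design: BWDesign, n_quad: int = 15):
        if n_quad < 1:
            raise GLMMError("n_quad must be >= 1")
        self.design = design
        self.n_quad = int(n_quad)
        x, w = hermgauss(self.n_quad)
        self.nodes = x
        self.logw = np.log(w)
        self.logp, self.d1, self.d2 = _kernel(design.link)
        d = design
        self.m2 = d.idx2 >= 0
        self.i2 = np.where(self.m2, d.idx2, 0)
        self.w2 = self.m2.astype(float)
        self._vcache = np.zeros(d.n_pairs)

    def _eta_pairs(self, beta):
        eta = self.design.X @ beta
        return eta[self.design.idx1], eta[self.i2]

    def _mode(self, eta1, eta2, y1, y2, s):
        """Newton solve for each pair's conditional mode of u = s*v, v scale."""
        v = self._vcache.copy()
        d1, d2, w2 = self.d1, self.d2, self.w2
        for _ in range(60):
            e1, e2 = eta1 + s * v, eta2 + s * v
            g = s * (d1(e1, y1) + w2 * d1(e2, y2)) - v
            h = s * s * (d2(e1, y1) + w2 * d2(e2, y2)) - 1.0
            step = np.clip(-g / h, -4.0, 4.0)
            v = v + step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._vcache = v
        e1, e2 = eta1 + s * v, eta2 + s * v
        h = s * s * (d2(e1, y1) + w2 * d2(e2, y2)) - 1.0
        return v, np.sqrt(-1.0 / h)

    def value_and_grad(self, params, want_grad: bool = True):
        d = self.design
        p = d.X.shape[1]
        beta = params[:p]
        if np.abs(beta).max() > 1e6 or not np.isfinite(params).all():
            raise GLMMError("non-finite linear predictor (diverging parameters)")
        ls_mz, ls_dz = params[p], params[p + 1]
        s = np.where(d.is_dz, np.exp(ls_dz), np.exp(ls_mz))

        y1, y2 = d.y[d.idx1], d.y[self.i2]
        eta1, eta2 = self._eta_pairs(beta)
        w2 = self.w2

        vhat, tau = self._mode(eta1, eta2, y1, y2, s)
        sq2t = np.sqrt(2.0) * tau

        K = self.n_quad
        n = d.n_pairs
        g = np.empty((K, n))
        d1_1 = np.empty((K, n))
        d1_2 = np.empty((K, n))
        vk_all = np.empty((K, n))
        for k in range(K):
            vk = vhat + sq2t * self.nodes[k]
            e1k, e2k = eta1 + s * vk, eta2 + s * vk
            g[k] = (
                self.logp(e1k, y1) + w2 * self.logp(e2k, y2)
                - 0.5 * vk * vk - _LOG_SQRT_2PI
                + self.logw[k] + self.nodes[k] ** 2
            )
            if want_grad:
                d1_1[k] = self.d1(e1k, y1)
                d1_2[k] = self.d1(e2k, y2)
                vk_all[k] = vk
        gmax = g.max(axis=0)
        sumexp = np.exp(g - gmax).sum(axis=0)
        ll_pairs = gmax + np.log(sumexp) + np.log(sq2t)
        ll = float(ll_pairs.sum())
        if not want_grad:
            return ll, None

        post = np.exp(g - gmax) / sumexp  # (K, n) posterior quadrature weights
        r1 = (post * d1_1).sum(axis=0)    # E[score wrt eta] member 1
        r2 = (post * d1_2).sum(axis=0) * w2
        grad_beta = d.X[d.idx1].T @ r1 + d.X[self.i2].T @ r2
        # d/d log s: sum_i E[d1_i * v] * s  per pair, split by zygosity
        ev = (post * (d1_1 + w2 * d1_2) * vk_all).sum(axis=0) * s
        grad = np.concatenate([
            grad_beta,
            [float(ev[~d.is_dz].sum()), float(ev[d.is_dz].sum())],
        ])
        return ll, grad

    def fixed_only_loglik(self, beta) -> float:
        """Log-likelihood with both variance components exactly zero."""
        eta = self.design.X @ beta
        return float(self.logp(eta, self.design.y).sum())

    def fixed_only_value_and_grad(self, beta):
        eta = self.design.X @ beta
        ll = float(self.logp(eta, self.design.y).sum())
        grad = self.design.X.T @ self.d1(eta, self.design.y)
        return ll, grad


def marginal_loglik(
    params: np.ndarray, design: BWDesign, n_quad: int = 15
) -> float:
    """AGHQ marginal log-likelihood at ``params = (beta, log sd_MZ, log sd_DZ)``.

    Passing ``sigma = 0`` exactly (i.e. ``log sd = -inf``) collapses to the
    ordinary fixed-effects log-likelihood.
    """
    params = np.asarray(params, dtype=float)
    p = design.X.shape[1]
    ml = _MarginalLikelihood(design, n_quad=n_quad)
    if np.all(np.isneginf(params[p:])) or np.all(np.exp(params[p:]) < 1e-12):
        return ml.fixed_only_loglik(params[:p])
    ll, _ = ml.value_and_grad(params, want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

def _numerical_hessian_from_grad(fun_grad, x, h=1e-5):
    """Central-difference Hessian of f from its analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        hi = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        _, gp = fun_grad(xp)
        _, gm = fun_grad(xm)
        H[i] = (gp - gm) / (2.0 * hi)
    return 0.5 * (H + H.T)


class BetweenWithinGLMM(BaseEstimator):
    """Between-within GLMM estimator for clustered binary twin outcomes.

    Parameters
    ----------
    model_id : int, default 2
        Position on the model ladder (1-5), see module docstring.
    link : {'logit', 'log', 'gaussian'}, default 'logit'
        Outcome kernel.  'logit' is the primary binomial model (coefficients
        are changes in log-odds of dementia); 'log' gives log-risk
        coefficients; 'gaussian' (identity) exists for analytic checks.
    n_quad : int, default 15
        Adaptive Gauss-Hermite quadrature points per pair.
    alpha : float, default 0.05
        Two-sided significance level used by :meth:`summary`.
    center_between : bool, default False
        Centre the between-pair education mean at the grand mean (affects the
        intercept only).
    extra_covariates : tuple of str, default ()
        Additional harmonized columns entered linearly (risk-factor
        adjustment analyses).
    max_iter : int, default 200
        L-BFGS-B iteration cap.
    fix_variances : float or None, default None
        Fix both random-intercept variances at this value instead of
        estimating them (0 collapses the model to an ordinary GLM; used for
        analytic equivalence checks).

    Attributes (after ``fit``)
    --------------------------
    coef_, se_, zvalues_, pvalues_ : ndarray aligned with ``coef_names_``
    var_MZ_, var_DZ_ : random-intercept variances (link scale)
    scale_MZ_, scale_DZ_ : per-zygosity Pearson dispersion diagnostics
    minus2ll_, converged_, n_obs_, n_pairs_, result_ (:class:`GLMMFit`)
    """

    def __init__(
        self,
        model_id: int = 2,
        link: str = "logit",
        n_quad: int = 15,
        alpha: float = 0.05,
        center_between: bool = False,
        extra_covariates: tuple = (),
        max_iter: int = 200,
        fix_variances: float | None = None,
    ):
        self.model_id = model_id
        self.link = link
        self.n_quad = n_quad
        self.alpha = alpha
        self.center_between = center_between
        self.extra_covariates = extra_covariates
        self.max_iter = max_iter
        self.fix_variances = fix_variances

    # -- core ---------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "BetweenWithinGLMM":
        spec = ModelSpec.from_model_id(self.model_id, self.link)
        design = build_design(
            X, spec, center_between=self.center_between,
            extra_covariates=tuple(self.extra_covariates),
        )
        if self.fix_variances is None:
            for z, lab in ((False, "MZ"), (True, "DZ")):
                if (design.is_dz == z).sum() < 2:
                    raise GLMMError(
                        f"at least 2 {lab} pairs required for zygosity-specific"
                        " variances"
                    )
        ml = _MarginalLikelihood(design, n_quad=self.n_quad)
        p = design.X.shape[1]
        beta0 = self._start_values(design)

        if self.fix_variances is not None:
            if self.fix_variances < 0:
                raise GLMMError("fix_variances must be >= 0")
            if self.fix_variances == 0.0:
                full = ml.fixed_only_value_and_grad
            else:
                ls = 0.5 * np.log(self.fix_variances)

                def full(beta):
                    ll, g = ml.value_and_grad(np.concatenate([beta, [ls, ls]]))
                    return ll, g[:p]

            x0 = beta0
            bounds = [(None, None)] * p
        else:
            def full(params):
                return ml.value_and_grad(params)

            x0 = np.concatenate([beta0, [0.5 * np.log(0.5)] * 2])
            bounds = [(None, None)] * p + [(-6.0, 3.0)] * 2

        def neg(params):
            ll, grad = full(params)
            return -ll, -grad

        res = optimize.minimize(
            neg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            # ftol effectively disabled: the variance directions are flat and
            # termination must be gradient-based to be quadrature-stable
            options={"maxiter": self.max_iter, "ftol": 1e-16, "gtol": 1e-7},
        )
        xhat = res.x
        ll, grad = full(xhat)
        grad_norm = float(np.max(np.abs(grad)))
        # relative gradient criterion as fallback when L-BFGS-B stops on ftol
        converged = bool(res.success or grad_norm < 1e-5 * max(1.0, abs(ll)))

        H = _numerical_hessian_from_grad(lambda t: full(t), xhat)
        info = -H  # observed information of the log-likelihood
        try:
            cov = np.linalg.inv(info)
            if not np.all(np.diag(cov) > 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
            converged = converged and bool(np.all(np.diag(cov)[:p] > 0))
        se = np.sqrt(np.abs(np.diag(cov)))

        beta, se_beta = xhat[:p], se[:p]
        zval = np.divide(beta, se_beta, out=np.zeros_like(beta), where=se_beta > 0)
        pval = 2.0 * stats.norm.sf(np.abs(zval))
        if self.fix_variances is not None:
            s_mz = s_dz = float(np.sqrt(self.fix_variances))
            var_se = np.zeros(2)
            full_params = np.concatenate(
                [beta, [np.log(max(s_mz, 1e-300))] * 2])
        else:
            s_mz, s_dz = np.exp(xhat[p]), np.exp(xhat[p + 1])
            # delta method: var = s^2, d var / d log s = 2 s^2
            var_se = 2.0 * np.array([s_mz**2, s_dz**2]) * se[p:]
            full_params = xhat

        scale_mz, scale_dz = self._dispersion(ml, full_params)

        coef = pd.DataFrame(
            {"estimate": beta, "se": se_beta, "z": zval, "p": pval},
            index=design.names,
        )
        self.result_ = GLMMFit(
            model_id=self.model_id,
            link=self.link,
            coef=coef,
            var_pair_MZ=float(s_mz**2), var_pair_MZ_se=float(var_se[0]),
            var_pair_DZ=float(s_dz**2), var_pair_DZ_se=float(var_se[1]),
            scale_MZ=scale_mz, scale_DZ=scale_dz,
            minus2ll=float(-2.0 * ll),
            n_obs=design.n_obs, n_pairs=design.n_pairs,
            converged=converged, n_quad=self.n_quad, grad_norm=grad_norm,
            separation=bool(np.abs(beta).max() > _SEPARATION_BOUND),
            message=str(res.message),
            params=xhat,
        )
        self.coef_names_ = list(design.names)
        self.coef_ = beta
        self.se_ = se_beta
        self.zvalues_ = zval
        self.pvalues_ = pval
        self.var_MZ_ = float(s_mz**2)
        self.var_DZ_ = float(s_dz**2)
        self.scale_MZ_ = scale_mz
        self.scale_DZ_ = scale_dz
        self.minus2ll_ = float(-2.0 * ll)
        self.converged_ = converged
        self.n_obs_ = design.n_obs
        self.n_pairs_ = design.n_pairs
        self.design_ = design
        return self

    def _start_values(self, design: BWDesign) -> np.ndarray:
        import statsmodels.api as sm

        if design.link == "gaussian":
            return np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        fam = sm.families.Binomial(
            sm.families.links.Log() if design.link == "log"
            else sm.families.links.Logit()
        )
        try:
            glm = sm.GLM(design.y, design.X, family=fam).fit(maxiter=50)
            if np.isfinite(glm.params).all():
                return np.asarray(glm.params)
        except Exception:
            pass
        return np.zeros(design.X.shape[1])

    def _dispersion(self, ml: _MarginalLikelihood, params) -> tuple:
        """Per-zygosity Pearson-residual dispersion at the conditional modes."""
        if ml.design.link != "logit":
            return float("nan"), float("nan")
        d = ml.design
        p = d.X.shape[1]
        beta = params[:p]
        s = np.where(d.is_dz, np.exp(params[p + 1]), np.exp(params[p]))
        eta1, eta2 = ml._eta_pairs(beta)
        y1, y2 = d.y[d.idx1], d.y[ml.i2]
        vhat, _ = ml._mode(eta1, eta2, y1, y2, s)
        out = []
        for z in (False, True):
            m = d.is_dz == z
            mu1 = special.expit(eta1[m] + s[m] * vhat[m])
            mu2 = special.expit(eta2[m] + s[m] * vhat[m])
            r1 = (y1[m] - mu1) ** 2 / np.clip(mu1 * (1 - mu1), 1e-12, None)
            r2 = (y2[m] - mu2) ** 2 / np.clip(mu2 * (1 - mu2), 1e-12, None)
            w2 = ml.w2[m]
            out.append(float((r1.sum() + (w2 * r2).sum()) / (m.sum() + w2.sum())))
        return out[0], out[1]

    # -- post-fit API ---------------------------------------------------------
    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Conditional (u = 0) outcome probabilities, sklearn-style (n, 2)."""
        self._check_fitted()
        spec = ModelSpec.from_model_id(self.model_id, self.link)
        design = build_design(
            X, spec, center_between=self.center_between,
            extra_covariates=tuple(self.extra_covariates),
        )
        eta = design.X @ self.coef_
        p1 = special.expit(eta) if self.link != "gaussian" else eta
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def summary(self) -> pd.DataFrame:
        self._check_fitted()
        return wald_summary(self.result_, alpha=self.alpha)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise GLMMError("estimator is not fitted")


def fit_bw_glmm(
    df: pd.DataFrame,
    model_id: int = 2,
    link: str = "logit",
    n_quad: int = 15,
    **kwargs,
) -> GLMMFit:
    """Fit one model of the ladder and return its :class:`GLMMFit`."""
    est = BetweenWithinGLMM(model_id=model_id, link=link, n_quad=n_quad, **kwargs)
    return est.fit(df).result_


def wald_summary(fit: GLMMFit, alpha: float = 0.05) -> pd.DataFrame:
    """Coefficient table with two-sided Wald significance flags."""
    if not fit.converged:
        raise GLMMError("refusing to summarize an unconverged fit")
    out = fit.coef.copy()
    out["significant"] = out["p"] < alpha
    return out
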