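"""Joint estimation of the three-equation CRM system by SUR.

Both estimators are feasible generalized least squares on the stacked
system with a block-diagonal design: stage-1 per-equation fits supply
residuals, the 3x3 cross-equation residual covariance is estimated from
them, and the generalized criterion is then minimized — in closed form for
the linear system (LSUR), by Gauss-Newton with step-halving for the
nonlinear exponential-in-1/X system (NSUR).  Both iterate the covariance
update to convergence by default.

Because all three equations share the same regressor, the linear FGLS
estimate coincides with per-equation OLS (Kruskal's theorem); the joint
fit still supplies the cross-equation residual covariance that motivates
SUR and the system goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import EquationParams, ModelForm, Predictor, transform_predictor
from .records import SYSTEM_COMPONENTS, TreeRecord


class SingularCovarianceError(np.linalg.LinAlgError):
    """The estimated residual covariance is (numerically) singular."""


@dataclass
class SystemData:
    """Responses and predictor values of the three-equation ratio system.

    ``y`` has one column per modeled component (stem, branch, twig) and one
    row per tree; ``x`` is the shared predictor value per tree.
    """

    x: np.ndarray
    y: np.ndarray
    tree_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2 or self.y.shape[1] != len(SYSTEM_COMPONENTS):
            raise ValueError("y must be an (n, 3) array of stem/branch/twig ratios")
        if self.x.shape != (self.y.shape[0],):
            raise ValueError("x must be a length-n vector matching y")
        if self.n < 3:
            raise ValueError("at least 3 trees are required")
        if np.any(self.x <= 0):
            raise ValueError("predictor values must be positive")
        if np.any(self.y < 0) or np.any(self.y > 1):
            raise ValueError("responses must be ratios in [0, 1]")
        if self.tree_ids is not None and len(self.tree_ids) != self.n:
            raise ValueError("tree_ids length must match n")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @classmethod
    def from_ratios(cls, ratios: pd.DataFrame, spec: Predictor) -> "SystemData":
        """Build system data from a per-tree ratio table.

        The table needs ``dbh_cm`` and the three ``r_*`` response columns;
        ``ht_m`` is required (non-missing) for the dbh^2*ht predictor.
        """
        spec = Predictor(spec)
        required = ["dbh_cm"] + [f"r_{c}" for c in SYSTEM_COMPONENTS]
        if spec is Predictor.DBH_SQ_HT:
            required.append("ht_m")
        for col in required:
            if col not in ratios.columns:
                raise ValueError(f"ratio table missing required column '{col}'")
        if spec is Predictor.DBH_SQ_HT and ratios["ht_m"].isna().any():
            raise ValueError("ratio table has missing ht_m values; predictor "
                             "'dbh2ht' requires ht")
        trees = [
            TreeRecord(
                str(row.tree_id) if hasattr(row, "tree_id") else str(row.Index),
                float(row.dbh_cm),
                float(row.ht_m) if "ht_m" in ratios.columns and not pd.isna(row.ht_m) else None,
            )
            for row in ratios.itertuples()
        ]
        x = np.array([transform_predictor(t, spec) for t in trees])
        y = ratios[[f"r_{c}" for c in SYSTEM_COMPONENTS]].to_numpy(dtype=float)
        return cls(x=x, y=y, tree_ids=[t.tree_id for t in trees])


@dataclass
class EquationFit:
    """Fit summary of one component-ratio equation."""

    params: EquationParams
    se_beta0: float
    se_beta1: float
    p_beta0: float
    p_beta1: float
    rse: float
    r2: float
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def component(self) -> str:
        return self.params.component


@dataclass
class SystemFit:
    """Jointly fitted three-equation system with diagnostics."""

    fits: dict[str, EquationFit]
    sigma: np.ndarray
    corr: np.ndarray
    overall_r2: float
    form: ModelForm
    spec: Predictor | None
    converged: bool
    n_iter: int
    #: per-iteration (objective before step, after step) at that iteration's
    #: weighting covariance; the criterion rescales when sigma updates, so
    #: monotonicity holds within each pair, not across iterations
    objective_history: list[tuple[float, float]] = dc_field(default_factory=list)
    tree_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return len(next(iter(self.fits.values())).residuals)

    def params_map(self) -> dict[str, EquationParams]:
        return {c: f.params for c, f in self.fits.items()}

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        n = self.n
        return {
            "form": ModelForm(self.form).value,
            "predictor": Predictor(self.spec).value if self.spec else None,
            "n_trees": n,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "overall_r2": float(self.overall_r2),
            "overall_r2_definition": "McElroy system R2",
            "equations": {
                c: {
                    "beta0": f.params.beta0,
                    "beta1": f.params.beta1,
                    "se0": f.se_beta0,
                    "se1": f.se_beta1,
                    "p0": f.p_beta0,
                    "p1": f.p_beta1,
                    "stars_beta1": significance_stars(f.p_beta1),
                    "rse": f.rse,
                    "r2": f.r2,
                }
                for c, f in self.fits.items()
            },
            "sigma": self.sigma.tolist(),
            "correlation": self.corr.tolist(),
        }


def significance_stars(p: float) -> str:
    """Star label of a p-value (boundaries inclusive): ns, *, **, ***, ****."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def fit_ols_equation(y: np.ndarray, X: np.ndarray, component: str = "") -> EquationFit:
    """Ordinary least squares for one equation with a [1, x] design.

    ``rse = sqrt(SSR / (n - k))`` with k the number of columns of ``X``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ssr = float(resid @ resid)
    s2 = ssr / (n - k)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - k)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return EquationFit(
        params=EquationParams(component, float(beta[0]), float(beta[1])),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        p_beta0=float(pvals[0]),
        p_beta1=float(pvals[1]),
        rse=float(np.sqrt(s2)),
        r2=r2,
        fitted=fitted,
        residuals=resid,
    )


def estimate_sigma(
    residuals: np.ndarray,
    ks: Sequence[int] = (2, 2, 2),
    policy: str = "geometric",
) -> np.ndarray:
    """Cross-equation residual covariance from an (n, m) residual matrix.

    ``sigma_ij = e_i'e_j / d_ij`` with ``d_ij = sqrt((n - k_i)(n - k_j))``
    under the default geometric degrees-of-freedom policy, or ``d_ij = n``
    under ``policy="n"``.  The result is symmetric and positive
    semi-definite by construction.
    """
    E = np.asarray(residuals, dtype=float)
    n, m = E.shape
    if policy == "geometric":
        dof = np.array([n - k for k in ks], dtype=float)
        if np.any(dof <= 0):
            raise ValueError("n must exceed the parameter count of every equation")
        d = np.sqrt(np.outer(dof, dof))
    elif policy == "n":
        d = np.full((m, m), float(n))
    else:
        raise ValueError(f"unknown df policy {policy!r}")
    sigma = (E.T @ E) / d
    return (sigma + sigma.T) / 2.0


def _inv_sigma(sigma: np.ndarray) -> np.ndarray:
    if np.linalg.cond(sigma) > 1e12:
        raise SingularCovarianceError(
            "estimated residual covariance is singular or near-singular; "
            "too few trees or collinear residuals across equations"
        )
    return np.linalg.inv(sigma)


def _safe_sinv(sigma: np.ndarray) -> np.ndarray:
    """Weighting inverse that degrades to identity on singular covariance.

    Used inside the nonlinear iteration, where a (near-)exact fit drives
    the residual covariance to zero; the weighting is then irrelevant and
    unweighted least squares is the continuous limit.
    """
    try:
        return _inv_sigma(sigma)
    except SingularCovarianceError:
        return np.eye(sigma.shape[0])


def _safe_corr(sigma: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(sigma))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = sigma / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _gls_solve(X: np.ndarray, Y: np.ndarray, sinv: np.ndarray):
    """Closed-form stacked GLS for m equations sharing design ``X``.

    Exploits the block structure: the (i, j) block of the normal matrix is
    ``sinv[i, j] * X'X``.  Returns the coefficient matrix (k, m) and the
    stacked-coefficient covariance (mk, mk), parameter order equation-major.
    """
    n, k = X.shape
    m = Y.shape[1]
    xtx = X.T @ X
    A = np.kron(sinv, xtx)
    rhs = np.concatenate([X.T @ (Y @ sinv[:, i]) for i in range(m)])
    beta = np.linalg.solve(A, rhs)
    cov = np.linalg.inv(A)
    return beta.reshape(m, k).T, cov


def _mcelroy_r2(Y: np.ndarray, E: np.ndarray, sinv: np.ndarray) -> float:
    """McElroy's system R2: 1 - e'(S^-1 (x) I)e / yc'(S^-1 (x) I)yc."""
    Yc = Y - Y.mean(axis=0)
    num = float(np.einsum("ni,ij,nj->", E, sinv, E))
    den = float(np.einsum("ni,ij,nj->", Yc, sinv, Yc))
    return 1.0 - num / den if den > 0 else 0.0


def _finalize_linear(
    data: SystemData,
    X: np.ndarray,
    B: np.ndarray,
    cov: np.ndarray,
    sigma: np.ndarray,
    form: ModelForm,
    spec: Predictor | None,
    converged: bool,
    n_iter: int,
    history: list[float],
    fitted: np.ndarray,
) -> SystemFit:
    n, k = X.shape
    E = data.y - fitted
    fits = {}
    for j, c in enumerate(SYSTEM_COMPONENTS):
        resid = E[:, j]
        ssr = float(resid @ resid)
        sst = float(np.sum((data.y[:, j] - data.y[:, j].mean()) ** 2))
        se = np.sqrt(np.diag(cov)[j * k : (j + 1) * k])
        beta = B[:, j]
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df=n - k)
        fits[c] = EquationFit(
            params=EquationParams(c, float(beta[0]), float(beta[1])),
            se_beta0=float(se[0]),
            se_beta1=float(se[1]),
            p_beta0=float(pvals[0]),
            p_beta1=float(pvals[1]),
            rse=float(np.sqrt(ssr / (n - k))),
            r2=1.0 - ssr / sst if sst > 0 else 0.0,
            fitted=fitted[:, j].copy(),
            residuals=resid.copy(),
        )
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    overall = _mcelroy_r2(data.y, E, _inv_sigma(sigma))
    return SystemFit(
        fits=fits,
        sigma=sigma,
        corr=corr,
        overall_r2=overall,
        form=form,
        spec=spec,
        converged=converged,
        n_iter=n_iter,
        objective_history=history,
        tree_ids=data.tree_ids,
    )


def fit_lsur(
    data: SystemData,
    spec: Predictor | None = None,
    *,
    iterate: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
    df_policy: str = "geometric",
    sigma_override: np.ndarray | None = None,
) -> SystemFit:
    """Linear SUR of the three ratio equations by stacked FGLS.

    Stage 1 fits each equation by OLS; stage 2 estimates the residual
    covariance; stage 3 solves the stacked GLS normal equations.  By
    default stages 2-3 iterate until the largest coefficient change falls
    below ``tol``; ``iterate=False`` gives the classic one-step estimator.
    ``sigma_override`` fixes the weighting covariance (e.g. the identity,
    which reduces GLS to per-equation OLS).

    Standard errors come from the GLS coefficient covariance; p-values use
    a t reference with n - 2 degrees of freedom per equation.
    """
    X = np.column_stack([np.ones(data.n), data.x])
    n, k = X.shape
    # stage 1: per-equation OLS
    B = np.column_stack(
        [np.linalg.lstsq(X, data.y[:, j], rcond=None)[0] for j in range(3)]
    )
    E = data.y - X @ B
    converged = not iterate
    n_iter = 0
    sigma = None
    for n_iter in range(1, max_iter + 1):
        sigma = (
            np.asarray(sigma_override, dtype=float)
            if sigma_override is not None
            else estimate_sigma(E, ks=(k, k, k), policy=df_policy)
        )
        sinv = _inv_sigma(sigma)
        B_new, cov = _gls_solve(X, data.y, sinv)
        delta = float(np.max(np.abs(B_new - B)))
        B = B_new
        E = data.y - X @ B
        if not iterate or sigma_override is not None:
            converged = True
            break
        if delta < tol:
            converged = True
            break
    # report the covariance of the final residuals unless it was overridden
    sigma_report = (
        sigma
        if sigma_override is not None
        else estimate_sigma(E, ks=(k, k, k), policy=df_policy)
    )
    return _finalize_linear(
        data, X, B, cov, sigma_report, ModelForm.LINEAR, spec,
        converged, n_iter, [], X @ B,
    )


def nsur_start_values(data: SystemData) -> dict[str, EquationParams]:
    """Starting values for NSUR via exact log-linearization.

    ``ln R = beta0 + beta1 / X`` is linear in 1/X, so per-equation OLS of
    the log response on 1/X recovers the parameters exactly on noiseless
    data.  Requires strictly positive responses.
    """
    if np.any(data.y <= 0):
        raise ValueError("log-linearized start values require positive responses")
    Z = np.column_stack([np.ones(data.n), 1.0 / data.x])
    out = {}
    for j, c in enumerate(SYSTEM_COMPONENTS):
        beta, *_ = np.linalg.lstsq(Z, np.log(data.y[:, j]), rcond=None)
        out[c] = EquationParams(c, float(beta[0]), float(beta[1]))
    return out


def _nsur_mean_and_grad(beta: np.ndarray, x: np.ndarray):
    """Mean surface and per-equation Jacobians of the exponential form.

    ``beta`` is equation-major (b0_stem, b1_stem, b0_branch, ...).
    """
    F = np.empty((len(x), 3))
    G = []
    for j in range(3):
        b0, b1 = beta[2 * j], beta[2 * j + 1]
        f = np.exp(b0 + b1 / x)
        F[:, j] = f
        G.append(np.column_stack([f, f / x]))
    return F, G


def _nsur_objective(beta: np.ndarray, data: SystemData, sinv: np.ndarray) -> float:
    F, _ = _nsur_mean_and_grad(beta, data.x)
    E = data.y - F
    return float(np.einsum("ni,ij,nj->", E, sinv, E))


def fit_nsur(
    data: SystemData,
    spec: Predictor | None = None,
    *,
    tol_beta: float = 1e-8,
    tol_obj: float = 1e-10,
    max_iter: int = 500,
    df_policy: str = "geometric",
    sigma_override: np.ndarray | None = None,
) -> SystemFit:
    """Nonlinear SUR of the exponential-in-1/X system.

    Minimizes the stacked generalized criterion ``e(b)'(S^-1 (x) I)e(b)``
    by Gauss-Newton with step-halving, starting from the log-linearized
    values and alternating coefficient steps with covariance updates.
    Convergence requires both a relative criterion change below
    ``tol_obj`` and a maximum coefficient step below ``tol_beta``.
    Non-convergence is reported via ``converged=False``, never raised.
    """
    start = nsur_start_values(data)
    beta = np.concatenate([[start[c].beta0, start[c].beta1] for c in SYSTEM_COMPONENTS])
    n = data.n
    k = 2
    F, _ = _nsur_mean_and_grad(beta, data.x)
    E = data.y - F
    converged = False
    history: list[tuple[float, float]] = []
    sigma = None
    for n_iter in range(1, max_iter + 1):
        sigma = (
            np.asarray(sigma_override, dtype=float)
            if sigma_override is not None
            else estimate_sigma(E, ks=(k, k, k), policy=df_policy)
        )
        sinv = _safe_sinv(sigma)
        q_old = _nsur_objective(beta, data, sinv)
        F, G = _nsur_mean_and_grad(beta, data.x)
        E = data.y - F
        # Gauss-Newton normal equations on the stacked weighted system
        H = np.empty((6, 6))
        g = np.empty(6)
        for i in range(3):
            for j in range(3):
                H[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = sinv[i, j] * (G[i].T @ G[j])
            g[2 * i : 2 * i + 2] = sum(
                sinv[i, j] * (G[i].T @ E[:, j]) for j in range(3)
            )
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        q_new = _nsur_objective(beta + lam * step, data, sinv)
        while q_new > q_old and lam > 1e-10:
            lam *= 0.5
            q_new = _nsur_objective(beta + lam * step, data, sinv)
        if q_new > q_old:  # no descent direction left
            history.append((q_old, q_old))
            converged = q_old < 1e-20  # exact fit reached
            break
        beta = beta + lam * step
        history.append((q_old, q_new))
        assert q_new <= q_old + 1e-12 * (1.0 + abs(q_old))
        F, _ = _nsur_mean_and_grad(beta, data.x)
        E = data.y - F
        max_step = float(np.max(np.abs(lam * step)))
        rel_change = abs(q_old - q_new) / (1.0 + abs(q_old))
        if max_step < tol_beta and rel_change < tol_obj:
            converged = True
            break
    sigma_report = (
        np.asarray(sigma_override, dtype=float)
        if sigma_override is not None
        else estimate_sigma(E, ks=(k, k, k), policy=df_policy)
    )
    sinv = _safe_sinv(sigma_report)
    F, G = _nsur_mean_and_grad(beta, data.x)
    E = data.y - F
    H = np.empty((6, 6))
    for i in range(3):
        for j in range(3):
            H[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = sinv[i, j] * (G[i].T @ G[j])
    cov = np.linalg.inv(H)
    fits = {}
    for j, c in enumerate(SYSTEM_COMPONENTS):
        resid = E[:, j]
        ssr = float(resid @ resid)
        sst = float(np.sum((data.y[:, j] - data.y[:, j].mean()) ** 2))
        se = np.sqrt(np.diag(cov)[2 * j : 2 * j + 2])
        b = beta[2 * j : 2 * j + 2]
        pvals = 2 * stats.t.sf(np.abs(b / se), df=n - k)
        fits[c] = EquationFit(
            params=EquationParams(c, float(b[0]), float(b[1])),
            se_beta0=float(se[0]),
            se_beta1=float(se[1]),
            p_beta0=float(pvals[0]),
            p_beta1=float(pvals[1]),
            rse=float(np.sqrt(ssr / (n - k))),
            r2=1.0 - ssr / sst if sst > 0 else 0.0,
            fitted=F[:, j].copy(),
            residuals=resid.copy(),
        )
    corr = _safe_corr(sigma_report)
    return SystemFit(
        fits=fits,
        sigma=sigma_report,
        corr=corr,
        overall_r2=_mcelroy_r2(data.y, E, sinv),
        form=ModelForm.NONLINEAR,
        spec=spec,
        converged=converged,
        n_iter=n_iter,
        objective_history=history,
        tree_ids=data.tree_ids,
    )


def equation_diagnostics(fit: EquationFit, n: int) -> dict:
    """Per-equation diagnostic report with the significance star label."""
    return {
        "component": fit.component,
        "n": int(n),
        "rse": fit.rse,
        "r2": fit.r2,
        "p_beta0": fit.p_beta0,
        "p_beta1": fit.p_beta1,
        "stars_beta1": significance_stars(fit.p_beta1),
    }


def foliage_slope_screen(
    ratios: pd.DataFrame, spec: Predictor, form: ModelForm = ModelForm.LINEAR
) -> dict:
    """Pre-fit screen of the foliage-ratio slope against a predictor.

    The foliage equation is never estimated inside the system; this check
    reports whether its slope would differ significantly from zero (OLS on
    X for the linear form, log response on 1/X for the nonlinear form),
    supporting the choice to model foliage as the complement.
    """
    data = SystemData.from_ratios(ratios, spec)
    y = ratios["r_foliage"].to_numpy(dtype=float)
    form = ModelForm(form)
    if form is ModelForm.NONLINEAR:
        if np.any(y <= 0):
            raise ValueError("nonlinear screen requires positive foliage ratios")
        X = np.column_stack([np.ones(data.n), 1.0 / data.x])
        fit = fit_ols_equation(np.log(y), X, component="foliage")
    else:
        X = np.column_stack([np.ones(data.n), data.x])
        fit = fit_ols_equation(y, X, component="foliage")
    return {
        "form": form.value,
        "predictor": Predictor(spec).value,
        "beta1": fit.params.beta1,
        "p_beta1": fit.p_beta1,
        "significant": fit.p_beta1 <= 0.05,
    }
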