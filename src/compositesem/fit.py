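"""Normal-theory maximum-likelihood estimation.

Minimizes the ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over the free parameters of a :class:`ParameterTable`, with all affine
constraints (effects coding, sum-to-zero loadings) substituted out
exactly.  Standard errors come from the inverse expected information
scaled by the chi-square sample size; derived quantities (weights,
standardized coefficients) get delta-method standard errors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .covariance import CompiledTable
from .exceptions import (
    ConvergenceWarning,
    DegenerateSolutionError,
    HeywoodWarning,
    InputError,
)
from .moments import SampleMoments
from .table import ParameterTable


@dataclass
class FitResult:
    table: ParameterTable
    compiled: CompiledTable
    moments: SampleMoments          # ML (divisor n) convention, table order
    theta: np.ndarray
    estimates: dict[str, float]
    f_min: float
    loglik: float
    sigma: np.ndarray               # implied covariance of the observed variables
    sigma_full: np.ndarray          # implied covariance of all model variables
    converged: bool
    n_iter: int
    grad_norm: float
    retries_used: int = 0
    param_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def q(self) -> int:
        return self.compiled.q

    @property
    def dof(self) -> int:
        return self.table.dof()

    @property
    def p(self) -> int:
        return self.compiled.p

    def sd_of(self, name: str) -> float:
        i = self.compiled.index[name]
        var = self.sigma_full[i, i]
        if var <= 0:
            warnings.warn(
                f"implied variance of {name!r} is not positive ({var:.3g})",
                HeywoodWarning,
                stacklevel=2,
            )
            return np.nan
        return float(np.sqrt(var))

    def to_dict(self) -> dict:
        ses = standard_errors(self)
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standard_errors": {k: float(v) for k, v in ses.items()},
            "discrepancy": float(self.f_min),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "q": self.q,
            "df": self.dof,
            "n": int(self.moments.n),
        }


def _default_starts(compiled: CompiledTable, moments: SampleMoments) -> np.ndarray:
    """Zero for free loadings/paths/covariances (zero loading starts are a
    good choice for composite loadings); sample-variance-based starts for
    variance parameters."""
    table = compiled.table
    obs = set(table.observed)
    block_of = {}
    for b in table.blocks:
        for name in b.composites:
            block_of[name] = b
    latent_of = {l.name: l for l in table.latents}
    x0 = np.zeros(compiled.q)
    for k, lab in enumerate(compiled.labels):
        row = compiled.row_of_label[lab]
        if row.start is not None:
            x0[k] = row.start
        elif row.role == "variance":
            name = row.source
            if name in obs:
                x0[k] = moments.variance(name)
            elif name in block_of:
                comps = block_of[name].components
                x0[k] = float(np.mean([moments.variance(c) for c in comps]))
            elif name in latent_of:
                x0[k] = 0.5 * moments.variance(latent_of[name].indicator)
            else:
                x0[k] = 1.0
        # loadings / paths / covariances default to 0
    return x0


def fit_ml(
    table: ParameterTable,
    moments: SampleMoments,
    *,
    seed: int = 0,
    max_retries: int = 3,
    gtol: float = 1e-8,
    maxiter: int = 2000,
) -> FitResult:
    """Fit a parameter table to sample moments by normal-theory ML.

    An unbiased (divisor n-1) input matrix is rescaled by (n-1)/n first,
    so the chi-square statistic ``n * F`` follows the divisor-n
    convention throughout.  Non-convergence sets the ``converged`` flag
    rather than raising; up to ``max_retries`` seeded jittered restarts
    are attempted.
    """
    compiled = CompiledTable(table)
    moments = moments.reorder(table.observed).as_ml()
    moments.check_positive_definite()
    moments.warn_if_small()
    S = moments.S
    x0 = _default_starts(compiled, moments)
    rng = np.random.default_rng(seed)

    def fun(theta):
        f, g = compiled.discrepancy(theta, S)
        if not np.isfinite(f):
            return np.inf, np.zeros(compiled.q)
        return f, g

    variance_ix = np.array(
        [compiled.row_of_label[lab].role == "variance" for lab in compiled.labels]
    )

    def feasible_start(x):
        for _ in range(30):
            if np.isfinite(fun(x)[0]):
                return x
            x = x + rng.normal(scale=0.1 * (1.0 + np.abs(x)))
            if variance_ix.any():
                x[variance_ix] = np.abs(x[variance_ix]) + 1e-3
        return x

    best = None
    retries_used = 0
    for attempt in range(max_retries + 1):
        if attempt == 0:
            x_init = x0.copy()
        else:
            retries_used += 1
            x_init = x0 + rng.normal(scale=0.1 * (1.0 + np.abs(x0)))
            if variance_ix.any():
                x_init[variance_ix] = np.abs(x_init[variance_ix]) + 1e-3
        x_init = feasible_start(x_init)
        if compiled.q == 0:
            res_x, res_nit = x_init, 0
        else:
            res = scipy.optimize.minimize(
                fun, x_init, jac=True, method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            res_x, res_nit = res.x, res.nit
        f, g = compiled.discrepancy(res_x, S)
        gnorm = float(np.max(np.abs(g))) if compiled.q else 0.0
        ok = np.isfinite(f) and gnorm <= 1e-6
        cand = (ok, f, gnorm, res_x, res_nit)
        if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
            best = cand
        if ok:
            break

    ok, f, gnorm, theta, nit = best
    if not ok:
        warnings.warn(
            f"ML estimation did not reach gradient norm 1e-6 (got {gnorm:.2e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    A, Psi = compiled.resolve(theta)
    M = compiled.M(A)
    sigma_full = M @ Psi @ M.T
    sigma_full = (sigma_full + sigma_full.T) / 2.0
    sigma = sigma_full[np.ix_(compiled.obs_idx, compiled.obs_idx)]
    n, p = moments.n, compiled.p
    sign, logdet = np.linalg.slogdet(sigma)
    if sign > 0:
        tr = float(np.trace(S @ np.linalg.inv(sigma)))
        loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet + tr)
    else:
        loglik = -np.inf
    return FitResult(
        table=table,
        compiled=compiled,
        moments=moments,
        theta=np.asarray(theta, dtype=float),
        estimates={lab: float(v) for lab, v in zip(compiled.labels, theta)},
        f_min=float(max(f, 0.0)) if np.isfinite(f) else float(f),
        loglik=loglik,
        sigma=sigma,
        sigma_full=sigma_full,
        converged=bool(ok),
        n_iter=int(nit),
        grad_norm=gnorm,
        retries_used=retries_used,
    )


# -- standard errors --------------------------------------------------

def parameter_covariance(fit: FitResult) -> np.ndarray | None:
    """Inverse expected information at theta-hat, scaled by the
    chi-square sample size n."""
    if fit.param_cov is not None:
        return fit.param_cov
    if fit.q == 0:
        fit.param_cov = np.zeros((0, 0))
        return fit.param_cov
    D = fit.compiled.dsigma(fit.theta)
    Sinv = np.linalg.inv(fit.sigma)
    T = np.einsum("ab,kbc->kac", Sinv, D)
    info = 0.5 * np.einsum("jab,kba->jk", T, T)
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "expected information matrix is (near) singular; standard errors "
            "are undefined",
            ConvergenceWarning,
            stacklevel=2,
        )
        fit.param_cov = None
        return None
    fit.param_cov = np.linalg.inv(info) / fit.moments.n
    return fit.param_cov


def standard_errors(fit: FitResult) -> dict[str, float]:
    acov = parameter_covariance(fit)
    if acov is None:
        return {lab: float("nan") for lab in fit.compiled.labels}
    se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    return {lab: float(s) for lab, s in zip(fit.compiled.labels, se)}


def delta_method_se(fit: FitResult, func, *, rel_step: float = 1e-6) -> np.ndarray:
    """SEs of ``func(theta)`` (vector-valued) by the delta method with
    central-difference gradients."""
    acov = parameter_covariance(fit)
    g0 = np.atleast_1d(np.asarray(func(fit.theta), dtype=float))
    if acov is None:
        return np.full(g0.shape, np.nan)
    J = np.empty((g0.size, fit.q))
    for k in range(fit.q):
        h = rel_step * max(1.0, abs(fit.theta[k]))
        tp = fit.theta.copy(); tp[k] += h
        tm = fit.theta.copy(); tm[k] -= h
        J[:, k] = (
            np.atleast_1d(func(tp)).ravel() - np.atleast_1d(func(tm)).ravel()
        ) / (2 * h)
    var = np.einsum("ij,jk,ik->i", J, acov, J)
    return np.sqrt(np.maximum(var, 0.0))


# -- weights ----------------------------------------------------------

def _loading_matrix(compiled: CompiledTable, theta, block) -> np.ndarray:
    """k x k block loading matrix: rows = components, columns = composite
    of interest then excrescent variables."""
    A, _ = compiled.resolve(theta)
    rows = [compiled.index[c] for c in block.components]
    cols = [compiled.index[c] for c in block.composites]
    return A[np.ix_(rows, cols)]


def _block_info(fit: FitResult, block):
    if isinstance(block, str):
        for b in fit.table.blocks:
            if b.name == block:
                return b
        raise KeyError(block)
    for b in fit.table.blocks:
        if b.name == getattr(block, "name", None):
            return b
    raise KeyError(getattr(block, "name", block))


def _weights_at(compiled, theta, binfo) -> np.ndarray:
    lam = _loading_matrix(compiled, theta, binfo)
    if abs(np.linalg.det(lam)) < 1e-12:
        raise DegenerateSolutionError(
            f"loading matrix of block {binfo.name!r} is singular"
        )
    w = np.linalg.inv(lam)[0, :]
    return w * _block_sign(compiled, theta, binfo)


def _block_sign(compiled, theta, binfo) -> float:
    """Canonical sign for variance-standardized composites: the sum of
    the composite-of-interest loadings is taken positive."""
    if binfo.scale_method != "variance_std":
        return 1.0
    lam = _loading_matrix(compiled, theta, binfo)
    return 1.0 if lam[:, 0].sum() >= 0 else -1.0


def recover_weights(fit: FitResult, block) -> pd.Series:
    """Composite weights as the first row of the inverted block loading
    matrix (the weight form of the loading parameterization)."""
    binfo = _block_info(fit, block)
    w = _weights_at(fit.compiled, fit.theta, binfo)
    return pd.Series(w, index=list(binfo.components), name=f"w_{binfo.name}")


def weights_se(fit: FitResult, block) -> pd.Series:
    binfo = _block_info(fit, block)
    se = delta_method_se(fit, lambda t: _weights_at(fit.compiled, t, binfo))
    return pd.Series(se, index=list(binfo.components), name=f"se_w_{binfo.name}")


def standardized_weights(fit: FitResult, block) -> pd.Series:
    """w_std_i = w_i * sd(x_i) / sd(c), with both standard deviations
    taken from the model-implied covariance matrix."""
    binfo = _block_info(fit, block)
    w = _weights_at(fit.compiled, fit.theta, binfo)
    sds = np.array([fit.sd_of(c) for c in binfo.components])
    sd_c = fit.sd_of(binfo.name)
    return pd.Series(
        w * sds / sd_c, index=list(binfo.components), name=f"wstd_{binfo.name}"
    )


# -- standardized solution -------------------------------------------

def _signs_for(compiled, theta) -> dict[str, float]:
    return {
        b.name: _block_sign(compiled, theta, b)
        for b in compiled.table.blocks
    }


def _std_entries(compiled: CompiledTable, theta, rows) -> np.ndarray:
    A, Psi = compiled.resolve(theta)
    M = compiled.M(A)
    full = M @ Psi @ M.T
    sd = np.sqrt(np.maximum(np.diag(full), 0.0))
    signs = _signs_for(compiled, theta)
    out = np.empty(len(rows))
    for r, row in enumerate(rows):
        i, j = compiled.index[row.target], compiled.index[row.source]
        s = signs.get(row.source, 1.0) * signs.get(row.target, 1.0)
        if row.role in ("path", "loading"):
            if sd[i] == 0:
                raise ZeroDivisionError(
                    f"implied variance of {row.target!r} is zero"
                )
            out[r] = s * A[i, j] * sd[j] / sd[i]
        else:  # covariance
            denom = sd[i] * sd[j]
            out[r] = s * full[i, j] / denom if denom > 0 else np.nan
    return out


def _solution_rows(table: ParameterTable, include_nuisance: bool):
    """Path and free-covariance rows of the structural solution.

    Rows tied to the composite parameterization rather than the
    structural model -- weight rows (component -> composite), rows
    involving excrescent variables, and covariances among block
    components -- are nuisance terms and excluded by default.
    """
    excrescent = {nu for b in table.blocks for nu in b.composites[1:]}
    components = {c for b in table.blocks for c in b.components}
    weight_cells = {
        (c, b.name) for b in table.blocks for c in b.components
    }
    rows = [
        r for r in table.rows
        if (r.role == "path" and r.status != "fixed"
            and (r.source, r.target) not in weight_cells)
        or (r.role == "covariance" and r.status == "free")
    ]
    if not include_nuisance:
        rows = [
            r for r in rows
            if r.source not in excrescent and r.target not in excrescent
            and not (
                r.role == "covariance"
                and r.source in components
                and r.target in components
            )
        ]
    return rows


def standardized_solution(
    fit: FitResult, *, with_se: bool = False, include_nuisance: bool = False
) -> pd.DataFrame:
    """Standardized structural paths and covariances (correlations),
    using model-implied standard deviations."""
    rows = _solution_rows(fit.table, include_nuisance)
    if not rows:
        rows = [r for r in fit.table.rows if r.role == "path"]
    est = np.array([
        fit.estimates[r.label] if r.status == "free"
        else r.expr.evaluate(fit.estimates)
        for r in rows
    ])
    std = _std_entries(fit.compiled, fit.theta, rows)
    data = {
        "source": [r.source for r in rows],
        "target": [r.target for r in rows],
        "role": [r.role for r in rows],
        "est": est,
        "std": std,
    }
    if with_se:
        ses = standard_errors(fit)
        data["se"] = [ses.get(r.label, np.nan) for r in rows]
        data["se_std"] = delta_method_se(
            fit, lambda t: _std_entries(fit.compiled, t, rows)
        )
    return pd.DataFrame(data)
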