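"""Global fit assessment and nested-model comparison.

Chi-square scaling follows the divisor-n convention: the test statistic
is ``n * F_ML`` computed against the divisor-n sample covariance (an
unbiased input matrix is rescaled before fitting).  The baseline model
for the incremental indices is the independence model: all observed
variables uncorrelated with free variances, which has the closed-form
discrepancy ``F_b = sum(ln s_ii) - ln|S|``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import ConvergenceWarning, NotNestedError, SpecificationError
from .fit import FitResult
from .moments import SampleMoments


@dataclass(frozen=True)
class FitIndices:
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    srmr: float
    cfi: float
    tli: float
    aic: float
    bic: float
    sabic: float
    q: int
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class ChiSquareTest(NamedTuple):
    chi_square: float
    df: int
    p_value: float


class ChiSquareDifference(NamedTuple):
    delta_chi_square: float
    delta_df: int
    p_value: float


def chi_square_test(fit: FitResult, moments: SampleMoments | None = None) -> ChiSquareTest:
    """chi2 = n * F-hat; p from the upper tail at df = p(p+1)/2 - q."""
    n = (moments or fit.moments).n
    df = fit.dof
    chi2 = n * fit.f_min
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 <= 1e-10 else 0.0)
    return ChiSquareTest(float(chi2), int(df), p)


def independence_chi_square(moments: SampleMoments) -> ChiSquareTest:
    """Baseline (independence) model: uncorrelated observed variables
    with free variances; fitted in closed form."""
    m = moments.as_ml()
    sign, logdet = np.linalg.slogdet(m.S)
    f_b = float(np.sum(np.log(np.diag(m.S))) - logdet)
    df_b = m.p * (m.p - 1) // 2
    chi2 = m.n * f_b
    return ChiSquareTest(chi2, df_b, float(stats.chi2.sf(chi2, df_b)))


def fit_indices(fit: FitResult, baseline: ChiSquareTest | None = None):
    """(RMSEA, SRMR, CFI, TLI) with conventional definitions."""
    chi2, df, _ = chi_square_test(fit)
    n = fit.moments.n
    if baseline is None:
        baseline = independence_chi_square(fit.moments)
    chi2_b, df_b = baseline.chi_square, baseline.df

    if df > 0:
        rmsea = float(np.sqrt(max((chi2 - df) / (df * n), 0.0)))
    else:
        rmsea = 0.0 if chi2 <= 1e-8 else float("nan")

    S = fit.moments.S
    sd = np.sqrt(np.diag(S))
    resid = (S - fit.sigma) / np.outer(sd, sd)
    iu = np.triu_indices(fit.p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0

    if df > 0 and df_b > 0:
        rb = chi2_b / df_b
        tli = (rb - chi2 / df) / (rb - 1.0) if rb != 1.0 else float("nan")
    else:
        tli = 1.0 if chi2 <= 1e-8 else float("nan")
    return rmsea, srmr, cfi, tli


def information_criteria(fit: FitResult):
    """(AIC, BIC, SABIC) from the normal log-likelihood at theta-hat."""
    q, n = fit.q, fit.moments.n
    m2ll = -2.0 * fit.loglik
    aic = m2ll + 2.0 * q
    bic = m2ll + q * np.log(n)
    sabic = m2ll + q * np.log((n + 2.0) / 24.0)
    return float(aic), float(bic), float(sabic)


def compute_fit_indices(fit: FitResult) -> FitIndices:
    chi2, df, p = chi_square_test(fit)
    rmsea, srmr, cfi, tli = fit_indices(fit)
    aic, bic, sabic = information_criteria(fit)
    return FitIndices(
        chi_square=chi2, df=df, p_value=p,
        rmsea=rmsea, srmr=srmr, cfi=cfi, tli=tli,
        aic=aic, bic=bic, sabic=sabic,
        q=fit.q, n=int(fit.moments.n),
    )


# -- nested comparison ------------------------------------------------

def _cell_map(table):
    cells = {}
    for row in table.rows:
        if row.role == "covariance":
            key = (frozenset((row.source, row.target)), row.role)
        else:
            key = (row.source, row.target, row.role)
        if row.status == "free":
            cells[key] = ("free",)
        elif row.status == "fixed":
            cells[key] = ("fixed", row.value)
        else:
            cells[key] = ("constrained", str(row.expr))
    return cells


def assert_nested(restricted, full) -> None:
    """Structural check that ``restricted``'s parameter set nests in
    ``full``'s: every cell of the restricted table must be free in the
    full table or determined identically in both; cells absent from a
    table are implicitly fixed at zero."""
    if set(restricted.observed) != set(full.observed):
        raise NotNestedError("models are defined over different observed variables")
    if set(restricted.variables) != set(full.variables):
        raise NotNestedError("models are defined over different model variables")
    rmap, fmap = _cell_map(restricted), _cell_map(full)
    for key in set(rmap) | set(fmap):
        rs = rmap.get(key, ("fixed", 0.0))
        fs = fmap.get(key, ("fixed", 0.0))
        if fs == ("free",) or fs == rs:
            continue
        raise NotNestedError(f"cell {key} is {rs} in the restricted model but {fs} "
                             "in the full model")


def chi_square_difference(restricted: FitResult, full: FitResult) -> ChiSquareDifference:
    """Likelihood-ratio (chi-square difference) test of nested fits to
    the same moments."""
    if set(restricted.moments.names) != set(full.moments.names):
        raise NotNestedError("fits were not computed on identical sample moments")
    if restricted.moments.n != full.moments.n or not np.allclose(
        restricted.moments.reorder(full.moments.names).S, full.moments.S, atol=1e-10
    ):
        raise NotNestedError("fits were not computed on identical sample moments")
    assert_nested(restricted.table, full.table)
    c_r = chi_square_test(restricted)
    c_f = chi_square_test(full)
    d_chi2 = c_r.chi_square - c_f.chi_square
    d_df = c_r.df - c_f.df
    if d_chi2 < -1e-6 * max(1.0, c_f.chi_square):
        warnings.warn(
            f"negative chi-square difference ({d_chi2:.3g}); one of the fits "
            "has likely not converged",
            ConvergenceWarning,
            stacklevel=2,
        )
    if d_df > 0:
        p = float(stats.chi2.sf(max(d_chi2, 0.0), d_df))
    else:
        p = 1.0 if d_chi2 <= 1e-8 else 0.0
    return ChiSquareDifference(float(d_chi2), int(d_df), p)
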