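"""Covariance engine.

Maps a :class:`~compositesem.table.ParameterTable` and free-parameter
values to the model-implied covariance matrix using an all-endogenous
(RAM-style) representation: all model variables -- observed variables,
composites, excrescent variables, latents -- share one ordering, with

    Sigma_full = (I - A)^-1 Psi (I - A)^-T,       Sigma = G Sigma_full G',

where ``A`` holds loadings and structural coefficients, ``Psi`` the
exogenous/residual (co)variances and ``G`` selects the observed rows.
Because every matrix entry is affine in the free parameters, the engine
also provides exact analytic derivatives of Sigma, used by the ML
gradient and the expected-information standard errors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CyclicModelError, InputError
from .moments import SampleMoments
from .table import ParameterTable


class CompiledTable:
    """Affine maps theta -> (A, Psi) precompiled from a parameter table."""

    def __init__(self, table: ParameterTable):
        table.validate()
        self.table = table
        self.variables = table.variables
        self.index = {v: i for i, v in enumerate(self.variables)}
        self.m = len(self.variables)
        self.obs_idx = np.array([self.index[v] for v in table.observed])
        self.p = len(table.observed)
        self.labels = table.free_labels
        self.q = len(self.labels)
        label_pos = {lab: k for k, lab in enumerate(self.labels)}

        self.A0 = np.zeros((self.m, self.m))
        self.Psi0 = np.zeros((self.m, self.m))
        # triplet lists per free parameter: (matrix, i, j, coef)
        self.A_terms: list[list[tuple[int, int, float]]] = [[] for _ in range(self.q)]
        self.P_terms: list[list[tuple[int, int, float]]] = [[] for _ in range(self.q)]
        self.starts = np.zeros(self.q)
        self._start_set = np.zeros(self.q, dtype=bool)
        self.row_of_label: dict[str, object] = {}

        for row in table.rows:
            if row.role in ("loading", "path"):
                i, j = self.index[row.target], self.index[row.source]
                positions = [(i, j)]
                mats = [("A", 1.0)]
            elif row.role == "variance":
                i = self.index[row.source]
                positions = [(i, i)]
                mats = [("P", 1.0)]
            else:  # covariance
                i, j = self.index[row.source], self.index[row.target]
                positions = [(i, j), (j, i)]
                mats = [("P", 1.0), ("P", 1.0)]

            if row.status == "fixed":
                affine = {"const": row.value, "terms": ()}
            elif row.status == "free":
                affine = {"const": 0.0, "terms": ((row.label, 1.0),)}
                k = label_pos[row.label]
                self.row_of_label[row.label] = row
                if row.start is not None:
                    self.starts[k] = row.start
                    self._start_set[k] = True
            else:
                affine = {"const": row.expr.const, "terms": row.expr.terms}

            for (i, j), (mat, _) in zip(positions, mats):
                target0 = self.A0 if mat == "A" else self.Psi0
                target0[i, j] += affine["const"]
                terms = self.A_terms if mat == "A" else self.P_terms
                for lab, coef in affine["terms"]:
                    terms[label_pos[lab]].append((i, j, coef))

    # -- resolution --------------------------------------------------
    def resolve(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.q,):
            raise InputError(f"theta must have length q = {self.q}")
        A = self.A0.copy()
        Psi = self.Psi0.copy()
        for k, val in enumerate(theta):
            for i, j, coef in self.A_terms[k]:
                A[i, j] += coef * val
            for i, j, coef in self.P_terms[k]:
                Psi[i, j] += coef * val
        return A, Psi

    def selection(self) -> np.ndarray:
        G = np.zeros((self.p, self.m))
        G[np.arange(self.p), self.obs_idx] = 1.0
        return G

    def M(self, A: np.ndarray) -> np.ndarray:
        eye = np.eye(self.m)
        try:
            M = np.linalg.solve(eye - A, eye)
        except np.linalg.LinAlgError:
            raise CyclicModelError("I - A is singular; the model is cyclic")
        return M

    def full_sigma(self, theta: np.ndarray) -> np.ndarray:
        A, Psi = self.resolve(theta)
        M = self.M(A)
        full = M @ Psi @ M.T
        return (full + full.T) / 2.0

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return self.full_sigma(theta)[np.ix_(self.obs_idx, self.obs_idx)]

    # -- ML discrepancy and gradient ---------------------------------
    def discrepancy(self, theta: np.ndarray, S: np.ndarray):
        """F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p and its gradient.

        Returns ``(inf, nan-gradient)`` when Sigma is not positive
        definite, which the line search treats as an infeasible step.
        """
        A, Psi = self.resolve(theta)
        M = self.M(A)
        P = M @ Psi @ M.T
        Sigma = P[np.ix_(self.obs_idx, self.obs_idx)]
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return np.inf, np.full(self.q, np.nan)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Sinv = np.linalg.inv(Sigma)
        sign_s, logdet_s = np.linalg.slogdet(S)
        F = logdet + np.trace(S @ Sinv) - logdet_s - self.p

        # gradient: dF = tr(C dSigma), C = Sigma^-1 (Sigma - S) Sigma^-1
        C = Sinv - Sinv @ S @ Sinv
        W = np.zeros((self.m, self.m))
        W[np.ix_(self.obs_idx, self.obs_idx)] = C
        Q = P @ W @ M          # tr(W dM Psi M') = tr(Q dA)
        U = M.T @ W @ M        # tr(W M dPsi M') = tr(U dPsi)
        grad = np.empty(self.q)
        for k in range(self.q):
            g = 0.0
            for i, j, coef in self.A_terms[k]:
                g += 2.0 * coef * Q[j, i]
            for i, j, coef in self.P_terms[k]:
                g += coef * U[j, i]
            grad[k] = g
        return F, grad

    def dsigma(self, theta: np.ndarray) -> np.ndarray:
        """Analytic derivatives of the observed Sigma, shape (q, p, p)."""
        A, Psi = self.resolve(theta)
        M = self.M(A)
        P = M @ Psi @ M.T
        out = np.zeros((self.q, self.p, self.p))
        obs = self.obs_idx
        for k in range(self.q):
            dA = np.zeros((self.m, self.m))
            for i, j, coef in self.A_terms[k]:
                dA[i, j] += coef
            dPsi = np.zeros((self.m, self.m))
            for i, j, coef in self.P_terms[k]:
                dPsi[i, j] += coef
            T1 = M @ dA @ P
            dfull = T1 + T1.T + M @ dPsi @ M.T
            out[k] = dfull[np.ix_(obs, obs)]
        return out


# -- public operations ------------------------------------------------

def resolve_constraints(table: ParameterTable, theta):
    """Evaluate all constrained/fixed rows: returns (B, Psi, G)."""
    compiled = CompiledTable(table)
    A, Psi = compiled.resolve(np.asarray(theta, dtype=float))
    return A, Psi, compiled.selection()


def implied_covariance(B, Psi, G) -> np.ndarray:
    """Sigma = G (I - B)^-1 Psi (I - B)^-T G'."""
    B = np.asarray(B, dtype=float)
    m = B.shape[0]
    try:
        M = np.linalg.solve(np.eye(m) - B, np.eye(m))
    except np.linalg.LinAlgError:
        raise CyclicModelError("I - B is singular; the model is cyclic")
    Sigma = G @ M @ Psi @ M.T @ G.T
    return (Sigma + Sigma.T) / 2.0


def two_step_reduce(
    moments: SampleMoments,
    blocks,
    weights: dict[str, np.ndarray] | None = None,
) -> SampleMoments:
    """Replace each block's components by a composite score (unit weights
    by default) and pass all other variables through: returns T S T'."""
    weights = weights or {}
    names = list(moments.names)
    comp_names = [b.name for b in blocks]
    passthrough = [
        v for v in names
        if not any(v in b.components for b in blocks)
    ]
    T = np.zeros((len(comp_names) + len(passthrough), len(names)))
    for r, b in enumerate(blocks):
        w = np.asarray(weights.get(b.name, np.ones(len(b.components))), dtype=float)
        for c, wi in zip(b.components, w):
            if c not in names:
                raise InputError(f"weight refers to unknown variable {c!r}")
            T[r, names.index(c)] = wi
    for r, v in enumerate(passthrough):
        T[len(comp_names) + r, names.index(v)] = 1.0
    return SampleMoments(
        names=tuple(comp_names) + tuple(passthrough),
        S=T @ moments.S @ T.T,
        n=moments.n,
        divisor=moments.divisor,
    )


@dataclass
class IdentificationReport:
    rank: int
    q: int
    deficient: bool
    null_space_labels: tuple[str, ...]
    singular_values: np.ndarray


def check_local_identification(
    table: ParameterTable,
    theta0=None,
    *,
    seed: int = 0,
    n_perturbations: int = 2,
    rel_step: float = 1e-6,
    rank_tol: float = 1e-8,
) -> IdentificationReport:
    """Local identification diagnostic.

    Computes the finite-difference Jacobian of vech(Sigma) with respect
    to theta at ``theta0`` and at small random perturbations of it, and
    reports the (maximal) numerical rank.  Rank < q flags an unidentified
    direction; the labels loading on the null space are reported.
    """
    compiled = CompiledTable(table)
    rng = np.random.default_rng(seed)
    if theta0 is None:
        theta0 = _random_admissible(compiled, rng)
    theta0 = np.asarray(theta0, dtype=float)
    if compiled.q == 0:
        return IdentificationReport(0, 0, False, (), np.array([]))

    iu = np.triu_indices(compiled.p)

    def vech_sigma(theta):
        return compiled.sigma(theta)[iu]

    def jacobian(theta):
        J = np.empty((len(iu[0]), compiled.q))
        for k in range(compiled.q):
            h = rel_step * max(1.0, abs(theta[k]))
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            J[:, k] = (vech_sigma(tp) - vech_sigma(tm)) / (2 * h)
        return J

    points = [theta0] + [
        theta0 + rng.normal(scale=0.05, size=compiled.q)
        for _ in range(n_perturbations)
    ]
    best_rank = -1
    best_sv = None
    best_V = None
    for point in points:
        try:
            J = jacobian(point)
        except CyclicModelError:
            continue
        _, sv, Vt = np.linalg.svd(J, full_matrices=True)
        tol = rank_tol * (sv[0] if len(sv) else 1.0)
        rank = int(np.sum(sv > tol))
        if rank > best_rank:
            best_rank, best_sv, best_V = rank, sv, Vt
    if best_rank < 0:
        raise CyclicModelError("Sigma is undefined at theta0 and all perturbations")
    null_labels: tuple[str, ...] = ()
    if best_rank < compiled.q:
        null_vecs = best_V[best_rank:, :]
        load = np.max(np.abs(null_vecs), axis=0)
        thresh = 0.3 * load.max() if load.max() > 0 else np.inf
        null_labels = tuple(
            lab for lab, l in zip(compiled.labels, load) if l >= thresh
        )
    return IdentificationReport(
        rank=best_rank,
        q=compiled.q,
        deficient=best_rank < compiled.q,
        null_space_labels=null_labels,
        singular_values=best_sv,
    )


def _random_admissible(compiled: CompiledTable, rng) -> np.ndarray:
    """Draw a generic admissible point: moderate loadings/paths, positive
    variances, small covariances."""
    theta = np.empty(compiled.q)
    for k, lab in enumerate(compiled.labels):
        row = compiled.row_of_label[lab]
        if row.role == "variance":
            theta[k] = rng.uniform(0.7, 1.3)
        elif row.role == "covariance":
            theta[k] = rng.uniform(-0.15, 0.15)
        else:
            theta[k] = rng.normal(0.4, 0.2)
    return theta
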