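"""Sample moments container."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InputError, SingularMomentsWarning


@dataclass(frozen=True)
class SampleMoments:
    """Covariance matrix ``S`` with variable names, sample size and the
    divisor convention used to compute it (``"ml"`` = divisor n,
    ``"unbiased"`` = divisor n - 1)."""

    names: tuple[str, ...]
    S: np.ndarray
    n: int
    divisor: str = "ml"

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] != len(self.names):
            raise InputError("covariance matrix shape does not match variable names")
        if not np.allclose(S, S.T, atol=1e-8):
            raise InputError("covariance matrix is asymmetric beyond 1e-8")
        object.__setattr__(self, "S", (S + S.T) / 2.0)
        if self.divisor not in ("ml", "unbiased"):
            raise InputError(f"unknown divisor convention {self.divisor!r}")
        if self.n is None:
            raise InputError("sample size n is required")

    @property
    def p(self) -> int:
        return len(self.names)

    def variance(self, name: str) -> float:
        return float(self.S[self.names.index(name), self.names.index(name)])

    def sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.S))

    def as_ml(self) -> "SampleMoments":
        """Rescale an unbiased (divisor n-1) matrix to the ML (divisor n)
        convention used by the discrepancy function and chi-square test."""
        if self.divisor == "ml":
            return self
        return replace(self, S=self.S * (self.n - 1) / self.n, divisor="ml")

    def reorder(self, names) -> "SampleMoments":
        names = tuple(names)
        missing = set(names) - set(self.names)
        if missing:
            raise InputError(f"moments are missing variables {sorted(missing)}")
        idx = [self.names.index(v) for v in names]
        return replace(self, names=names, S=self.S[np.ix_(idx, idx)])

    def check_positive_definite(self) -> None:
        try:
            np.linalg.cholesky(self.S)
        except np.linalg.LinAlgError:
            raise InputError("sample covariance matrix is not positive definite")

    def warn_if_small(self) -> None:
        if self.n < self.p:
            warnings.warn(
                f"n = {self.n} is smaller than the number of variables "
                f"p = {self.p}; sample moments are singular",
                SingularMomentsWarning,
                stacklevel=3,
            )


def moments_from_data(data, n=None, divisor: str = "ml") -> SampleMoments:
    """Compute sample moments from a rectangular data table."""
    import pandas as pd

    if isinstance(data, pd.DataFrame):
        names = tuple(map(str, data.columns))
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    nobs = X.shape[0]
    Xc = X - X.mean(axis=0)
    denom = nobs if divisor == "ml" else nobs - 1
    S = Xc.T @ Xc / denom
    return SampleMoments(names=names, S=S, n=nobs, divisor=divisor)
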