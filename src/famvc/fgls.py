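"""Fixed-effect burden (sum) test by feasible generalized least squares.

The comparator collapses a region into one per-individual burden score b and
tests its fixed-effect coefficient in y = Xβ + b·β_b + residual, using the
covariance V0 estimated once under the global null model (no burden) and
held fixed — feasible GLS.  The Wald chi-square on β_b is reported together
with a two-sided normal p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DimensionError
from .null_model import PolygenicResults

__all__ = ["FglsResult", "fgls_test"]


@dataclass
class FglsResult:
    """Burden-coefficient estimate, its SE and the Wald test."""

    beta_burden: float
    se: float
    statistic: float  # 1-df chi-square, = (beta/se)^2
    p: float

    @property
    def z(self) -> float:
        return self.beta_burden / self.se

    def summary(self) -> str:
        return "\n".join([
            "FGLS burden test",
            "-" * 34,
            f"beta_burden   {self.beta_burden:12.6f}",
            f"se            {self.se:12.6f}",
            f"chi2 (1 df)   {self.statistic:12.6f}",
            f"p             {self.p:12.4e}",
        ])

    def to_dict(self) -> dict:
        return {"beta_burden": self.beta_burden, "se": self.se,
                "statistic": self.statistic, "p": self.p}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def fgls_test(y, X, burden, fit: PolygenicResults) -> FglsResult:
    """Wald test of the burden coefficient under the null-model covariance.

    ``y``/``X`` default to the data held by the null fit when None.  The
    burden column is centered to match the fit's centering convention.
    """
    if not fit.converged:
        raise ValueError("null model fit did not converge")
    b = np.asarray(burden, dtype=float).ravel()
    yv = fit.model.y if y is None else np.asarray(y, float).ravel() - np.mean(y)
    Xv = fit.model.X if X is None else np.asarray(X, float)
    if b.shape[0] != yv.shape[0]:
        raise DimensionError("burden length does not match phenotype")
    if np.ptp(b) == 0:
        raise ValueError("burden score is constant")
    b = b - b.mean()
    Xstar = np.column_stack([Xv, b])
    VX = fit.v0_solve(Xstar)
    XtVX = Xstar.T @ VX
    # collinearity guard: condition of the augmented normal matrix
    if np.linalg.cond(XtVX) > 1e12:
        raise ValueError("burden is collinear with the covariates")
    cov = np.linalg.inv(XtVX)
    beta = cov @ (VX.T @ yv)
    bb = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = bb / se
    return FglsResult(beta_burden=bb, se=se, statistic=z * z,
                      p=float(2.0 * stats.norm.sf(abs(z))))
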