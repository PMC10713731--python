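"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q measures between-instrument heterogeneity around the IVW
fit and drives the fixed/random model choice (random iff its p < 0.05,
strict). The MR-Egger intercept tests directional pleiotropy.
Leave-one-out re-estimation flags single instruments that dominate the
causal estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import PleiotropyResult, _ivw_components, ivw, mr_egger, wald_ratio
from .exceptions import EstimationError
from .instruments import InstrumentSet

__all__ = [
    "HeterogeneityResult", "PleiotropyResult", "LeaveOneOutRow",
    "cochran_q", "leave_one_out", "pleiotropy_test",
]

MODEL_FIXED = "fixed"
MODEL_RANDOM = "random"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square upper-tail p and model choice."""

    q: float
    df: int
    pvalue: float
    model_selected: str


@dataclass(frozen=True)
class LeaveOneOutRow:
    """Re-estimate with one instrument removed."""

    dropped_snp: str
    theta: float
    se: float
    pvalue: float


def cochran_q(iset: InstrumentSet, theta_ivw: float | None = None) -> HeterogeneityResult:
    """Cochran's Q around the (fixed-effects) IVW estimate.

    Q = sum_j (beta_Y_j - theta*beta_X_j)² / se_Y_j² on k-1 degrees of
    freedom. The random-effects model is selected only when the
    chi-square upper-tail p is strictly below 0.05 (p = 0.05 keeps the
    fixed model).
    """
    k = iset.n_snp
    if k < 2:
        raise EstimationError("Cochran's Q requires >= 2 instruments")
    if theta_ivw is None:
        theta_ivw, _, _ = _ivw_components(iset)
    w = 1.0 / iset.se_out**2
    q = float(np.sum(w * (iset.beta_out - theta_ivw * iset.beta_exp) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    model = MODEL_RANDOM if p < 0.05 else MODEL_FIXED
    return HeterogeneityResult(q=q, df=df, pvalue=p, model_selected=model)


def leave_one_out(iset: InstrumentSet) -> list[LeaveOneOutRow]:
    """Re-estimate dropping each instrument in turn.

    Subsets use the fixed-effects IVW for comparability across rows
    (the Wald ratio when a single instrument remains); rows follow the
    parent set's order.
    """
    if iset.n_snp < 2:
        raise EstimationError("leave-one-out requires >= 2 instruments")
    rows = []
    for j, inst in enumerate(iset.instruments):
        sub = iset.drop(j)
        est = wald_ratio(sub.instruments[0]) if sub.n_snp == 1 else ivw(sub, "fixed")
        rows.append(
            LeaveOneOutRow(
                dropped_snp=inst.snp_id,
                theta=est.theta, se=est.se, pvalue=est.pvalue,
            )
        )
    return rows


def pleiotropy_test(iset: InstrumentSet) -> PleiotropyResult | None:
    """MR-Egger intercept test; None (not assessable) below 3 instruments."""
    if iset.n_snp < 3:
        return None
    _, intercept = mr_egger(iset)
    return intercept
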