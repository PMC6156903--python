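"""Logistic-regression comparators for the SNP-CpG interaction test.

LR-m1 enters the CpG as the binarized low/high label, LR-m2 as the raw
beta value; both fit Y ~ SNP + CpG + SNP x CpG by maximum likelihood and
test the interaction term with a 1-df likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

__all__ = ["LRResult", "DegenerateDesignError", "lr_interaction_test"]


class DegenerateDesignError(ValueError):
    """The design matrix cannot identify the interaction (constant predictor)."""


@dataclass
class LRResult:
    model_id: str  # "LR-m1" or "LR-m2"
    p_value: float  # nan when not converged
    lrt_stat: float
    df: int
    converged: bool


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", False):
        raise PerfectSeparationError("logit did not converge")
    # quasi-separated fits converge numerically but run the coefficients off
    # to infinity; treat them as non-converged like an outright separation
    if np.abs(res.params).max() > 1e3 or not np.isfinite(res.llf):
        raise PerfectSeparationError("divergent coefficients (separation)")
    return res


def lr_interaction_test(
    snp_coded,
    cpg_values,
    phenotype,
    cpg_mode: str = "continuous",
) -> LRResult:
    """Likelihood-ratio test of the SNP x CpG interaction term.

    The SNP enters as its numeric additive code, so the interaction carries
    one degree of freedom. ``cpg_mode="binary"`` expects the two-mean
    labels {0,1} (LR-m1); ``"continuous"`` the original beta values (LR-m2).
    Non-convergence or complete/quasi separation yields
    ``converged=False`` with a missing p-value.
    """
    if cpg_mode not in ("binary", "continuous"):
        raise ValueError(f"cpg_mode must be 'binary' or 'continuous', got {cpg_mode!r}")
    model_id = "LR-m1" if cpg_mode == "binary" else "LR-m2"
    g = np.asarray(snp_coded, dtype=float)
    m = np.asarray(cpg_values, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if not (g.shape == m.shape == y.shape):
        raise ValueError("snp, cpg and phenotype vectors differ in length")
    uniq = np.unique(y)
    if uniq.size != 2 or not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary with both classes present")
    if cpg_mode == "binary" and not np.isin(np.unique(m), (0.0, 1.0)).all():
        raise ValueError("binary mode expects CpG labels in {0,1}")
    if np.ptp(g) == 0 or np.ptp(m) == 0:
        raise DegenerateDesignError("constant SNP or CpG predictor")

    ones = np.ones_like(g)
    X_full = np.column_stack([ones, g, m, g * m])
    X_red = X_full[:, :3]
    try:
        full = _fit_logit(y, X_full)
        red = _fit_logit(y, X_red)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LRResult(model_id=model_id, p_value=np.nan, lrt_stat=np.nan, df=1, converged=False)
    lrt = max(0.0, 2.0 * (full.llf - red.llf))
    p = float(stats.chi2.sf(lrt, 1))
    return LRResult(model_id=model_id, p_value=p, lrt_stat=lrt, df=1, converged=True)
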