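"""Maximum-likelihood tetrachoric correlation for exchangeable sibling pairs.

Under the liability-threshold model each pair member carries a latent
standard-normal liability; a member is affected iff liability exceeds a
cutoff t.  For an exchangeable pair with common cutoff and latent correlation
rho, the collapsed cell probabilities are

    P11 = P(X > t, Y > t | rho)          (both affected)
    P10 = (1 - Phi(t)) - P11             (one particular member affected)
    P00 = 1 - 2 (1 - Phi(t)) + P11       (neither affected)

and the multinomial log-likelihood of a collapsed table is
``n11 log P11 + n10 log(2 P10) + n00 log P00`` — the discordant cell carries
the factor 2 because member order is not observed.

The birth-year-adjusted variant replaces the common cutoff with member
specific cutoffs t_i = b0 + b1 (birth_year_i - reference_year), fitted on
pair-level data.

Optimisation runs on a transformed scale (the cutoff directly — already a
probit of the implied prevalence — and atanh(rho)), with multistart to guard
against flat likelihoods in sparse tables.  Standard errors come from the
numerically differentiated observed information, mapped back to the natural
rho scale by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess2

from .bvn import orthant_upper
from .descriptives import PairTable

__all__ = [
    "TetrachoricFit",
    "cell_probabilities",
    "fit_tetrachoric",
    "fit_tetrachoric_adjusted",
]

_LOGLIK_TOL = 1e-8
_RHO_STARTS = (0.0, 0.3, -0.3)
_RHO_CAP = 0.999999


@dataclass
class TetrachoricFit:
    """Result of a tetrachoric ML fit.

    ``threshold`` holds the common cutoff for collapsed fits;
    ``threshold_params`` holds (b0, b1) for birth-year-adjusted fits
    (exactly one of the two is set).
    """

    rho: float
    se_rho: float
    loglik: float
    converged: bool
    n_pairs: int
    threshold: float | None = None
    threshold_params: tuple[float, float] | None = None
    se_threshold: float | None = None
    relationship: str | None = None
    cov: np.ndarray | None = field(default=None, repr=False)


def cell_probabilities(t: float, rho: float) -> tuple[float, float, float]:
    """Collapsed cell probabilities (P11, P10, P00) at common cutoff ``t``.

    P10 is the probability that one *particular* member is affected; the
    collapsed discordant probability is 2*P10.  The three collapsed cells
    P11 + 2*P10 + P00 sum to one by construction.
    """
    p11 = orthant_upper(t, t, rho)
    q = norm.sf(t)
    p10 = q - p11
    p00 = 1.0 - 2.0 * q + p11
    return p11, p10, p00


def _collapsed_nll(params: np.ndarray, n11: int, n10: int, n00: int) -> float:
    t, z = params
    rho = np.tanh(z)
    p11, p10, p00 = cell_probabilities(t, rho)
    if p11 <= 0.0 or p10 <= 0.0 or p00 <= 0.0:
        return np.inf
    ll = 0.0
    if n11:
        ll += n11 * np.log(p11)
    if n10:
        ll += n10 * np.log(2.0 * p10)
    if n00:
        ll += n00 * np.log(p00)
    return -ll


def _minimize_multistart(fun, starts, args=()):
    best = None
    for x0 in starts:
        res = minimize(
            fun, x0, args=args, method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=_LOGLIK_TOL * 1e-2, maxiter=20000,
                         maxfev=20000),
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return best


def fit_tetrachoric(table: PairTable) -> TetrachoricFit:
    """ML tetrachoric correlation from a collapsed exchangeable pair table.

    Parameters
    ----------
    table : PairTable
        Collapsed counts; ``total`` must be positive and at least two cells
        nonzero for an interior maximum to exist.

    Returns
    -------
    TetrachoricFit
        MLE of (threshold, rho) with delta-method standard errors.  Tables
        with an empty affected margin (n11 = n10 = 0) or perfect concordance
        pin rho to a boundary and are flagged ``converged=False``.
    """
    n11, n10, n00 = table.n11, table.n10, table.n00
    total = table.total
    if total <= 0:
        raise ValueError("empty pair table")

    if n11 == 0 and n10 == 0:
        # no affected individuals: threshold unbounded, rho at lower boundary
        return TetrachoricFit(
            rho=-1.0, se_rho=np.nan, loglik=0.0, converged=False,
            n_pairs=total, threshold=np.inf, relationship=table.relationship,
        )

    q0 = max((2 * n11 + n10) / (2.0 * total), 0.5 / total)
    t0 = norm.isf(min(q0, 1 - 1e-9))
    starts = [np.array([t0, np.arctanh(r)]) for r in _RHO_STARTS]
    best = _minimize_multistart(_collapsed_nll, starts, args=(n11, n10, n00))
    t_hat, z_hat = best.x
    rho_hat = float(np.tanh(z_hat))

    boundary = abs(rho_hat) > _RHO_CAP
    converged = bool(best.success) and not boundary and np.isfinite(best.fun)

    se_rho = np.nan
    se_t = np.nan
    cov_nat = None
    if converged:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess2(best.x, _collapsed_nll, args=(n11, n10, n00))
        try:
            cov = np.linalg.inv(hess)
            # delta method: d rho / d z = 1 - rho^2
            jac = np.diag([1.0, 1.0 - rho_hat**2])
            cov_nat = jac @ cov @ jac.T
            se_t = float(np.sqrt(max(cov_nat[0, 0], 0.0)))
            se_rho = float(np.sqrt(max(cov_nat[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            converged = False

    return TetrachoricFit(
        rho=float(np.clip(rho_hat, -1.0, 1.0)),
        se_rho=se_rho,
        loglik=float(-best.fun),
        converged=converged,
        n_pairs=total,
        threshold=float(t_hat),
        se_threshold=se_t,
        relationship=table.relationship,
        cov=cov_nat,
    )


# ---------------------------------------------------------------------------
# birth-year-adjusted pairwise likelihood
# ---------------------------------------------------------------------------

def _canonical_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Sort members within each pair and aggregate identical rows.

    The pairwise likelihood is exchangeable, so pairs are canonicalised by
    (affected, birth_year) and collapsed to unique rows with weights; this
    makes the likelihood cost scale with the number of distinct
    (outcome, birth-year) combinations, not the number of pairs.
    """
    a1 = pairs["affected_1"].to_numpy(int)
    a2 = pairs["affected_2"].to_numpy(int)
    b1 = pairs["birth_year_1"].to_numpy(float)
    b2 = pairs["birth_year_2"].to_numpy(float)
    # member with the larger (affected, birth_year) key first
    swap = (a2 > a1) | ((a2 == a1) & (b2 > b1))
    a1s = np.where(swap, a2, a1)
    a2s = np.where(swap, a1, a2)
    b1s = np.where(swap, b2, b1)
    b2s = np.where(swap, b1, b2)
    df = pd.DataFrame({"a1": a1s, "a2": a2s, "by1": b1s, "by2": b2s})
    return df.groupby(["a1", "a2", "by1", "by2"], sort=True).size().rename("w").reset_index()


def _adjusted_nll(params: np.ndarray, grp: pd.DataFrame, ref: float) -> float:
    z, b0, b1 = params
    rho = np.tanh(z)
    t1 = b0 + b1 * (grp["by1"].to_numpy() - ref)
    t2 = b0 + b1 * (grp["by2"].to_numpy() - ref)
    p11 = orthant_upper(t1, t2, rho)
    s1 = norm.sf(t1)
    s2 = norm.sf(t2)
    a1 = grp["a1"].to_numpy()
    a2 = grp["a2"].to_numpy()
    p = np.where(
        (a1 == 1) & (a2 == 1), p11,
        np.where(
            (a1 == 1) & (a2 == 0), s1 - p11,
            np.where((a1 == 0) & (a2 == 1), s2 - p11, 1.0 - s1 - s2 + p11),
        ),
    )
    if np.any(p <= 0.0):
        return np.inf
    return -float(np.dot(grp["w"].to_numpy(), np.log(p)))


def fit_tetrachoric_adjusted(
    pairs: pd.DataFrame,
    reference_year: float = 1980.0,
    relationship: str | None = None,
) -> TetrachoricFit:
    """Tetrachoric ML fit with a linear birth-year effect on the cutoff.

    Parameters
    ----------
    pairs : DataFrame
        One row per pair with columns ``affected_1``, ``affected_2``,
        ``birth_year_1``, ``birth_year_2``.
    reference_year : float
        Centering year for the cutoff regression t = b0 + b1*(year - ref).

    Returns
    -------
    TetrachoricFit
        With ``threshold_params`` = (b0, b1).  If the data show no birth-year
        variation the slope is not identifiable; the collapsed fit is
        returned instead, with a warning.
    """
    required = {"affected_1", "affected_2", "birth_year_1", "birth_year_2"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pair data must have columns {sorted(required)}")
    years = np.concatenate([pairs["birth_year_1"], pairs["birth_year_2"]])
    if np.ptp(years) == 0:
        warnings.warn(
            "no birth-year variation: slope not identifiable, "
            "falling back to the unadjusted collapsed fit",
            stacklevel=2,
        )
        n_aff = pairs["affected_1"].astype(int) + pairs["affected_2"].astype(int)
        table = PairTable(
            relationship or "pooled",
            int((n_aff == 2).sum()), int((n_aff == 1).sum()), int((n_aff == 0).sum()),
        )
        return fit_tetrachoric(table)

    grp = _canonical_pairs(pairs)
    n_pairs = int(grp["w"].sum())
    prev = (grp["w"] * (grp["a1"] + grp["a2"])).sum() / (2.0 * n_pairs)
    t0 = norm.isf(min(max(prev, 0.5 / (2 * n_pairs)), 1 - 1e-9))
    starts = [np.array([np.arctanh(r), t0, 0.0]) for r in _RHO_STARTS]
    best = _minimize_multistart(_adjusted_nll, starts, args=(grp, reference_year))
    z_hat, b0_hat, b1_hat = best.x
    rho_hat = float(np.tanh(z_hat))

    boundary = abs(rho_hat) > _RHO_CAP
    converged = bool(best.success) and not boundary and np.isfinite(best.fun)

    se_rho = np.nan
    cov_nat = None
    if converged:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess2(best.x, _adjusted_nll, args=(grp, reference_year))
        try:
            cov = np.linalg.inv(hess)
            jac = np.diag([1.0 - rho_hat**2, 1.0, 1.0])
            cov_nat = jac @ cov @ jac.T
            se_rho = float(np.sqrt(max(cov_nat[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            converged = False

    return TetrachoricFit(
        rho=float(np.clip(rho_hat, -1.0, 1.0)),
        se_rho=se_rho,
        loglik=float(-best.fun),
        converged=converged,
        n_pairs=n_pairs,
        threshold_params=(float(b0_hat), float(b1_hat)),
        relationship=relationship,
        cov=cov_nat,
    )
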