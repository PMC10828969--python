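"""ACE / AE liability-threshold variance-component estimation.

Liability is decomposed into additive-genetic (A), shared-environment (C)
and unique-environment (E) components with standardized variances
a2 + c2 + e2 = 1.  Under the sibling design the latent pair correlation is
structural:

    rho_stratum = k_A * a2 + c2,    k_A = 0.5 (full) or 0.25 (half sibs),

with shared environment fully shared in every stratum.  The joint likelihood
is the tetrachoric pairwise/multinomial likelihood summed over strata with
rho replaced by the structural correlation; thresholds follow a common
birth-year-linear probit model t = b0 + b1 * (year - reference).

Estimation maximizes the joint likelihood with variance components
constrained nonnegative (active set at zero); 95% confidence intervals come
from the delta method on the unconstrained observed information, so a
component estimated on the boundary can show a lower bound slightly below
zero — the familiar "0.00 (-0.00 to 0.01)" shape of biometric software
output.

With only one relationship stratum the ACE model is not identifiable: the
likelihood is flat along directions that keep k_A * a2 + c2 constant.  The
AE model (c2 = 0) is identifiable from a single stratum and then satisfies
a2 = min(1, 2 * rho_full).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess2

from .descriptives import PairTable
from .pedigree import K_ADDITIVE
from .tetrachoric import _adjusted_nll, _canonical_pairs, cell_probabilities

__all__ = [
    "BiometricFit",
    "implied_pair_correlation",
    "joint_neg_loglik",
    "fit_biometric",
    "likelihood_ratio",
]

_Z95 = norm.ppf(0.975)


@dataclass
class BiometricFit:
    """Fitted ACE or AE liability-threshold model."""

    model: str  # "ACE" | "AE"
    a2: float
    c2: float
    e2: float
    ci_a2: tuple[float, float] | None
    ci_c2: tuple[float, float] | None
    ci_e2: tuple[float, float] | None
    threshold_params: tuple[float, float]
    loglik: float
    converged: bool
    n_pairs: int
    n_free_params: int
    adjusted: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.loglik


def implied_pair_correlation(a2: float, c2: float, relationship: str) -> float:
    """Structural latent correlation k_A * a2 + c2 for a relationship stratum."""
    if a2 < 0 or c2 < 0:
        raise ValueError("variance components must be nonnegative")
    if a2 + c2 > 1:
        raise ValueError("a2 + c2 must not exceed 1")
    return K_ADDITIVE[relationship] * a2 + c2


def _prepare_strata(strata) -> list[tuple[str, str, object]]:
    """Normalise strata input to [(relationship, kind, payload), ...]."""
    prepared = []
    for rel, data in sorted(strata.items()):
        if rel not in K_ADDITIVE:
            raise ValueError(f"unknown relationship stratum {rel!r}")
        if isinstance(data, PairTable):
            prepared.append((rel, "table", data))
        elif isinstance(data, pd.DataFrame):
            prepared.append((rel, "pairs", _canonical_pairs(data)))
        else:
            raise TypeError("stratum data must be a PairTable or a pair-level DataFrame")
    return prepared


def _nll_prepared(theta, prepared, reference_year) -> float:
    """Joint negative log-likelihood; +inf outside the feasible rho region.

    Slightly negative variance components are evaluable (needed for numeric
    Hessians at active boundaries); only an implied |rho| >= 1 or a
    non-positive cell probability is infeasible.
    """
    a2, c2, b0, b1 = theta
    total = 0.0
    for rel, kind, payload in prepared:
        rho = K_ADDITIVE[rel] * a2 + c2
        if not abs(rho) < 1.0:
            return np.inf
        if kind == "table":
            p11, p10, p00 = cell_probabilities(b0, rho)
            if p11 <= 0 or p10 <= 0 or p00 <= 0:
                return np.inf
            tab: PairTable = payload
            ll = 0.0
            if tab.n11:
                ll += tab.n11 * np.log(p11)
            if tab.n10:
                ll += tab.n10 * np.log(2.0 * p10)
            if tab.n00:
                ll += tab.n00 * np.log(p00)
            total -= ll
        else:
            total += _adjusted_nll(
                np.array([np.arctanh(rho), b0, b1]), payload, reference_year
            )
    return float(total)


def joint_neg_loglik(theta, strata, reference_year: float = 1980.0) -> float:
    """Joint negative log-likelihood at theta = (a2, c2, b0[, b1]).

    ``strata`` maps relationship labels to either collapsed
    :class:`PairTable` objects (common cutoff ``b0``; ``b1`` inert) or
    pair-level DataFrames (member cutoffs b0 + b1*(year - reference)).
    Returns +inf when any implied stratum correlation leaves (-1, 1).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 3:
        theta = np.append(theta, 0.0)
    return _nll_prepared(theta, _prepare_strata(strata), reference_year)


def _pooled_threshold_start(prepared) -> float:
    n_aff = 0
    n_tot = 0
    for _, kind, payload in prepared:
        if kind == "table":
            n_aff += payload.n_affected
            n_tot += 2 * payload.total
        else:
            w = payload["w"].to_numpy()
            n_aff += int(np.dot(w, payload["a1"] + payload["a2"]))
            n_tot += 2 * int(w.sum())
    q = max(n_aff / n_tot, 0.5 / n_tot) if n_tot else 0.01
    return float(norm.isf(min(q, 1 - 1e-9)))


def fit_biometric(
    strata,
    model: str = "ACE",
    reference_year: float = 1980.0,
) -> BiometricFit:
    """Maximum-likelihood ACE or AE fit across relationship strata.

    Parameters
    ----------
    strata : mapping
        Relationship label -> PairTable (collapsed) or pair-level DataFrame;
        any pair-level stratum switches on the birth-year threshold slope.
    model : {"ACE", "AE"}
        AE fixes c2 = 0.

    Returns
    -------
    BiometricFit
        Standardized components normalized to a2 + c2 + e2 = 1, with 95%
        delta-method CIs from the unconstrained observed information.

    Raises
    ------
    ValueError
        For an ACE request on strata that do not include at least two
        distinct additive-sharing coefficients (flat likelihood along
        k_A*a2 + c2 = const).
    """
    model = model.upper()
    if model not in ("ACE", "AE"):
        raise ValueError("model must be 'ACE' or 'AE'")
    prepared = _prepare_strata(strata)
    if not prepared:
        raise ValueError("need at least one stratum")
    adjusted = any(kind == "pairs" for _, kind, _ in prepared)
    ks = {K_ADDITIVE[rel] for rel, _, _ in prepared}
    if model == "ACE" and len(ks) < 2:
        raise ValueError(
            "ACE is not identifiable from a single relatedness class: the "
            "likelihood is flat along k_A*a2 + c2 = const; fit AE or add a "
            "stratum with different additive sharing"
        )

    free_c2 = model == "ACE"
    b0_start = _pooled_threshold_start(prepared)

    def pack(x):
        """Free vector -> (a2, c2, b0, b1)."""
        if free_c2:
            a2, c2 = x[0], x[1]
            rest = x[2:]
        else:
            a2, c2 = x[0], 0.0
            rest = x[1:]
        b0 = rest[0]
        b1 = rest[1] if adjusted else 0.0
        return np.array([a2, c2, b0, b1])

    def nll_free(x):
        theta = pack(x)
        a2, c2 = theta[0], theta[1]
        if a2 < 0 or c2 < 0 or a2 + c2 > 1:
            return np.inf
        return _nll_prepared(theta, prepared, reference_year)

    starts = []
    for a0 in (0.1, 0.3, 0.6):
        x0 = [a0] + ([0.02] if free_c2 else []) + [b0_start] + ([0.0] if adjusted else [])
        starts.append(np.array(x0))

    best = None
    for x0 in starts:
        res = minimize(
            nll_free, x0, method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-10, maxiter=40000, maxfev=40000),
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    x_hat = best.x
    theta_hat = pack(x_hat)

    # active set: a component pinned to the boundary is reported as exactly 0
    if free_c2 and theta_hat[1] < 1e-6:
        def nll_c0(x):
            xfull = np.insert(x, 1, 0.0)
            return nll_free(xfull)
        x0 = np.delete(x_hat, 1)
        res0 = minimize(
            nll_c0, x0, method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-11, maxiter=40000, maxfev=40000),
        )
        if res0.fun <= best.fun + 1e-9:
            x_hat = np.insert(res0.x, 1, 0.0)
            theta_hat = pack(x_hat)
            best = res0

    a2_hat, c2_hat, b0_hat, b1_hat = theta_hat
    a2_hat = max(a2_hat, 0.0)
    c2_hat = max(c2_hat, 0.0)
    e2_hat = 1.0 - a2_hat - c2_hat
    loglik = -float(best.fun)
    converged = bool(np.isfinite(best.fun))

    # unconstrained observed information at the (possibly boundary) optimum
    n_free = (2 if free_c2 else 1) + 1 + (1 if adjusted else 0)
    free_hat = theta_hat[[0, 1, 2, 3]] if (free_c2 and adjusted) else (
        theta_hat[[0, 1, 2]] if free_c2 else (
            theta_hat[[0, 2, 3]] if adjusted else theta_hat[[0, 2]]
        )
    )

    def nll_unconstrained(x):
        if free_c2 and adjusted:
            theta = x
        elif free_c2:
            theta = np.append(x, 0.0)
        elif adjusted:
            theta = np.insert(x, 1, 0.0)
        else:
            theta = np.array([x[0], 0.0, x[1], 0.0])
        return _nll_prepared(np.asarray(theta, float), prepared, reference_year)

    ci_a2 = ci_c2 = ci_e2 = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess2(np.asarray(free_hat, float), nll_unconstrained)
        cov = np.linalg.inv(hess)

        def interval(est, var):
            # a non-positive diagonal signals a numerically singular
            # information matrix (flat ridge); report no interval
            if var <= 0 or not np.isfinite(var):
                return None
            half = _Z95 * np.sqrt(var)
            return (float(est - half), float(est + half))

        var_a2 = cov[0, 0]
        if free_c2:
            var_c2 = cov[1, 1]
            cov_ac = cov[0, 1]
        else:
            var_c2, cov_ac = 0.0, 0.0
        var_e2 = var_a2 + var_c2 + 2.0 * cov_ac
        ci_a2 = interval(a2_hat, var_a2)
        ci_e2 = interval(e2_hat, var_e2)
        if free_c2:
            ci_c2 = interval(c2_hat, var_c2)
    except np.linalg.LinAlgError:
        converged = False

    n_pairs = sum(
        payload.total if kind == "table" else int(payload["w"].sum())
        for _, kind, payload in prepared
    )
    return BiometricFit(
        model=model,
        a2=float(a2_hat),
        c2=float(c2_hat),
        e2=float(e2_hat),
        ci_a2=ci_a2,
        ci_c2=ci_c2,
        ci_e2=ci_e2,
        threshold_params=(float(b0_hat), float(b1_hat)),
        loglik=loglik,
        converged=converged,
        n_pairs=n_pairs,
        n_free_params=n_free,
        adjusted=adjusted,
    )


def likelihood_ratio(fit_full: BiometricFit, fit_reduced: BiometricFit):
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns ``(statistic, df, p_value)`` with the chi-square reference.
    For the ACE-vs-AE comparison the tested parameter (c2) sits on the
    boundary of its space under the null, so the nominal chi-square(1)
    p-value is conservative (the boundary reference is a 50:50 mixture of
    chi-square(0) and chi-square(1)).
    """
    if fit_full.n_free_params <= fit_reduced.n_free_params:
        raise ValueError("full model must have more free parameters than reduced")
    if fit_full.model == "AE" and fit_reduced.model == "ACE":
        raise ValueError("models are not nested in this order")
    if fit_full.n_pairs != fit_reduced.n_pairs:
        raise ValueError("fits are not on the same data")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -1e-4:
        raise ValueError(
            f"full-model likelihood below reduced ({stat=:.3g}): fits not nested "
            "or optimizer failure"
        )
    stat = max(stat, 0.0)
    df = fit_full.n_free_params - fit_reduced.n_free_params
    return stat, df, float(chi2.sf(stat, df))
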