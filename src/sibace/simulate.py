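"""Synthetic registry populations with kinship-structured liabilities.

The generator emulates the statistical structure the downstream analysis
assumes: family clusters of full and half siblings, a latent standard-normal
liability decomposed as

    y* = sqrt(a2) * A + sqrt(c2) * C + sqrt(e2) * E,     e2 = 1 - a2 - c2,

with the additive value A built from latent parental values
(A_child = (A_mother + A_father)/2 + Mendelian deviation of variance 1/2),
so that corr(A) is 0.5 between full siblings and 0.25 between half siblings;
C is drawn once per cluster and fully shared; E is individual.  An
individual is affected iff y* exceeds a birth-year-linear threshold
t(y) = t0 + slope * (y - reference_year).

Default parameters mirror the study conditions: a rare phenotype (baseline
prevalence 0.17%), birth cohorts 1950-2010, cluster-type mix tuned so the
selected-pair strata come out roughly 84% full / 5% maternal-half / 11%
paternal-half.

``simulate_pair_phenotypes`` is a direct bivariate shortcut (no pedigree)
for fast tests of the correlation and variance-component estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .descriptives import PairTable
from .pedigree import K_ADDITIVE

__all__ = [
    "SimulationParams",
    "simulate_registry",
    "simulate_pair_phenotypes",
    "simulate_study_tables",
]

#: Default mix of cluster types; "full_k" = full-sibling-only cluster of size
#: k, "mixed" = a full-sib core plus one half-sibling.  Chosen so selected
#: pair strata approximate the study's full/maternal-half/paternal-half split.
DEFAULT_CLUSTER_MIX = {"full_2": 0.50, "full_3": 0.25, "full_4": 0.086, "mixed": 0.164}


@dataclass
class SimulationParams:
    """Parameters of the synthetic registry generator.

    Exactly one of ``baseline_prevalence`` (in (0, 0.5)) and
    ``baseline_threshold`` (probit scale) must be given; they are related by
    t0 = Phi^-1(1 - prevalence) at the reference year.
    """

    n_clusters: int = 10_000
    cluster_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_MIX))
    paternal_half_fraction: float = 0.66
    a2: float = 0.29
    c2: float = 0.0
    baseline_prevalence: float | None = 0.0017
    baseline_threshold: float | None = None
    birth_year_slope: float = 0.01
    birth_year_range: tuple[int, int] = (1950, 2010)
    reference_year: int = 1980
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a2 < 0 or self.c2 < 0 or self.a2 + self.c2 > 1:
            raise ValueError("need a2 >= 0, c2 >= 0, a2 + c2 <= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if (self.baseline_prevalence is None) == (self.baseline_threshold is None):
            raise ValueError(
                "give exactly one of baseline_prevalence and baseline_threshold"
            )
        if self.baseline_prevalence is not None and not (
            0.0 < self.baseline_prevalence < 0.5
        ):
            raise ValueError("baseline_prevalence must lie in (0, 0.5)")
        if not 0.0 <= self.paternal_half_fraction <= 1.0:
            raise ValueError("paternal_half_fraction must lie in [0, 1]")
        mix = self.cluster_type_mix
        if set(mix) - set(DEFAULT_CLUSTER_MIX) or any(v < 0 for v in mix.values()):
            raise ValueError(f"cluster_type_mix keys must be {sorted(DEFAULT_CLUSTER_MIX)}")
        tot = sum(mix.values())
        if tot <= 0:
            raise ValueError("cluster_type_mix must have positive mass")
        self.cluster_type_mix = {k: mix.get(k, 0.0) / tot for k in DEFAULT_CLUSTER_MIX}
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError("birth_year_range must be (low, high)")

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2

    @property
    def threshold0(self) -> float:
        """Liability cutoff at the reference year."""
        if self.baseline_threshold is not None:
            return float(self.baseline_threshold)
        return float(norm.isf(self.baseline_prevalence))


def _child_additive(rng, a_mother, a_father):
    # Mendelian segregation: half the midparent variance is within-family
    return 0.5 * (a_mother + a_father) + np.sqrt(0.5) * rng.standard_normal(
        a_mother.shape
    )


def simulate_registry(params: SimulationParams) -> pd.DataFrame:
    """Generate a synthetic registry of sibling clusters.

    Returns
    -------
    DataFrame
        One row per child with columns ``person_id``, ``mother_id``,
        ``father_id``, ``sex``, ``birth_year``, ``is_twin``, ``affected``
        plus a diagnostic ``liability`` column.  Parents are latent: they
        receive ids but no rows.  Twins are never generated.  Output is
        deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    types = list(DEFAULT_CLUSTER_MIX)
    probs = np.array([params.cluster_type_mix[t] for t in types])
    draw = rng.choice(len(types), size=params.n_clusters, p=probs)

    sa, sc, se = np.sqrt(params.a2), np.sqrt(params.c2), np.sqrt(params.e2)
    lo, hi = params.birth_year_range
    t0 = params.threshold0

    frames = []
    person_counter = 0
    parent_counter = 0

    def parent_ids(m):
        nonlocal parent_counter
        ids = np.arange(parent_counter, parent_counter + m)
        parent_counter += m
        return ids

    for ti, tname in enumerate(types):
        m = int((draw == ti).sum())
        if m == 0:
            continue
        if tname.startswith("full_"):
            k = int(tname.split("_")[1])
            mothers = parent_ids(m)
            fathers = parent_ids(m)
            a_m = rng.standard_normal(m)
            a_f = rng.standard_normal(m)
            a_child = _child_additive(rng, np.repeat(a_m, k), np.repeat(a_f, k))
            c = np.repeat(rng.standard_normal(m), k)
            e = rng.standard_normal(m * k)
            mother_col = np.repeat(mothers, k)
            father_col = np.repeat(fathers, k)
        else:  # mixed: one full-sib core child + one half-sibling
            k = 2
            m1 = parent_ids(m)   # shared-core mother
            f1 = parent_ids(m)   # shared-core father
            m2 = parent_ids(m)   # alternative mother (paternal half-sib)
            f2 = parent_ids(m)   # alternative father (maternal half-sib)
            paternal = rng.random(m) < params.paternal_half_fraction
            a_m1 = rng.standard_normal(m)
            a_f1 = rng.standard_normal(m)
            a_m2 = rng.standard_normal(m)
            a_f2 = rng.standard_normal(m)
            # child 1: (m1, f1); child 2: (m2, f1) if paternal else (m1, f2)
            a_child = np.empty(2 * m)
            a_child[0::2] = _child_additive(rng, a_m1, a_f1)
            a_child[1::2] = _child_additive(
                rng,
                np.where(paternal, a_m2, a_m1),
                np.where(paternal, a_f1, a_f2),
            )
            mother_col = np.empty(2 * m, dtype=np.int64)
            father_col = np.empty(2 * m, dtype=np.int64)
            mother_col[0::2] = m1
            father_col[0::2] = f1
            mother_col[1::2] = np.where(paternal, m2, m1)
            father_col[1::2] = np.where(paternal, f1, f2)
            c = np.repeat(rng.standard_normal(m), k)
            e = rng.standard_normal(m * k)

        n_children = m * k
        liability = sa * a_child + sc * c + se * e
        birth_year = rng.integers(lo, hi + 1, size=n_children)
        sex = rng.choice(np.array(["male", "female"]), size=n_children)
        threshold = t0 + params.birth_year_slope * (birth_year - params.reference_year)
        affected = (liability > threshold).astype(np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.arange(person_counter, person_counter + n_children),
                    "mother_id": mother_col,
                    "father_id": father_col,
                    "sex": sex,
                    "birth_year": birth_year,
                    "is_twin": np.zeros(n_children, dtype=np.int8),
                    "affected": affected,
                    "liability": liability,
                }
            )
        )
        person_counter += n_children

    out = pd.concat(frames, ignore_index=True)
    # parent ids must never collide with person ids
    out["mother_id"] = out["mother_id"] + person_counter + 1
    out["father_id"] = out["father_id"] + person_counter + 1
    return out


def simulate_pair_phenotypes(
    rho: float,
    thresholds: tuple[float, float],
    n_pairs: int,
    seed: int,
    relationship: str = "pair",
) -> PairTable:
    """Dichotomized bivariate-normal pairs, collapsed to (n11, n10, n00).

    Draws ``n_pairs`` bivariate standard-normal liabilities with correlation
    ``rho``, cuts each member at its threshold, and collapses the outcomes.
    Expected cell fractions equal the corresponding orthant probabilities.
    """
    if not abs(rho) < 1:
        raise ValueError("need |rho| < 1")
    if n_pairs < 1:
        raise ValueError("need n_pairs >= 1")
    t1, t2 = thresholds
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_pairs)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n_pairs)
    y1 = z1 > t1
    y2 = z2 > t2
    n11 = int(np.sum(y1 & y2))
    n10 = int(np.sum(y1 ^ y2))
    return PairTable(relationship, n11, n10, n_pairs - n11 - n10)


def simulate_pair_level(
    rho: float,
    b0: float,
    b1: float,
    n_pairs: int,
    seed: int,
    birth_year_range: tuple[int, int] = (1950, 2010),
    reference_year: int = 1980,
    year_gap_sd: float = 0.0,
    relationship: str = "full",
) -> pd.DataFrame:
    """Pair-level phenotypes with member-specific birth-year cutoffs.

    Liabilities are bivariate standard normal with correlation ``rho``; a
    member born in year y is affected iff liability exceeds
    b0 + b1*(y - reference_year).  With ``year_gap_sd = 0`` both members
    share a birth year drawn uniformly (maximal within-pair year
    correlation); a positive value adds an independent rounded-normal gap to
    the second member, clipped to the range.
    """
    if not abs(rho) < 1:
        raise ValueError("need |rho| < 1")
    rng = np.random.default_rng(seed)
    lo, hi = birth_year_range
    by1 = rng.integers(lo, hi + 1, size=n_pairs)
    if year_gap_sd > 0:
        gap = np.rint(rng.normal(0.0, year_gap_sd, size=n_pairs))
        by2 = np.clip(by1 + gap, lo, hi).astype(int)
    else:
        by2 = by1.copy()
    z1 = rng.standard_normal(n_pairs)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n_pairs)
    t1 = b0 + b1 * (by1 - reference_year)
    t2 = b0 + b1 * (by2 - reference_year)
    return pd.DataFrame(
        {
            "relationship": relationship,
            "affected_1": (z1 > t1).astype(int),
            "affected_2": (z2 > t2).astype(int),
            "birth_year_1": by1,
            "birth_year_2": by2,
        }
    )


def simulate_study_tables(
    a2: float,
    c2: float,
    prevalence: float,
    n_pairs: dict[str, int],
    seed: int,
) -> dict[str, PairTable]:
    """Collapsed tables per relationship stratum under an ACE truth.

    Each stratum is simulated with latent correlation k_A * a2 + c2
    (k_A = 0.5 full, 0.25 half) and a common cutoff Phi^-1(1 - prevalence).
    Stratum seeds are derived from ``seed`` so strata are independent.
    """
    t = float(norm.isf(prevalence))
    out = {}
    for i, (rel, n) in enumerate(sorted(n_pairs.items())):
        rho = K_ADDITIVE[rel] * a2 + c2
        out[rel] = simulate_pair_phenotypes(
            rho, (t, t), n, seed=(seed * 97 + i) % (2**31 - 1), relationship=rel
        )
    return out
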