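import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sibace.bvn import orthant_upper
from sibace.datasets import all_pair_tables, pooled_half_table, selected_pair_tables


@pytest.fixture(scope="session")
def selected_tables():
    """Collapsed counts of the randomly selected analysis pairs."""
    return selected_pair_tables()


@pytest.fixture(scope="session")
def all_tables():
    """Collapsed counts of all sibling pairs before random selection."""
    return all_pair_tables()


@pytest.fixture(scope="session")
def pooled_half_selected(selected_tables):
    return pooled_half_table(selected_tables)


def make_registry(rows):
    """Hand-built registry frame from (person, mother, father, birth_year, is_twin, affected)."""
    df = pd.DataFrame(
        rows,
        columns=["person_id", "mother_id", "father_id", "birth_year", "is_twin", "affected"],
    )
    df["sex"] = "female"
    return df


@pytest.fixture
def mini_registry():
    """Two full sibs (A,B of M1/F1), one paternal half-sib (C of M2/F1)."""
    return make_registry(
        [
            ("A", "M1", "F1", 1970, 0, 0),
            ("B", "M1", "F1", 1972, 0, 1),
            ("C", "M2", "F1", 1975, 0, 0),
        ]
    )


def grid_search_tetrachoric(n11, n10, n00, t_range=(-3.0, 3.0), step=1e-3):
    """Exhaustive grid-search oracle for the collapsed tetrachoric MLE.

    Evaluates the exchangeable multinomial log-likelihood on the full
    (threshold, rho) lattice at the given resolution and returns the argmax.
    Independent of the package's optimizer.
    """
    t = np.arange(t_range[0], t_range[1] + step / 2, step)
    rho = np.arange(-0.999, 0.999 + step / 2, step)
    p11 = orthant_upper(t[:, None], t[:, None], rho[None, :])
    q = norm.sf(t)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.zeros_like(p11)
        if n11:
            ll = ll + n11 * np.log(p11)
        if n10:
            ll = ll + n10 * np.log(2.0 * (q - p11))
        if n00:
            ll = ll + n00 * np.log(1.0 - 2.0 * q + p11)
    ll[~np.isfinite(ll)] = -np.inf
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(t[i]), float(rho[j])
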