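"""Published collapsed pair counts for nervous system tumors.

Counts originate from a nationwide Swedish register study of nervous system
tumors among siblings born 1950-2010 (roughly 6.3 million individuals with
both parents known).  Two datasets are provided:

* ``selected_pair_tables`` — the analysis dataset after random selection of
  one sibling pair per family cluster (1,748,528 full-sibling pairs, 117,298
  maternal and 226,196 paternal half-sibling pairs);
* ``all_pair_tables`` — all possible sibling pairs prior to random
  selection, used in the study's sensitivity analysis.

These tables are the inputs for reproducing the published concordance rates
and tetrachoric correlations; the phenotype is rare (~0.17% of pair
members affected).
"""

from __future__ import annotations

from .descriptives import PairTable, pool_tables

__all__ = ["selected_pair_tables", "all_pair_tables", "pooled_half_table"]

_SELECTED = {
    "full": (25, 5934, 1742569),
    "maternal_half": (1, 330, 116967),
    "paternal_half": (1, 670, 225525),
}

_ALL_PAIRS = {
    "full": (53, 15185, 4127789),
    "maternal_half": (4, 3668, 1260820),
    "paternal_half": (8, 5148, 1611074),
}


def _build(counts: dict[str, tuple[int, int, int]]) -> dict[str, PairTable]:
    return {rel: PairTable(rel, *c) for rel, c in counts.items()}


def selected_pair_tables() -> dict[str, PairTable]:
    """Collapsed counts for the randomly selected (analysis) pairs."""
    return _build(_SELECTED)


def all_pair_tables() -> dict[str, PairTable]:
    """Collapsed counts for all sibling pairs before random selection."""
    return _build(_ALL_PAIRS)


def pooled_half_table(tables: dict[str, PairTable]) -> PairTable:
    """Pool the maternal and paternal half-sibling strata of a table set."""
    return pool_tables(
        [tables["maternal_half"], tables["paternal_half"]], relationship="half_pooled"
    )
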