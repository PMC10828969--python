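"""Collapsed pair tables, prevalence and probandwise concordance.

An exchangeable sibling pair with a binary phenotype collapses to three
counts: both affected (``n11``), discordant (``n10``), both unaffected
(``n00``).  Probandwise (casewise) concordance, 2*n11 / (2*n11 + n10), is the
probability that the co-sibling of a randomly chosen affected pair member is
also affected; it is the descriptive statistic quoted alongside liability
models in twin and sibling studies of disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PairTable",
    "pool_tables",
    "build_pair_table",
    "probandwise_concordance",
    "pairwise_concordance",
    "individual_prevalence",
    "summarize_tables",
]


@dataclass(frozen=True)
class PairTable:
    """Collapsed 2x2 outcome counts for one relationship stratum.

    Attributes
    ----------
    relationship : str
        Stratum label (``full``, ``maternal_half``, ``paternal_half``, or a
        pooled label).
    n11, n10, n00 : int
        Both-affected, discordant, and both-unaffected pair counts.
    """

    relationship: str
    n11: int
    n10: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n00"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        """Number of pairs in the stratum."""
        return self.n11 + self.n10 + self.n00

    @property
    def n_affected(self) -> int:
        """Number of affected individuals among pair members."""
        return 2 * self.n11 + self.n10


def pool_tables(tables: Iterable[PairTable], relationship: str = "pooled") -> PairTable:
    """Sum counts across strata (e.g. maternal + paternal half-siblings)."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty collection of tables")
    return PairTable(
        relationship,
        sum(t.n11 for t in tables),
        sum(t.n10 for t in tables),
        sum(t.n00 for t in tables),
    )


def build_pair_table(pairs, records: pd.DataFrame) -> dict[str, PairTable]:
    """Collapse selected pairs into one :class:`PairTable` per stratum.

    Parameters
    ----------
    pairs : iterable of SiblingPair or DataFrame
        Pairs with ``index_id``, ``sibling_id`` and ``relationship``.
    records : DataFrame
        Registry table indexed (or indexable) by ``person_id`` with an
        ``affected`` column.

    Raises
    ------
    KeyError
        If a pair member is absent from ``records``.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(
            [(p.index_id, p.sibling_id, p.relationship) for p in pairs],
            columns=["index_id", "sibling_id", "relationship"],
        )
    affected = records.set_index("person_id")["affected"] if "person_id" in records.columns \
        else records["affected"]
    missing = set(pairs["index_id"]).union(pairs["sibling_id"]) - set(affected.index)
    if missing:
        raise KeyError(f"pair members missing from records: {sorted(missing)[:5]} ...")

    out: dict[str, PairTable] = {}
    if pairs.empty:
        return out
    a1 = affected.loc[pairs["index_id"]].to_numpy()
    a2 = affected.loc[pairs["sibling_id"]].to_numpy()
    n_aff = a1 + a2
    df = pd.DataFrame({"relationship": pairs["relationship"].to_numpy(), "n_aff": n_aff})
    for rel, grp in df.groupby("relationship", sort=True):
        counts = grp["n_aff"].value_counts()
        out[rel] = PairTable(
            rel,
            int(counts.get(2, 0)),
            int(counts.get(1, 0)),
            int(counts.get(0, 0)),
        )
    return out


def probandwise_concordance(table: PairTable) -> float:
    """Probandwise concordance 2*n11 / (2*n11 + n10).

    Raises
    ------
    ValueError
        If the stratum contains no affected individuals (rate undefined).
    """
    denom = 2 * table.n11 + table.n10
    if denom == 0:
        raise ValueError(
            f"probandwise concordance undefined for {table.relationship!r}: "
            "no affected pair members"
        )
    return 2 * table.n11 / denom


def pairwise_concordance(table: PairTable) -> float:
    """Pairwise concordance n11 / (n11 + n10); always <= probandwise."""
    denom = table.n11 + table.n10
    if denom == 0:
        raise ValueError("pairwise concordance undefined: no affected pairs")
    return table.n11 / denom


def individual_prevalence(table: PairTable) -> float:
    """Fraction of affected individuals among pair members, (2*n11+n10)/(2*total)."""
    if table.total == 0:
        raise ValueError("prevalence undefined for an empty table")
    return table.n_affected / (2 * table.total)


def summarize_tables(tables: Mapping[str, PairTable]) -> pd.DataFrame:
    """Per-stratum summary mirroring the collapsed-count report layout.

    Concordance and prevalence are reported raw and rounded half-even to
    three decimals (the convention used for printed rates).
    """
    rows = []
    for rel in sorted(tables):
        t = tables[rel]
        try:
            conc = probandwise_concordance(t)
        except ValueError:
            conc = float("nan")
        prev = individual_prevalence(t) if t.total else float("nan")
        rows.append(
            {
                "relationship": rel,
                "n11": t.n11,
                "n10": t.n10,
                "n00": t.n00,
                "n_pairs": t.total,
                "probandwise_concordance": conc,
                "concordance_3dp": round(conc, 3),
                "prevalence": prev,
            }
        )
    return pd.DataFrame(rows)
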