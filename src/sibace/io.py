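"""Delimited-text readers/writers for registry, pair and pair-table files.

All files are TSV with a header row.  Layouts:

* registry: person_id, mother_id, father_id, sex, birth_year, is_twin, affected
* pairs: index_id, sibling_id, relationship
* pair tables: relationship, n11, n10, n00
* pair-level phenotypes: relationship, affected_1, affected_2,
  birth_year_1, birth_year_2
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .descriptives import PairTable
from .pedigree import SiblingPair

__all__ = [
    "REGISTRY_COLUMNS",
    "read_registry", "write_registry",
    "read_pairs", "write_pairs",
    "read_pair_tables", "write_pair_tables",
    "build_pair_level", "read_pair_level", "write_pair_level",
]

REGISTRY_COLUMNS = [
    "person_id", "mother_id", "father_id", "sex", "birth_year", "is_twin", "affected",
]


def write_registry(records: pd.DataFrame, path) -> None:
    records[REGISTRY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry file {path} lacks columns {sorted(missing)}")
    return df


def write_pairs(pairs: list[SiblingPair], path) -> None:
    pd.DataFrame(
        [(p.index_id, p.sibling_id, p.relationship) for p in pairs],
        columns=["index_id", "sibling_id", "relationship"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pair_tables(tables: dict[str, PairTable], path) -> None:
    pd.DataFrame(
        [(t.relationship, t.n11, t.n10, t.n00) for t in tables.values()],
        columns=["relationship", "n11", "n10", "n00"],
    ).sort_values("relationship").to_csv(path, sep="\t", index=False)


def read_pair_tables(path) -> dict[str, PairTable]:
    df = pd.read_csv(path, sep="\t")
    return {
        r.relationship: PairTable(r.relationship, int(r.n11), int(r.n10), int(r.n00))
        for r in df.itertuples()
    }


def build_pair_level(pairs, records: pd.DataFrame) -> pd.DataFrame:
    """Join selected pairs to member phenotypes and birth years."""
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(
            [(p.index_id, p.sibling_id, p.relationship) for p in pairs],
            columns=["index_id", "sibling_id", "relationship"],
        )
    idx = records.set_index("person_id")
    out = pd.DataFrame(
        {
            "relationship": pairs["relationship"].to_numpy(),
            "affected_1": idx["affected"].loc[pairs["index_id"]].to_numpy(),
            "affected_2": idx["affected"].loc[pairs["sibling_id"]].to_numpy(),
            "birth_year_1": idx["birth_year"].loc[pairs["index_id"]].to_numpy(),
            "birth_year_2": idx["birth_year"].loc[pairs["sibling_id"]].to_numpy(),
        }
    )
    return out


def write_pair_level(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pair_level(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
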