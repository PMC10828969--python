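"""Pipeline orchestration: simulate -> select-pairs -> describe -> tetrachoric -> fit.

Each stage reads/writes TSV files under an output directory, and the run
leaves a machine-readable ``summary.json``, the resolved configuration
(``config.json``) and a plain-text log with seeds, package versions and
stage timings, so a run is reproducible from its output bundle alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, descriptives, io, tetrachoric
from .biometric import fit_biometric, likelihood_ratio
from .pedigree import select_study_pairs, sibling_clusters
from .simulate import SimulationParams, simulate_registry

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "select-pairs", "describe", "tetrachoric", "fit")

log = logging.getLogger("sibace")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    ``mode`` is a single stage name or ``all``.  Stages consume the outputs
    of earlier stages when run together; standalone stages need the matching
    input path (``registry`` for select-pairs, ``pairs``+``registry`` or
    ``pair_tables`` for the statistical stages).
    """

    mode: str = "all"
    out_dir: str = "sibace_out"
    seed: int | None = None
    registry: str | None = None
    pairs: str | None = None
    pair_tables: str | None = None
    model: str = "both"  # ACE | AE | both
    adjust_birth_year: bool = False
    reference_year: int = 1980
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in STAGES + ("all",):
            raise ValueError(f"mode must be one of {STAGES + ('all',)}")
        if self.model.lower() not in ("ace", "ae", "both"):
            raise ValueError("model must be ACE, AE or both")
        needs_seed = self.mode in ("simulate", "select-pairs", "all")
        if needs_seed and self.seed is None:
            raise ValueError(f"mode {self.mode!r} is stochastic: a seed is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _fit_to_dict(fit) -> dict:
    d = dataclasses.asdict(fit)
    d.pop("cov", None)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stage(s) and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    Raises on missing inputs or non-converged fits; the CLI converts those
    into a nonzero exit status.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("sibace %s | numpy %s | pandas %s | seed=%s",
             __version__, np.__version__, pd.__version__, config.seed)

    stages = STAGES if config.mode == "all" else (config.mode,)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": list(stages)}
    registry = None
    pairs_df = None
    tables = None

    def timed(name):
        t0 = time.perf_counter()

        def done():
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

        return done

    if "simulate" in stages:
        fin = timed("simulate")
        params = SimulationParams(seed=config.seed, **config.sim)
        registry = simulate_registry(params)
        io.write_registry(registry, out / "registry.tsv")
        summary["simulate"] = {
            "n_individuals": int(len(registry)),
            "prevalence": float(registry["affected"].mean()),
            "params": {k: v for k, v in dataclasses.asdict(params).items()},
        }
        fin()

    if "select-pairs" in stages:
        fin = timed("select-pairs")
        if registry is None:
            if not config.registry:
                raise ValueError("select-pairs needs a registry file")
            registry = io.read_registry(config.registry)
        clusters = sibling_clusters(registry)
        pairs = select_study_pairs(clusters, registry, seed=config.seed)
        io.write_pairs(pairs, out / "pairs.tsv")
        pairs_df = io.read_pairs(out / "pairs.tsv")
        summary["select_pairs"] = {
            "n_clusters": len(clusters),
            "n_pairs": len(pairs),
            "by_relationship": pairs_df["relationship"].value_counts().to_dict(),
        }
        fin()

    def _load_tables():
        nonlocal registry, pairs_df
        if config.pair_tables:
            return io.read_pair_tables(config.pair_tables)
        if pairs_df is None:
            if not config.pairs:
                raise ValueError("this stage needs pairs + registry or a pair-table file")
            pairs_df = io.read_pairs(config.pairs)
        if registry is None:
            if not config.registry:
                raise ValueError("this stage needs a registry file")
            registry = io.read_registry(config.registry)
        return descriptives.build_pair_table(pairs_df, registry)

    if "describe" in stages:
        fin = timed("describe")
        tables = _load_tables()
        summ = descriptives.summarize_tables(tables)
        summ.to_csv(out / "descriptives.tsv", sep="\t", index=False)
        summary["describe"] = summ.set_index("relationship").to_dict("index")
        fin()

    if "tetrachoric" in stages:
        fin = timed("tetrachoric")
        tables = tables or _load_tables()
        block = {}
        for rel, tab in sorted(tables.items()):
            if config.adjust_birth_year and registry is not None and pairs_df is not None:
                sub = io.build_pair_level(
                    pairs_df[pairs_df["relationship"] == rel], registry
                )
                fit = tetrachoric.fit_tetrachoric_adjusted(
                    sub, reference_year=config.reference_year, relationship=rel
                )
            else:
                fit = tetrachoric.fit_tetrachoric(tab)
            block[rel] = _fit_to_dict(fit)
        pd.DataFrame(block).T.to_csv(out / "tetrachoric.tsv", sep="\t")
        summary["tetrachoric"] = block
        fin()

    if "fit" in stages:
        fin = timed("fit")
        if config.adjust_birth_year:
            if pairs_df is None or registry is None:
                raise ValueError("birth-year adjustment needs pairs + registry input")
            strata = {
                rel: io.build_pair_level(grp, registry)
                for rel, grp in pairs_df.groupby("relationship")
            }
        else:
            strata = tables or _load_tables()
        wanted = ["ACE", "AE"] if config.model.lower() == "both" else [config.model.upper()]
        fits = {}
        for m in wanted:
            fit = fit_biometric(strata, model=m, reference_year=config.reference_year)
            if not fit.converged:
                raise RuntimeError(f"{m} fit did not converge")
            fits[m] = fit
            summary.setdefault("fit", {})[m] = _fit_to_dict(fit)
        if set(fits) == {"ACE", "AE"}:
            stat, df_, p = likelihood_ratio(fits["ACE"], fits["AE"])
            summary["fit"]["lr_ACE_vs_AE"] = {"statistic": stat, "df": df_, "p": p}
        pd.DataFrame(
            {m: _fit_to_dict(f) for m, f in fits.items()}
        ).T.to_csv(out / "model_fits.tsv", sep="\t")
        fin()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)
    log.removeHandler(handler)
    handler.close()
    return summary
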