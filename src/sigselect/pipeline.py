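"""Configuration-driven orchestration of the analysis stages.

All randomness flows from the config seed through named per-stage
substreams; no stage touches global random state, so identical config and
seed give byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, channels, exposures, selection, simulate

logger = logging.getLogger(__name__)

STAGES = ("exposures", "associate", "power", "select")

# fixed offsets keep stage streams independent of execution order
_STAGE_SEED_OFFSET = {"simulate": 11, "exposures": 23, "associate": 37, "power": 53, "select": 71, "calibrate": 89}


def stage_seed(base_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([base_seed, _STAGE_SEED_OFFSET[stage]]).generate_state(1)[0])


class DependencyError(RuntimeError):
    """A stage was requested before the stage that produces its input."""


@dataclass
class RunConfig:
    mutations: str = ""
    signatures: str = ""  # empty -> bundled COSMIC v2
    driver_list: str = ""  # empty -> bundled default list
    active_by_type: dict[str, list[str]] = field(default_factory=dict)
    output_dir: str = "sigselect_out"
    min_mutations: int = 20
    min_recurrence: int = 4
    fdr: float = 0.05
    min_occurrence: int = 10
    common_fraction: float = 0.01
    seed: int = 0
    dialect: str = "generic"
    restrict_to_enriched: bool = True
    two_sided_method: str = "min_likelihood"
    per_type_fdr: bool = False
    rescale_exome: bool = False
    bootstrap_iters: int = 100
    select_genes: list[str] = field(default_factory=list)
    select_cancer_type: str = ""

    def __post_init__(self) -> None:
        for name in ("min_mutations", "min_recurrence", "min_occurrence", "bootstrap_iters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_catalog(config: RunConfig) -> exposures.SignatureCatalog:
    if config.signatures:
        catalog = exposures.read_catalog(config.signatures)
    else:
        catalog = exposures.load_cosmic_v2()
    if config.rescale_exome:
        catalog = exposures.rescale_to_exome(catalog, exposures.load_default_frequencies())
    return catalog


def _load_driver_genes(config: RunConfig) -> set[str]:
    if config.driver_list:
        return channels.read_driver_genes(config.driver_list)
    from importlib import resources

    with resources.as_file(resources.files("sigselect.data") / "driver_genes.txt") as p:
        return channels.read_driver_genes(p)


def run_pipeline(config: RunConfig, stages: Sequence[str]) -> dict:
    """Execute the requested stages in canonical order; write per-stage TSVs
    and a JSON manifest into the output directory."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    if ("associate" in ordered or "select" in ordered or "power" in ordered) and "exposures" not in ordered:
        raise DependencyError("associate/power/select require the 'exposures' stage first")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
    }

    catalog = _load_catalog(config)
    driver_genes = _load_driver_genes(config)
    records = channels.read_mutations(config.mutations, dialect=config.dialect)
    driver_records = channels.filter_driver_nonsynonymous(records, driver_genes)

    fitted: list[exposures.ExposureVector] = []
    for stage in ordered:
        t0 = time.monotonic()
        info: dict = {"seed": stage_seed(config.seed, stage)}
        if stage == "exposures":
            counts = channels.count_channels(records, exclude=driver_records)
            by_type: dict[str, list[int]] = {}
            for i, ct in enumerate(counts.cancer_types):
                by_type.setdefault(ct, []).append(i)
            for ct, idx in by_type.items():
                active = config.active_by_type.get(ct) or list(catalog.names)
                sub = channels.ChannelCountMatrix(
                    sample_ids=[counts.sample_ids[i] for i in idx],
                    counts=counts.counts[idx],
                    cancer_types=[ct] * len(idx),
                )
                fitted.extend(
                    exposures.fit_exposures(
                        sub, catalog, active=active, min_mutations=config.min_mutations
                    )
                )
            df = exposures.exposures_to_frame(fitted)
            df.to_csv(outdir / "exposures.tsv", sep="\t", index=False)
            info["rows"] = len(df)
        elif stage == "associate":
            results = association.run_association_scan(
                driver_records,
                fitted,
                catalog,
                config.active_by_type,
                min_recurrence=config.min_recurrence,
                min_mutations=config.min_mutations,
                alpha=config.fdr,
                restrict_to_enriched=config.restrict_to_enriched,
                per_type_fdr=config.per_type_fdr,
            )
            df = pd.DataFrame(
                [
                    {
                        "cancer_type": r.mutation.cancer_type,
                        "gene": r.mutation.gene,
                        "protein_change": r.mutation.protein_change,
                        "channel": r.mutation.causal_channel.label,
                        "signature": r.signature,
                        "n_carriers": r.n_carriers,
                        "p": r.p_value,
                        "q": r.q_value,
                        "direction": r.direction,
                        "enriched_flag": r.enriched,
                    }
                    for r in results
                ]
            )
            df.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            info["rows"] = len(df)
        elif stage == "power":
            seed = info["seed"]
            recurrent = association.find_recurrent(driver_records, config.min_recurrence)
            rows = []
            for mut in recurrent:
                samples = [
                    e
                    for e in fitted
                    if e.cancer_type == mut.cancer_type
                    and not e.below_cutoff
                    and not e.flagged
                ]
                if len(samples) < 2 or mut.recurrence >= len(samples):
                    continue
                active = config.active_by_type.get(mut.cancer_type) or list(catalog.names)
                for sig in association.enriched_signatures(
                    mut.causal_channel, catalog, active
                ):
                    est = association.estimate_power(
                        samples,
                        catalog,
                        mut.causal_channel,
                        m=mut.recurrence,
                        signature=sig,
                        alpha=config.fdr,
                        iterations=200,
                        seed=seed,
                        mutation_label=mut.label,
                    )
                    rows.append(vars(est))
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "power.tsv", sep="\t", index=False)
            info["rows"] = len(df)
        elif stage == "select":
            genes = config.select_genes or sorted({r.gene for r in driver_records})
            ctypes = (
                [config.select_cancer_type]
                if config.select_cancer_type
                else sorted({r.cancer_type for r in driver_records})
            )
            rows = []
            for ct in ctypes:
                results = selection.pairwise_selection_scan(
                    driver_records,
                    fitted,
                    catalog,
                    genes=genes,
                    cancer_type=ct,
                    common_fraction=config.common_fraction,
                    min_occurrence=config.min_occurrence,
                    fdr=config.fdr,
                    bootstrap_iters=config.bootstrap_iters,
                    seed=info["seed"],
                    two_sided_method=config.two_sided_method,
                )
                for r in results:
                    rows.append(
                        {
                            "cancer_type": r.cancer_type,
                            "mutation_1": r.m1_label,
                            "mutation_2": r.m2_label,
                            "n_included": r.n_included,
                            "m1": r.m1_count,
                            "m2": r.m2_count,
                            "p": r.p_two_tailed,
                            "q_value": r.q_value,
                            "r_mle": r.relative_risk.r,
                            "ci_low": r.relative_risk.ci_low,
                            "ci_high": r.relative_risk.ci_high,
                            "censored_flag": r.relative_risk.censored,
                        }
                    )
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "selection.tsv", sep="\t", index=False)
            info["rows"] = len(df)
        info["wall_seconds"] = round(time.monotonic() - t0, 3)
        manifest["stages"][stage] = info
        logger.info("stage %s done in %.2fs", stage, info["wall_seconds"])

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
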