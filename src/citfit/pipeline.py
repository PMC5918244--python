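"""End-to-end pipeline: fitness -> combine -> classify -> cluster -> model.

The pipeline ties the modules together for a single configured run:
per-replicate fitness from the competition table, combined citT-activation
effects with bootstrap uncertainty, per-strain classification, lineage
ordering and epoch clustering, comparison against the competing-mutation
schedule, and (optionally) qPCR relative expression.  Outputs are tidy
TSVs plus a machine-readable JSON summary; every file header carries the
config hash and seed so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .adaptation import TrajectoryParams, epoch_vs_model, mutation_schedule
from .lineage import (
    StrainRecord,
    classify_effects,
    cluster_adjacent,
    main_lineage_order,
)
from .qpcr import expression_table
from .resampling import ReplicateSet, combined_cit_effect, strain_rng

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    competition_csv: str = ""
    qpcr_csv: str | None = None
    tree: str | None = None           # path or literal Newick
    metadata_csv: str = ""
    terminal: str | None = None       # Cit+ progenitor label (with a tree)
    out_dir: str = "citfit_out"
    b_reps: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    alpha: float = 0.05
    max_divergence: float = 5000.0
    exclude_strains: tuple = ()
    column_maps: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)   # TrajectoryParams overrides
    n_max: int | None = None
    qpcr_calibrator: str = "REL606"
    qpcr_target: str = "citT"
    qpcr_ref_genes: tuple = ("16S", "idnT")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclude_strains", "qpcr_ref_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def combined_effects_from_table(
    fitness_table: pd.DataFrame, b_reps: int, seed: int, ci_level: float = 0.95
) -> dict:
    """Per-strain CombinedEffect from a tidy per-replicate fitness table.

    Strains with both a cit_effect (or population_context) and an
    ara_marker replicate set are combined; each strain uses its own RNG
    substream derived from (seed, strain) so processing order is
    irrelevant.
    """
    effects = {}
    for strain, sub in fitness_table.groupby("strain", sort=False):
        sets = {}
        for klass, rows in sub.groupby("competition_class"):
            sets[klass] = ReplicateSet(
                label=str(strain), values=tuple(rows["fitness"]),
                competition_class=str(klass),
            )
        cit = sets.get("cit_effect") or sets.get("population_context")
        ara = sets.get("ara_marker")
        if cit is None or ara is None:
            logger.warning(
                "strain %s lacks a %s competition; skipped", strain,
                "cit" if cit is None else "ara",
            )
            continue
        effects[str(strain)] = combined_cit_effect(
            cit, ara, b_reps=b_reps, seed=strain_rng(seed, str(strain)),
            ci_level=ci_level, strain=str(strain),
        )
    return effects


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and write the report bundle.

    Returns the JSON-ready summary dict.  Any stage failure raises with
    the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cio.config_hash(config.as_dict()), "seed": config.seed}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # fitness
    fitness_table = stage(
        "fitness", cio.read_competition_csv, config.competition_csv,
        config.column_maps.get("competition"),
    )
    cio.write_tsv(fitness_table, out / "fitness.tsv", meta)

    # combine
    effects = stage(
        "combine", combined_effects_from_table, fitness_table,
        config.b_reps, config.seed, config.ci_level,
    )
    eff_df = pd.DataFrame(
        [
            {"strain": s, "w_combined": e.w_combined, "ci_lo": e.boot.ci_lo,
             "ci_hi": e.boot.ci_hi, "n_cit": e.n_cit, "n_ara": e.n_ara}
            for s, e in effects.items()
        ]
    )
    cio.write_tsv(eff_df, out / "combined_effects.tsv", meta)

    # lineage ordering
    metadata = stage(
        "order", cio.read_metadata_csv, config.metadata_csv,
        config.column_maps.get("metadata"),
    )
    records = []
    for _, r in metadata.iterrows():
        strain = str(r["strain"])
        if strain not in effects:
            logger.warning("strain %s has metadata but no effect; skipped", strain)
            continue
        records.append(
            StrainRecord(
                strain=strain, generation=float(r["generation"]),
                effect=effects[strain],
                divergence=float(r.get("divergence", 0.0)),
            )
        )
    tree = cio.read_tree(config.tree) if config.tree else None
    ordering = stage(
        "order", main_lineage_order, records, tree=tree,
        terminal=config.terminal, max_divergence=config.max_divergence,
        exclude_strains=set(config.exclude_strains),
    )

    # classify (all strains with effects, on-lineage or not)
    classes = stage("classify", classify_effects, records, config.alpha)
    cls_df = pd.DataFrame([dataclasses.asdict(c) for c in classes])
    cio.write_tsv(cls_df, out / "classification.tsv", meta)

    # cluster
    clusters = stage("cluster", cluster_adjacent, ordering, config.alpha)
    grp_df = pd.DataFrame(
        [
            {"group": i, "members": ",".join(g.strains),
             "gen_start": g.gen_start, "gen_end": g.gen_end,
             "pooled_effect": g.pooled_point,
             "ci_lo": g.pooled_ci[0], "ci_hi": g.pooled_ci[1]}
            for i, g in enumerate(clusters.groups)
        ]
    )
    cio.write_tsv(grp_df, out / "groups.tsv", meta)

    # model comparison
    params = TrajectoryParams(**config.model)
    schedule = stage("model", mutation_schedule, params, config.n_max)
    sched_df = pd.DataFrame(schedule.entries, columns=["n", "t_n", "s_n"])
    cio.write_tsv(sched_df, out / "schedule.tsv", meta)
    verdicts = stage("compare", epoch_vs_model, clusters, schedule)
    ver_df = pd.DataFrame([dataclasses.asdict(v) for v in verdicts])
    ver_df["strains"] = ver_df["strains"].map(",".join)
    cio.write_tsv(ver_df, out / "verdicts.tsv", meta)

    summary = {
        "config_hash": meta["config_hash"],
        "seed": config.seed,
        "n_strains": len(records),
        "n_on_lineage": len(ordering.ordered),
        "excluded": {r.strain: reason for r, reason in ordering.excluded},
        "classification_counts": cls_df["category"].value_counts().to_dict(),
        "n_severe_deficit": int(cls_df["severe"].sum()),
        "groups": [
            {"members": g.strains, "gen_span": [g.gen_start, g.gen_end],
             "pooled_effect": round(g.pooled_point, 6),
             "ci": [round(g.pooled_ci[0], 6), round(g.pooled_ci[1], 6)]}
            for g in clusters.groups
        ],
        "intermediates": [r.strain for r in clusters.intermediates],
        "verdicts": [v.verdict for v in verdicts],
    }

    # qPCR (optional)
    if config.qpcr_csv:
        cq = stage("qpcr", cio.read_qpcr_csv, config.qpcr_csv,
                   config.column_maps.get("qpcr"))
        expr = stage(
            "qpcr", expression_table, cq, config.qpcr_calibrator,
            config.qpcr_target, config.qpcr_ref_genes,
        )
        cio.write_tsv(expr, out / "qpcr_expression.tsv", meta)
        summary["qpcr"] = {
            r["strain"]: round(r["r"], 6) for _, r in expr.iterrows()
        }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
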