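"""Readers and writers: competition CSV, qPCR CSV, Newick trees, tidy TSV.

All tabular inputs are comma-separated UTF-8 with a header row.  A
column-mapping dict adapts the readers to a deposited file's actual
headers, so the pipeline code only ever sees canonical column names.
Competition tables come in two layouts: raw plate counts (preferred; one
row per replicate with initial/final counts, dilutions and volumes for
both competitors) or precomputed per-replicate fitness values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import pandas as pd

from .fitness import CompetitionAssay, PlateCount, relative_fitness

#: canonical column names for a count-level competition table
COUNT_COLUMNS = [
    "assay_id", "competitor_a", "competitor_b", "competition_class",
    "days", "transfer_dilution", "replicate_id",
    "initial_a_colonies", "initial_a_dilution", "initial_a_volume",
    "initial_b_colonies", "initial_b_dilution", "initial_b_volume",
    "final_a_colonies", "final_a_dilution", "final_a_volume",
    "final_b_colonies", "final_b_dilution", "final_b_volume",
]

#: canonical column names for a fitness-level competition table
FITNESS_COLUMNS = ["strain", "competition_class", "replicate_id", "fitness"]

QPCR_COLUMNS = ["strain", "target", "bio_rep", "tech_rep", "cq"]

METADATA_COLUMNS = ["strain", "generation", "divergence"]


def _apply_colmap(df: pd.DataFrame, colmap: dict | None) -> pd.DataFrame:
    if colmap:
        df = df.rename(columns={v: k for k, v in colmap.items()})
    return df


def read_competition_csv(path, colmap: dict | None = None) -> pd.DataFrame:
    """Read a competition CSV into a tidy per-replicate fitness table.

    Raw plate counts are preferred when present: each row is converted to
    a :class:`~citfit.fitness.CompetitionAssay` and its relative fitness
    computed.  Otherwise a precomputed ``fitness`` column is accepted
    as-is.  Returns columns strain, competition_class, replicate_id,
    fitness.
    """
    df = _apply_colmap(pd.read_csv(path), colmap)
    if "initial_a_colonies" in df.columns:
        rows = []
        for _, r in df.iterrows():
            assay = assay_from_row(r)
            est = relative_fitness(assay)
            rows.append(
                {"strain": assay.competitor_a,
                 "competition_class": assay.competition_class,
                 "replicate_id": assay.replicate_id, "fitness": est.w}
            )
        return pd.DataFrame(rows)
    if "fitness" in df.columns:
        missing = [c for c in FITNESS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"competition CSV missing columns: {missing}")
        return df[FITNESS_COLUMNS].copy()
    raise ValueError(
        "competition CSV has neither raw count columns "
        "(initial_a_colonies, ...) nor a fitness column"
    )


def assay_from_row(r) -> CompetitionAssay:
    """Build a CompetitionAssay from one canonical count-level CSV row."""

    def plate(prefix: str) -> PlateCount:
        return PlateCount(
            colonies=float(r[f"{prefix}_colonies"]),
            plating_dilution=float(r.get(f"{prefix}_dilution", 1.0)),
            volume_plated=float(r.get(f"{prefix}_volume", 1.0)),
        )

    return CompetitionAssay(
        assay_id=str(r.get("assay_id", "")),
        competitor_a=str(r["competitor_a"]),
        competitor_b=str(r["competitor_b"]),
        initial_a=plate("initial_a"), initial_b=plate("initial_b"),
        final_a=plate("final_a"), final_b=plate("final_b"),
        days=int(r.get("days", 3)),
        transfer_dilution=float(r.get("transfer_dilution", 100.0)),
        competition_class=str(r.get("competition_class", "cit_effect")),
        replicate_id=str(r.get("replicate_id", "")),
    )


def assays_to_csv(assays: list[CompetitionAssay], path) -> None:
    """Write count-level assays back to the canonical CSV layout."""
    rows = []
    for a in assays:
        row = {
            "assay_id": a.assay_id, "competitor_a": a.competitor_a,
            "competitor_b": a.competitor_b,
            "competition_class": a.competition_class, "days": a.days,
            "transfer_dilution": a.transfer_dilution,
            "replicate_id": a.replicate_id,
        }
        for prefix in ("initial_a", "initial_b", "final_a", "final_b"):
            p = getattr(a, prefix)
            row[f"{prefix}_colonies"] = p.colonies
            row[f"{prefix}_dilution"] = p.plating_dilution
            row[f"{prefix}_volume"] = p.volume_plated
        rows.append(row)
    pd.DataFrame(rows)[COUNT_COLUMNS].to_csv(path, index=False)


def read_qpcr_csv(path, colmap: dict | None = None) -> pd.DataFrame:
    df = _apply_colmap(pd.read_csv(path), colmap)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {missing}")
    return df


def read_metadata_csv(path, colmap: dict | None = None) -> pd.DataFrame:
    df = _apply_colmap(pd.read_csv(path), colmap)
    if "strain" not in df.columns or "generation" not in df.columns:
        raise ValueError("metadata CSV needs at least strain and generation columns")
    return df


def read_tree(path_or_string) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    s = str(path_or_string)
    if s.lstrip().startswith("(") or s.lstrip().startswith("["):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Tidy TSV with provenance comment lines (# key: value) up top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
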