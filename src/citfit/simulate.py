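"""Synthetic competition, lineage-study, and qPCR data with known truth.

The generator emulates the serial-transfer competition protocol (two
competitors mixed ~1:1, plated, propagated through daily 1:100 transfers
for three days, plated again), an epoch-structured lineage of strains
with step-function true fitness effects, and long-format qPCR Cq tables
with stable reference genes.  Every stage of the analysis pipeline can
therefore be tested against ground truth without external downloads.

Noise defaults to the physical sampling process, Poisson counts on the
plates; lognormal density noise is available to mimic day-to-day flask
effects.  With noise switched off, re-analysis recovers the simulated
truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .fitness import CompetitionAssay, PlateCount
from .resampling import strain_rng


@dataclass(frozen=True)
class CompetitionSimSpec:
    true_w: float = 1.02
    days: int = 3
    transfer_dilution: float = 100.0
    reference_daily_growth: float = 100.0  # fold-expansion of reference per day
    initial_ratio: float = 0.5             # focal fraction at mixing
    target_colonies: float = 300.0         # expected colonies per plate
    n_replicates: int = 6
    noise: str = "poisson_counts"          # none | poisson_counts | lognormal_density
    noise_sd: float = 0.1                  # lognormal sigma (log scale)
    competition_class: str = "cit_effect"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_w <= 0:
            raise ValueError("true_w must be > 0")
        if not (0 < self.initial_ratio < 1):
            raise ValueError("initial_ratio must be in (0, 1)")
        if self.noise not in ("none", "poisson_counts", "lognormal_density"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class LineageSimSpec:
    """Epoch-structured lineage: (gen_start, gen_end, true_effect, n_strains).

    Defaults mirror the scale of the real study: four epochs with effects
    +1.7%, -5.4%, +0.4%, +2.4%, three strains each, replicate W noise of
    sd 0.005 (CI half-widths ~1%), n = 10 replicates per competition, and
    a selectively neutral Ara marker.
    """

    epochs: tuple = (
        (0, 7_500, 0.017, 3),
        (10_000, 20_000, -0.054, 3),
        (25_000, 27_000, 0.004, 3),
        (29_000, 31_500, 0.024, 3),
    )
    n_cit: int = 10
    n_ara: int = 10
    noise_sd: float = 0.005
    marker_effect: float = 0.0  # Ara-marker fitness deviation; 0 = neutral
    seed: int = 0

    def __post_init__(self) -> None:
        spans = [(e[0], e[1]) for e in self.epochs]
        if any(a > b for a, b in spans):
            raise ValueError("epoch gen_start must be <= gen_end")
        if any(b2 <= a1 for (_, a1), (b2, _) in zip(spans, spans[1:])):
            raise ValueError("epochs must be ordered and non-overlapping")


def _expected_densities(spec: CompetitionSimSpec) -> tuple[float, float, float, float]:
    """Deterministic initial/final densities under Malthusian growth.

    m_ref = ln(reference_daily_growth) per day; m_focal = true_w * m_ref.
    Final plating happens after ``days`` growth cycles with ``days - 1``
    intervening transfer dilutions.
    """
    d0 = 1.0e6  # cells/ml in the initial mixture; arbitrary reference scale
    a0 = d0 * spec.initial_ratio
    b0 = d0 * (1 - spec.initial_ratio)
    m_ref = math.log(spec.reference_daily_growth)
    m_foc = spec.true_w * m_ref
    carry = spec.transfer_dilution ** (spec.days - 1)
    a_final = a0 * math.exp(m_foc * spec.days) / carry
    b_final = b0 * math.exp(m_ref * spec.days) / carry
    return a0, b0, a_final, b_final


def _plate(density: float, target: float, rng, noise: str, noise_sd: float) -> PlateCount:
    """Plating whose expected colony count is ``target`` at the given density."""
    volume = 0.1  # ml
    dilution = max(density * volume / target, 1.0)
    expected = density * volume / dilution
    if expected < 1:
        raise ValueError(
            f"expected colonies {expected:.2g} < 1; density {density:.3g} too low"
        )
    if noise == "none":
        colonies = expected
    elif noise == "poisson_counts":
        colonies = float(rng.poisson(expected))
    elif noise == "lognormal_density":
        colonies = expected * float(rng.lognormal(-noise_sd**2 / 2, noise_sd))
    else:  # pragma: no cover - spec validates
        raise ValueError(noise)
    return PlateCount(colonies=colonies, plating_dilution=dilution, volume_plated=volume)


def simulate_competition(spec: CompetitionSimSpec) -> list[CompetitionAssay]:
    """Simulate replicate competition flasks for one strain pair.

    With ``noise='none'`` the platings carry the exact expected counts and
    :func:`citfit.fitness.relative_fitness` recovers ``true_w`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    a0, b0, a_fin, b_fin = _expected_densities(spec)
    assays = []
    for rep in range(spec.n_replicates):
        assays.append(
            CompetitionAssay(
                assay_id=f"sim_w{spec.true_w:g}_r{rep}",
                competitor_a="focal",
                competitor_b="reference",
                initial_a=_plate(a0, spec.target_colonies, rng, spec.noise, spec.noise_sd),
                initial_b=_plate(b0, spec.target_colonies, rng, spec.noise, spec.noise_sd),
                final_a=_plate(a_fin, spec.target_colonies, rng, spec.noise, spec.noise_sd),
                final_b=_plate(b_fin, spec.target_colonies, rng, spec.noise, spec.noise_sd),
                days=spec.days,
                transfer_dilution=spec.transfer_dilution,
                competition_class=spec.competition_class,
                replicate_id=str(rep),
            )
        )
    return assays


def _caterpillar_newick(strains: list[tuple[str, float]], tip_branch: float = 1.0) -> str:
    """Ladder tree along the lineage; branch lengths in generations.

    Strains attach to a backbone at their isolation generation with a
    short private branch (``tip_branch``), so every strain is minimally
    diverged from the root-to-terminal path; the latest strain is the
    terminal itself.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    backbone = tree.seed_node
    prev_gen = 0.0
    asc = sorted(strains, key=lambda x: (x[1], x[0]))
    for strain, gen in asc[:-1]:
        node = backbone.new_child(edge_length=gen - prev_gen)
        tip = node.new_child(edge_length=tip_branch)
        tip.taxon = taxa.new_taxon(strain)
        backbone = node
        prev_gen = gen
    strain, gen = asc[-1]
    tip = backbone.new_child(edge_length=(gen - prev_gen) + tip_branch)
    tip.taxon = taxa.new_taxon(strain)
    return tree.as_string(schema="newick")


def simulate_lineage_study(
    spec: LineageSimSpec = LineageSimSpec(),
) -> tuple[pd.DataFrame, str, pd.DataFrame]:
    """Simulate an epoch-structured lineage study.

    Returns (metadata frame, Newick string, competition frame).  The
    competition frame is W-level (one fitness value per replicate row),
    the fast path for statistical tests.  Cit replicate values are drawn
    Normal((1 + effect) / marker_w, sd) and Ara replicates
    Normal(marker_w, sd), so the product of the two means recovers
    1 + effect in expectation whatever the marker deviation.
    """
    meta_rows, comp_rows, tips = [], [], []
    marker_w = 1.0 + spec.marker_effect
    if marker_w <= 0:
        raise ValueError("marker_effect must be > -1")
    for e_idx, (g0, g1, effect, n_strains) in enumerate(spec.epochs):
        gens = np.linspace(g0, g1, n_strains) if n_strains > 1 else [0.5 * (g0 + g1)]
        for s_idx, gen in enumerate(gens):
            strain = f"SYN{e_idx}{chr(ord('A') + s_idx)}"
            rng = strain_rng(spec.seed, strain)
            meta_rows.append(
                {"strain": strain, "generation": float(round(gen)),
                 "divergence": 1.0, "epoch": e_idx, "true_effect": effect}
            )
            tips.append((strain, float(round(gen))))
            # Cit competition carries effect and marker; Ara carries marker only
            cit_vals = rng.normal((1.0 + effect) / marker_w, spec.noise_sd, spec.n_cit)
            ara_vals = rng.normal(marker_w, spec.noise_sd, spec.n_ara)
            for klass, vals in (("cit_effect", cit_vals), ("ara_marker", ara_vals)):
                for rep, w in enumerate(vals):
                    comp_rows.append(
                        {"strain": strain, "competition_class": klass,
                         "replicate_id": rep, "fitness": float(w)}
                    )
    metadata = pd.DataFrame(meta_rows)
    newick = _caterpillar_newick(tips)
    competition = pd.DataFrame(comp_rows)
    return metadata, newick, competition


def simulate_qpcr(
    true_fold_changes: dict[str, float],
    cq_noise_sd: float = 0.1,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    calibrator: str = "REL606",
    target: str = "citT",
    ref_baselines: dict[str, float] = None,
    target_baseline: float = 22.0,
) -> pd.DataFrame:
    """Long-format Cq table with known per-strain fold changes vs calibrator.

    Reference genes are stable across strains; the target Cq in a strain
    with true fold change F is baseline - log2(F) plus Normal noise per
    well.  F = 1 and zero noise reproduce R = 1 for every strain.
    """
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be > 0")
    ref_baselines = ref_baselines or {"16S": 10.0, "idnT": 24.0}
    rows = []
    strains = {calibrator: 1.0, **true_fold_changes}
    for strain, fold in strains.items():
        rng = strain_rng(seed, strain)
        for bio in range(1, n_bio + 1):
            genes = {target: target_baseline - math.log2(fold), **ref_baselines}
            for gene, base in genes.items():
                for tech in range(1, n_tech + 1):
                    cq = base + (rng.normal(0, cq_noise_sd) if cq_noise_sd > 0 else 0.0)
                    rows.append(
                        {"strain": strain, "target": gene, "bio_rep": bio,
                         "tech_rep": tech, "cq": cq}
                    )
    return pd.DataFrame(rows)
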