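"""Ordering strains along a focal lineage and clustering fitness epochs.

Strains sampled through time from an evolving population are ordered by
isolation generation along the line of descent leading to a focal
terminal (here, the Cit+ progenitor).  Strains on long private branches
are excluded: their genotypes are not representative of the main
lineage.  Phylogenetically adjacent strains whose measured fitness
effects are statistically indistinguishable (all pairwise
Bonferroni-corrected two-sided bootstrap tests non-significant) are
merged into epoch groups; a strain compatible with both of two adjacent,
mutually distinct groups is flagged as an intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .resampling import (
    BootstrapResult,
    CombinedEffect,
    DEFAULT_CI_LEVEL,
    TestResult,
    bootstrap_test_vs_null,
    pairwise_difference_test,
    threshold_benefit_test,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIVERGENCE = 5000.0  # generations of private-branch divergence
SEVERE_DEFICIT_THRESHOLD = 0.80  # W below this is a >20% fitness decrease


@dataclass
class StrainRecord:
    strain: str
    generation: float
    effect: CombinedEffect | None = None
    divergence: float = 0.0
    on_lineage: bool = True

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError(f"{self.strain}: generation must be >= 0")
        if self.divergence < 0:
            raise ValueError(f"{self.strain}: divergence must be >= 0")


@dataclass
class LineageOrdering:
    """Strains on the focal lineage, in ascending isolation generation."""

    ordered: list[StrainRecord]
    excluded: list[tuple[StrainRecord, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        gens = [r.generation for r in self.ordered]
        if any(b < a for a, b in zip(gens, gens[1:])):
            raise ValueError("ordered strains must have non-decreasing generations")


@dataclass
class EpochGroup:
    """Contiguous strains with statistically indistinguishable effects."""

    members: list[StrainRecord]
    pooled_point: float
    pooled_ci: tuple[float, float]
    pooled_draws: np.ndarray = field(repr=False, default=None)

    @property
    def gen_start(self) -> float:
        return min(r.generation for r in self.members)

    @property
    def gen_end(self) -> float:
        return max(r.generation for r in self.members)

    @property
    def strains(self) -> list[str]:
        return [r.strain for r in self.members]


@dataclass
class ClusterResult:
    groups: list[EpochGroup]
    intermediates: list[StrainRecord] = field(default_factory=list)
    excluded: list[tuple[StrainRecord, str]] = field(default_factory=list)


def compute_divergences(
    tree: dendropy.Tree, terminal: str
) -> dict[str, float]:
    """Private-branch divergence of every leaf from the root->terminal path.

    For each leaf, the sum of branch lengths from the leaf up to its first
    ancestor lying on the path from the root to ``terminal``.  A strain
    sampled directly from the main lineage hangs off that path by only its
    own short terminal branch, so its divergence is small; a strain in a
    long-isolated side clade accumulates the whole private subtree path.
    """
    term_leaf = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == terminal:
            term_leaf = leaf
            break
    if term_leaf is None:
        raise ValueError(f"terminal strain {terminal!r} not found in tree")
    on_path = set()
    node = term_leaf
    while node is not None:
        on_path.add(id(node))
        node = node.parent_node
    div = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            continue
        total = 0.0
        node = leaf
        while node is not None and id(node) not in on_path:
            total += node.edge.length or 0.0
            node = node.parent_node
        div[leaf.taxon.label] = total
    return div


def main_lineage_order(
    records: list[StrainRecord],
    tree: dendropy.Tree | None = None,
    terminal: str | None = None,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    exclude_strains: set[str] | None = None,
) -> LineageOrdering:
    """Restrict to strains near the focal line of descent, sorted by generation.

    Divergence is taken from the tree (branch lengths in generations) when
    a tree and terminal are given, otherwise from each record's
    ``divergence`` field.  Strains with divergence > ``max_divergence``,
    strains missing from the tree, and strains in ``exclude_strains``
    (manual curation, e.g. private subclades with their own shared effect
    shifts) are excluded with reasons.
    """
    exclude_strains = exclude_strains or set()
    if tree is not None:
        if terminal is None:
            raise ValueError("terminal strain label required with a tree")
        div = compute_divergences(tree, terminal)
    else:
        div = None

    ordered, excluded = [], []
    for rec in records:
        if rec.strain in exclude_strains:
            excluded.append((rec, "excluded by configuration"))
            continue
        if div is not None:
            if rec.strain not in div:
                logger.warning("strain %s absent from tree; excluded", rec.strain)
                excluded.append((rec, "absent from tree"))
                continue
            rec.divergence = div[rec.strain]
        if rec.divergence > max_divergence:
            excluded.append(
                (rec, f"divergence {rec.divergence:.0f} > {max_divergence:.0f} generations")
            )
            rec.on_lineage = False
            continue
        rec.on_lineage = True
        ordered.append(rec)
    ordered.sort(key=lambda r: (r.generation, r.strain))
    return LineageOrdering(ordered=ordered, excluded=excluded)


def groupwise_effect(
    members: list[StrainRecord], ci_level: float = DEFAULT_CI_LEVEL
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Pooled effect of a group: per-draw mean across members, equal weight.

    Draw b of the group is the mean over members of their draw b (members'
    draws were generated independently); the point estimate is the mean of
    member points and the CI the percentile interval of the group draws.
    """
    points = [r.effect.w_combined for r in members]
    draw_mat = np.vstack([r.effect.boot.draws for r in members])
    group_draws = draw_mat.mean(axis=0)
    alpha = 1 - ci_level
    lo, hi = np.quantile(group_draws, [alpha / 2, 1 - alpha / 2])
    return float(np.mean(points)), (float(lo), float(hi)), group_draws


def _pairwise_ps(members: list[StrainRecord]) -> list[float]:
    ps = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            ps.append(
                pairwise_difference_test(members[i].effect, members[j].effect).p
            )
    return ps


def _homogeneous(members: list[StrainRecord], alpha: float, k_family: int | None) -> bool:
    """All pairwise two-sided bootstrap p > alpha / K.

    K is the Bonferroni family size: the number of pairwise tests across
    the whole ordered lineage when ``k_family`` is given, otherwise the
    k(k-1)/2 pairs within the tentative group.
    """
    if len(members) < 2:
        return True
    ps = _pairwise_ps(members)
    corrected_alpha = alpha / (k_family if k_family else len(ps))
    return all(p > corrected_alpha for p in ps)


def _make_group(members: list[StrainRecord]) -> EpochGroup:
    point, ci, draws = groupwise_effect(members)
    return EpochGroup(members=list(members), pooled_point=point, pooled_ci=ci,
                      pooled_draws=draws)


def _group_boot(group: EpochGroup) -> BootstrapResult:
    return BootstrapResult(
        point=group.pooled_point, b_reps=group.pooled_draws.size,
        ci_level=DEFAULT_CI_LEVEL, ci_lo=group.pooled_ci[0],
        ci_hi=group.pooled_ci[1], draws=group.pooled_draws,
    )


def cluster_adjacent(
    ordering: LineageOrdering, alpha: float = 0.05, family: str = "lineage"
) -> ClusterResult:
    """Greedy earliest-to-latest agglomeration into epoch groups.

    The current group is extended with the next strain iff all pairwise
    two-sided bootstrap p-values among the tentative members exceed
    alpha/K (Bonferroni).  ``family`` sets the correction family K:
    ``"lineage"`` (default) corrects over all m(m-1)/2 pairwise tests
    among the ordered strains, controlling the familywise split error for
    the whole reconstruction; ``"group"`` corrects only over the
    k(k-1)/2 pairs within the tentative group, which is more prone to
    spurious splits (familywise error ~alpha per group).  When a strain
    breaks the group, it is tested for individual compatibility
    (p > corrected alpha against every member) with both the closed group
    and the group that forms after it; if compatible with both and the
    two groups differ significantly, it is an intermediate and
    contributes to neither pooled effect.
    """
    records = [r for r in ordering.ordered]
    if not records:
        raise ValueError("empty lineage ordering")
    for r in records:
        if r.effect is None:
            raise ValueError(f"strain {r.strain} has no combined effect")
    if family == "lineage":
        m = len(records)
        k_family = max(m * (m - 1) // 2, 1)
    elif family == "group":
        k_family = None
    else:
        raise ValueError(f"unknown Bonferroni family {family!r}")
    alpha_pair = alpha / (k_family or 1)
    b = records[0].effect.boot.b_reps
    if 2 / (b + 1) > alpha_pair:
        logger.warning(
            "bootstrap floor 2/(B+1) = %.2g exceeds corrected threshold %.2g; "
            "no pairwise test can reach significance — increase b_reps",
            2 / (b + 1), alpha_pair,
        )

    # greedy pass
    groups_members: list[list[StrainRecord]] = []
    current = [records[0]]
    for rec in records[1:]:
        if _homogeneous(current + [rec], alpha, k_family):
            current.append(rec)
        else:
            groups_members.append(current)
            current = [rec]
    groups_members.append(current)

    # intermediate pass: a strain adjacent to a group boundary that is
    # individually compatible with every member of both flanking groups,
    # while the groups themselves differ, belongs to neither — it sits on
    # the branch where the effect changed.  Greedy assignment will have
    # absorbed such a strain into the earlier group (or left it as a
    # singleton), so peel candidates off both sides of each boundary.
    def _compat(rec: StrainRecord, members: list[StrainRecord]) -> bool:
        return all(
            pairwise_difference_test(rec.effect, m.effect).p > alpha_pair
            for m in members
        )

    def _separated(g1: list[StrainRecord], g2: list[StrainRecord]) -> bool:
        sep = pairwise_difference_test(
            _group_boot(_make_group(g1)), _group_boot(_make_group(g2))
        ).p
        return sep <= alpha

    intermediates: list[StrainRecord] = []
    changed = True
    while changed:
        changed = False
        for i in range(len(groups_members) - 1):
            g, h = groups_members[i], groups_members[i + 1]
            if len(g) > 1 and _compat(g[-1], h) and _separated(g[:-1], h):
                intermediates.append(g.pop())
                changed = True
                break
            if len(h) > 1 and _compat(h[0], g) and _separated(g, h[1:]):
                intermediates.append(h.pop(0))
                changed = True
                break
            if (
                len(g) == 1
                and i > 0
                and _compat(g[0], groups_members[i - 1])
                and _compat(g[0], h)
                and _separated(groups_members[i - 1], h)
            ):
                intermediates.append(g[0])
                del groups_members[i]
                changed = True
                break

    intermediates.sort(key=lambda r: (r.generation, r.strain))
    groups = [_make_group(m) for m in groups_members]
    return ClusterResult(groups=groups, intermediates=intermediates,
                         excluded=list(ordering.excluded))


@dataclass(frozen=True)
class EffectClass:
    strain: str
    category: str  # significant_benefit | neutral | significant_deficit
    severe: bool  # deficit with point < 0.80
    benefit_ge_1pct_not_excluded: bool
    p_upper: float
    p_lower: float


def classify_effects(
    records: list[StrainRecord],
    alpha: float = 0.05,
    benefit_threshold: float = 1.01,
    severe_threshold: float = SEVERE_DEFICIT_THRESHOLD,
) -> list[EffectClass]:
    """Classify each strain's citT-activation effect.

    significant_benefit: one-tailed upper bootstrap p < alpha (effect > 1);
    significant_deficit: one-tailed lower p < alpha, flagged severe when
    the point estimate is below ``severe_threshold`` (a >20% decrease);
    otherwise neutral, with an extra flag when a benefit of 1% or more
    cannot be ruled out (threshold test p >= alpha).
    """
    out = []
    for rec in records:
        eff = rec.effect
        # benefit is significant when almost no draws fall at or below 1
        p_benefit = bootstrap_test_vs_null(eff, 1.0, "lower").p
        # deficit is significant when almost no draws fall at or above 1
        p_deficit = bootstrap_test_vs_null(eff, 1.0, "upper").p
        if p_benefit < alpha:
            cat, severe = "significant_benefit", False
            not_excl = False
        elif p_deficit < alpha:
            cat = "significant_deficit"
            severe = eff.w_combined < severe_threshold
            not_excl = False
        else:
            cat, severe = "neutral", False
            not_excl = threshold_benefit_test(eff, benefit_threshold).p >= alpha
        out.append(
            EffectClass(
                strain=rec.strain, category=cat, severe=severe,
                benefit_ge_1pct_not_excluded=not_excl,
                p_upper=p_deficit, p_lower=p_benefit,
            )
        )
    return out
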