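"""Genome-level capability calling: which vitamins can a genome make de novo?

A genome is called a *producer* of a vitamin when at least one pathway
variant has every indispensable functional role represented by at least one
of its KOs in the genome's annotation.  Cobalamin is branch-structured: an
early corrin-ring segment (anaerobic or aerobic) must be satisfied together
with the shared post-cobyrinate a,c-diamide segment; a variant tagged
``post_cobyrinate`` is never sufficient on its own.

The module also applies the genome quality rules (strict completeness >
min, contamination < max), computes completeness/contamination-corrected
genome sizes, types genomes on the cobalamin producer–consumer axis
(complete / partial / absent biosynthesis gene complement, plus corrinoid
transporter and dependent-enzyme flags), and derives core-KO comparisons
between producer and non-producer genome sets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .knowledge import KnowledgeBase, PathwayVariant

__all__ = [
    "GenomeAnnotation",
    "VitaminVerdict",
    "CapabilityCall",
    "CobalaminClass",
    "CoverReport",
    "MalformedRecordError",
    "quality_filter",
    "corrected_genome_size",
    "predict_capability",
    "classify_cobalamin",
    "core_kos",
    "exclusive_core_kos",
    "complementarity_matrix",
    "capability_table",
]

logger = logging.getLogger(__name__)

LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class MalformedRecordError(ValueError):
    """A genome record with impossible quality metrics."""


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome's KO content plus assembly metadata.

    ``taxonomy`` is the ordered lineage (domain → genus, empty strings for
    unassigned ranks); ``completeness``/``contamination`` are CheckM-style
    percentages.
    """

    genome_id: str
    ko_set: frozenset[str]
    completeness: float = 100.0
    contamination: float = 0.0
    taxonomy: tuple[str, ...] = ("", "", "", "", "", "")
    assembly_size: int = 2_000_000
    source_region: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ko_set", frozenset(self.ko_set))
        object.__setattr__(self, "taxonomy", tuple(self.taxonomy))

    @property
    def phylum(self) -> str:
        return self.taxonomy[1] if len(self.taxonomy) > 1 else ""

    @property
    def genus(self) -> str:
        return self.taxonomy[5] if len(self.taxonomy) > 5 else ""


@dataclass(frozen=True)
class VitaminVerdict:
    producer: bool
    satisfied_variant_ids: tuple[str, ...]
    #: variant_id -> indispensable roles with no KO present in the genome
    missing_by_variant: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class CapabilityCall:
    """Per-vitamin producer verdicts for one genome."""

    genome_id: str
    verdicts: dict[str, VitaminVerdict]

    @property
    def n_vitamins_producible(self) -> int:
        return sum(v.producer for v in self.verdicts.values())

    def producible(self) -> tuple[str, ...]:
        return tuple(vit for vit, v in self.verdicts.items() if v.producer)


@dataclass(frozen=True)
class CobalaminClass:
    """Cobalamin producer/consumer typology for one genome.

    ``biosynthesis_class`` is ``complete`` (CCG: an early segment plus the
    post-cobyrinate segment fully satisfied), ``partial`` (PCG: some
    biosynthesis role present but no route complete), or ``absent``.  The
    transporter / dependent-enzyme facets are independent consumer markers.
    """

    genome_id: str
    biosynthesis_class: str
    has_transporter: bool
    has_dependent_enzyme: bool
    #: segment tag -> roles of that segment present in the genome
    present_roles: dict[str, tuple[str, ...]]
    #: segment tag -> indispensable roles of that segment absent
    missing_indispensable_roles: dict[str, tuple[str, ...]]
    present_transporters: tuple[str, ...] = ()
    present_enzymes: tuple[str, ...] = ()


def _validate_record(g: GenomeAnnotation) -> None:
    if g.contamination < 0:
        raise MalformedRecordError(
            f"genome {g.genome_id!r}: negative contamination {g.contamination}"
        )
    if g.completeness > 100 or g.completeness < 0:
        raise MalformedRecordError(
            f"genome {g.genome_id!r}: completeness {g.completeness} outside [0, 100]"
        )


def quality_filter(
    genomes: Sequence[GenomeAnnotation],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> tuple[list[GenomeAnnotation], list[GenomeAnnotation]]:
    """Partition genomes into (kept, rejected) by strict quality bounds.

    A genome is kept iff completeness is strictly greater than
    ``min_completeness`` AND contamination strictly less than
    ``max_contamination``; boundary genomes are rejected.  Input order is
    preserved in both lists.
    """
    kept: list[GenomeAnnotation] = []
    rejected: list[GenomeAnnotation] = []
    for g in genomes:
        _validate_record(g)
        if g.completeness > min_completeness and g.contamination < max_contamination:
            kept.append(g)
        else:
            rejected.append(g)
    return kept, rejected


def corrected_genome_size(g: GenomeAnnotation) -> float:
    """Assembly size rescaled by completeness and contamination.

    size × (100 / completeness) × (1 − contamination / 100): inflates an
    incomplete assembly to its expected full size and strips the estimated
    contaminant fraction.
    """
    _validate_record(g)
    if g.completeness == 0:
        raise ValueError(f"genome {g.genome_id!r}: completeness is 0")
    return g.assembly_size * (100.0 / g.completeness) * (1.0 - g.contamination / 100.0)


# ---------------------------------------------------------------------------
# producer prediction
# ---------------------------------------------------------------------------

def _missing_roles(variant: PathwayVariant, ko_set: frozenset[str], kb: KnowledgeBase) -> tuple[str, ...]:
    """Indispensable roles of the variant with no KO in ``ko_set``."""
    return tuple(
        rid
        for rid in variant.role_ids
        if rid in variant.indispensable_role_ids and not (kb.role(rid).ko_ids & ko_set)
    )


def predict_capability(g: GenomeAnnotation, kb: KnowledgeBase) -> CapabilityCall:
    """Call per-vitamin de novo producer status for one genome.

    A variant is satisfied iff every indispensable role has at least one of
    its KOs in the genome.  For a vitamin with a ``post_cobyrinate`` segment
    (cobalamin), a producer verdict requires a satisfied early-segment
    variant AND a satisfied post-cobyrinate variant; the satisfied route is
    reported under the early variant's id.  KOs in the annotation that the
    KB does not know are ignored.  The call is deterministic and monotone:
    adding KOs can only add producer verdicts.
    """
    verdicts: dict[str, VitaminVerdict] = {}
    for vitamin in kb.vitamins:
        early = kb.early_variants(vitamin)
        posts = kb.post_cobyrinate_variants(vitamin)
        missing: dict[str, tuple[str, ...]] = {}
        for v in kb.variants_for(vitamin):
            missing[v.variant_id] = _missing_roles(v, g.ko_set, kb)
        sat_early = tuple(v.variant_id for v in early if not missing[v.variant_id])
        if posts:
            post_ok = any(not missing[p.variant_id] for p in posts)
            satisfied = sat_early if post_ok else ()
        else:
            satisfied = sat_early
        verdicts[vitamin] = VitaminVerdict(
            producer=bool(satisfied),
            satisfied_variant_ids=satisfied,
            missing_by_variant=missing,
        )
    return CapabilityCall(genome_id=g.genome_id, verdicts=verdicts)


def classify_cobalamin(g: GenomeAnnotation, kb: KnowledgeBase) -> CobalaminClass:
    """Type one genome on the cobalamin producer/consumer axes.

    ``complete`` requires a fully satisfied early corrin-ring segment
    (anaerobic or aerobic) together with the post-cobyrinate segment;
    ``partial`` means at least one biosynthesis role is present but no
    complete route exists; ``absent`` means none.  Transporter and
    dependent-enzyme flags are each "at least one gene present".
    """
    present: dict[str, tuple[str, ...]] = {}
    missing: dict[str, tuple[str, ...]] = {}
    any_role_present = False
    sat_by_tag: dict[str, bool] = {}
    for v in kb.variants_for("COB"):
        tag = v.segment_tag or v.variant_id
        pres = tuple(rid for rid in v.role_ids if kb.role(rid).ko_ids & g.ko_set)
        miss = _missing_roles(v, g.ko_set, kb)
        present[tag] = pres
        missing[tag] = miss
        any_role_present = any_role_present or bool(pres)
        sat_by_tag[tag] = sat_by_tag.get(tag, False) or not miss

    post_ok = sat_by_tag.get("post_cobyrinate", False)
    early_ok = any(ok for tag, ok in sat_by_tag.items() if tag != "post_cobyrinate")
    if early_ok and post_ok:
        cls = "complete"
    elif any_role_present:
        cls = "partial"
    else:
        cls = "absent"

    util = kb.cobalamin_utilization
    transporters = tuple(
        sym for sym, kos in sorted(util.transporter_roles.items()) if kos & g.ko_set
    )
    enzymes = tuple(
        sym for sym, kos in sorted(util.dependent_enzyme_roles.items()) if kos & g.ko_set
    )
    return CobalaminClass(
        genome_id=g.genome_id,
        biosynthesis_class=cls,
        has_transporter=bool(transporters),
        has_dependent_enzyme=bool(enzymes),
        present_roles=present,
        missing_indispensable_roles=missing,
        present_transporters=transporters,
        present_enzymes=enzymes,
    )


# ---------------------------------------------------------------------------
# core-KO comparisons
# ---------------------------------------------------------------------------

def core_kos(
    group: Sequence[GenomeAnnotation], prevalence_threshold: float = 0.9
) -> frozenset[str]:
    """KOs present in strictly more than ``prevalence_threshold`` of genomes.

    A KO carried by 9 of 10 genomes is *not* core at threshold 0.9 (0.9 is
    not > 0.9).
    """
    if not group:
        raise ValueError("core_kos: empty genome group")
    if not 0 < prevalence_threshold < 1:
        raise ValueError("prevalence_threshold must be in (0, 1)")
    n = len(group)
    counts: Counter[str] = Counter()
    for g in group:
        counts.update(g.ko_set)
    return frozenset(ko for ko, c in counts.items() if c / n > prevalence_threshold)


def exclusive_core_kos(
    vpg_group: Sequence[GenomeAnnotation],
    npg_group: Sequence[GenomeAnnotation],
    prevalence_threshold: float = 0.9,
    strict: bool = True,
) -> frozenset[str]:
    """Core KOs of the producer set that the non-producer set lacks.

    With ``strict=True`` (default) a KO qualifies only if it is core among
    producers and occurs in *no* non-producer genome ("only present in"
    producers).  ``strict=False`` relaxes the exclusion to "not core among
    non-producers".
    """
    if not vpg_group or not npg_group:
        raise ValueError("exclusive_core_kos: empty genome group")
    vpg_core = core_kos(vpg_group, prevalence_threshold)
    if strict:
        npg_any: set[str] = set()
        for g in npg_group:
            npg_any |= g.ko_set
        return vpg_core - npg_any
    return vpg_core - core_kos(npg_group, prevalence_threshold)


# ---------------------------------------------------------------------------
# complementarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverReport:
    """Whether the pooled gene content of a genome set completes a route."""

    covered: bool
    satisfied_route_tags: tuple[str, ...]
    #: per early-segment tag, indispensable roles missing from the pooled set
    bottleneck_roles: dict[str, tuple[str, ...]] = field(default_factory=dict)


def complementarity_matrix(
    classes: Sequence[CobalaminClass], kb: KnowledgeBase
) -> tuple[pd.DataFrame, CoverReport]:
    """Role × genome presence table for cobalamin biosynthesis/utilization.

    Rows are the COB biosynthesis roles in KB (segment) order followed by
    transporter and dependent-enzyme symbols; entries are 0/1 presence.
    The cover report states whether the *union* of all genomes satisfies a
    complete route (early segment + post-cobyrinate) — the gene-sharing
    reading of partial producers complementing one another — and, if not,
    which indispensable roles are the community-level bottlenecks.
    """
    if not classes:
        raise ValueError("complementarity_matrix: no genomes")
    role_order: list[str] = []
    for v in kb.variants_for("COB"):
        for rid in v.role_ids:
            if rid not in role_order:
                role_order.append(rid)
    util = kb.cobalamin_utilization
    role_order += sorted(util.transporter_roles) + sorted(util.dependent_enzyme_roles)

    table = pd.DataFrame(
        0, index=role_order, columns=[c.genome_id for c in classes], dtype=int
    )
    pooled: set[str] = set()
    for c in classes:
        present = set()
        for roles in c.present_roles.values():
            present.update(roles)
        present.update(c.present_transporters)
        present.update(c.present_enzymes)
        pooled |= present
        table.loc[sorted(present & set(role_order)), c.genome_id] = 1

    posts = kb.post_cobyrinate_variants("COB")
    post_missing = {
        p.variant_id: tuple(
            r for r in p.indispensable_role_ids if r not in pooled
        )
        for p in posts
    }
    post_ok = any(not m for m in post_missing.values())
    satisfied: list[str] = []
    bottlenecks: dict[str, tuple[str, ...]] = {}
    for v in kb.early_variants("COB"):
        tag = v.segment_tag or v.variant_id
        miss = tuple(sorted(r for r in v.indispensable_role_ids if r not in pooled))
        if not miss and post_ok:
            satisfied.append(tag)
        else:
            pooled_post_miss = min(post_missing.values(), key=len) if posts else ()
            bottlenecks[tag] = tuple(sorted(set(miss) | set(pooled_post_miss)))
    return table, CoverReport(
        covered=bool(satisfied),
        satisfied_route_tags=tuple(satisfied),
        bottleneck_roles=bottlenecks,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def capability_table(calls: Iterable[CapabilityCall]) -> pd.DataFrame:
    """One row per genome: 0/1 per vitamin plus satisfied-variant lists."""
    rows = []
    for call in calls:
        row: dict[str, object] = {"genome_id": call.genome_id}
        for vit, verdict in call.verdicts.items():
            row[vit] = int(verdict.producer)
            row[f"{vit}_variants"] = ",".join(verdict.satisfied_variant_ids)
        row["n_vitamins"] = call.n_vitamins_producible
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")
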