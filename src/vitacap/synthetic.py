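"""Synthetic data with planted ground truth for every pipeline stage.

Generates (i) knowledge bases with the same shape as the curated one,
(ii) genome annotation sets where each genome's per-vitamin producer status
is planted before an optional annotation-dropout noise step, and
(iii) multi-group metagenome datasets — a gene catalog derived from the
genomes, group-specific expected abundances carrying planted per-vitamin
fold changes, and multinomial read sampling at fixed depth.  Every planted
fact is recorded in a machine-readable :class:`PlantedTruth` so downstream
verdicts can be scored exactly.

Counts are multinomial at fixed per-sample depth (not Poisson), which keeps
TPM denominators stable across samples.  Optional per-genome, per-sample
log-normal jitter emulates biological compositional variability; it is
group-independent, so the null (all fold changes 1) stays exchangeable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .capability import GenomeAnnotation
from .knowledge import (
    VITAMINS,
    CobalaminUtilizationLists,
    FunctionalRole,
    KnowledgeBase,
    PathwayVariant,
    ko_universe,
)
from .profiling import GeneRecord

__all__ = [
    "PlantedTruth",
    "SyntheticDataset",
    "make_kb",
    "simulate_genomes",
    "simulate_community",
    "preset_dataset",
    "GIT_REGIONS",
    "TAXA_ONTOLOGY",
]

#: The ten gastrointestinal-tract regions, rumen to rectum.
GIT_REGIONS = ("RUM", "RET", "OMA", "ABO", "DUO", "JEJ", "ILE", "CEC", "COL", "REC")

#: Small fixed taxonomy used for readable synthetic outputs:
#: phylum -> genera, echoing taxa dominant in the ruminant gut.
TAXA_ONTOLOGY: dict[str, tuple[str, ...]] = {
    "Bacteroidetes": ("Prevotella", "Bacteroides", "Alistipes"),
    "Firmicutes": ("Clostridium", "Ruminococcus", "Eubacterium", "Butyrivibrio"),
    "Actinobacteria": ("Bifidobacterium", "Olsenella"),
    "Proteobacteria": ("Escherichia", "Succinivibrio"),
    "Euryarchaeota": ("Methanobrevibacter",),
}


@dataclass
class PlantedTruth:
    """Machine-readable record of everything the generator planted."""

    seed: int
    parameters: dict = field(default_factory=dict)
    #: genome_id -> vitamin -> planted producer flag (intent before dropout)
    capability: dict[str, dict[str, bool]] = field(default_factory=dict)
    #: genome_id -> vitamin -> variant id the producer content was drawn from
    chosen_variants: dict[str, dict[str, str]] = field(default_factory=dict)
    #: genome_id -> planted cobalamin biosynthesis class
    cobalamin_class: dict[str, str] = field(default_factory=dict)
    #: sample_id -> group label
    sample_groups: dict[str, str] = field(default_factory=dict)
    #: vitamin -> group label -> planted pathway fold change vs first group
    pathway_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    #: vitamin -> group label -> analytic expected pathway TPM (no jitter)
    expected_pathway_tpm: dict[str, dict[str, float]] = field(default_factory=dict)
    #: vitamin -> phylum -> analytic expected share of the vitamin's TPM
    #: in the first group (taxon attribution truth)
    expected_taxon_shares: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


@dataclass
class SyntheticDataset:
    """A complete, internally consistent synthetic study."""

    kb: KnowledgeBase
    genomes: list[GenomeAnnotation]
    catalog: list[GeneRecord]
    counts: pd.DataFrame
    sample_groups: pd.Series
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# knowledge bases
# ---------------------------------------------------------------------------

def make_kb(
    seed: int = 0,
    n_vitamins: int = 9,
    roles_per_variant: int = 4,
    variants_per_vitamin: int = 2,
    kos_per_role: int = 2,
) -> KnowledgeBase:
    """A valid synthetic KB, deterministic per (seed, sizes).

    Vitamins are taken in canonical order; if cobalamin is included it is
    always built with anaerobic + aerobic early segments plus a
    post-cobyrinate segment, and corrinoid utilization lists are always
    generated (disjoint from all biosynthesis KOs).
    """
    if min(n_vitamins, roles_per_variant, variants_per_vitamin, kos_per_role) < 1:
        raise ValueError("all KB sizes must be >= 1")
    vitamins = list(VITAMINS[:n_vitamins])
    counter = 50001 + (seed % 100) * 400  # seed shifts the KO namespace
    roles: list[FunctionalRole] = []
    variants: list[PathwayVariant] = []

    def new_role(vit: str, rid: str) -> str:
        nonlocal counter
        kos = frozenset(f"K{counter + i:05d}" for i in range(kos_per_role))
        counter += kos_per_role
        roles.append(FunctionalRole(rid, vit, kos, label=f"synthetic role {rid}"))
        return rid

    for vit in vitamins:
        if vit == "COB":
            segs = [("anaerobic", roles_per_variant), ("aerobic", roles_per_variant),
                    ("post_cobyrinate", max(1, roles_per_variant - 1))]
            for tag, n_roles in segs:
                rids = [new_role(vit, f"{vit}_{tag}_r{i}") for i in range(n_roles)]
                variants.append(
                    PathwayVariant(f"{vit}_{tag}", vit, tuple(rids), frozenset(rids), tag)
                )
        else:
            for j in range(variants_per_vitamin):
                rids = [new_role(vit, f"{vit}_v{j}_r{i}") for i in range(roles_per_variant)]
                variants.append(
                    PathwayVariant(f"{vit}_v{j}", vit, tuple(rids), frozenset(rids), f"branch{j}")
                )

    def util_kos(n: int) -> frozenset[str]:
        nonlocal counter
        out = frozenset(f"K{counter + i:05d}" for i in range(n))
        counter += n
        return out

    util = CobalaminUtilizationLists(
        transporter_roles={"btuB": util_kos(1), "btuFCD": util_kos(3), "cbrT": util_kos(1)},
        dependent_enzyme_roles={"metH": util_kos(1), "MCM": util_kos(2), "nrdJ": util_kos(1)},
    )
    return KnowledgeBase(
        version=f"synthetic-kb-seed{seed}",
        roles=tuple(roles),
        variants=tuple(variants),
        cobalamin_utilization=util,
    )


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def _vitamin_routes(kb: KnowledgeBase, vitamin: str) -> list[tuple[str, frozenset[str]]]:
    """(route id, indispensable KO set) per producing route of a vitamin."""
    early = kb.early_variants(vitamin)
    posts = kb.post_cobyrinate_variants(vitamin)

    def kos_of(variant: PathwayVariant) -> frozenset[str]:
        out: set[str] = set()
        for rid in variant.indispensable_role_ids:
            out |= kb.role(rid).ko_ids
        return frozenset(out)

    if posts:
        return [
            (e.variant_id, kos_of(e) | kos_of(p)) for e in early for p in posts
        ]
    return [(v.variant_id, kos_of(v)) for v in early]


def simulate_genomes(
    kb: KnowledgeBase,
    n_genomes: int,
    capability_design: Mapping[str, float],
    dropout: float = 0.0,
    seed: int = 0,
    partial_rate: float = 0.35,
) -> tuple[list[GenomeAnnotation], PlantedTruth]:
    """Plant per-vitamin producer capabilities into synthetic genomes.

    For each vitamin, ``round(fraction × n_genomes)`` genomes are planted as
    producers and receive every KO of the indispensable roles of one
    randomly chosen route (for cobalamin: an early segment plus the
    post-cobyrinate segment).  Non-producers receive a random subset of the
    vitamin's KOs constructed so that at least one indispensable role of
    every variant is fully absent — planted truth is never ambiguous.
    After planting, every KO is independently dropped with probability
    ``dropout``; truth records the pre-dropout intent.
    """
    for vit, frac in capability_design.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"producer fraction for {vit} outside [0, 1]: {frac}")
    if not 0 <= dropout < 1:
        raise ValueError(f"dropout outside [0, 1): {dropout}")
    rng = np.random.default_rng(seed)
    vitamins = kb.vitamins
    truth = PlantedTruth(
        seed=seed,
        parameters={
            "n_genomes": n_genomes,
            "capability_design": dict(capability_design),
            "dropout": dropout,
            "partial_rate": partial_rate,
        },
    )
    gids = [f"G{i + 1:04d}" for i in range(n_genomes)]
    producer_idx: dict[str, set[int]] = {}
    for vit in vitamins:
        frac = capability_design.get(vit, 0.0)
        n_prod = int(round(frac * n_genomes))
        producer_idx[vit] = set(
            rng.choice(n_genomes, size=n_prod, replace=False).tolist()
        ) if n_prod else set()

    phyla = sorted(TAXA_ONTOLOGY)
    genomes: list[GenomeAnnotation] = []
    for i, gid in enumerate(gids):
        ko_set: set[str] = set()
        truth.capability[gid] = {}
        truth.chosen_variants[gid] = {}
        cob_partial = False
        for vit in vitamins:
            is_producer = i in producer_idx[vit]
            truth.capability[gid][vit] = bool(is_producer)
            routes = _vitamin_routes(kb, vit)
            if is_producer:
                ridx = int(rng.integers(len(routes)))
                route_id, kos = routes[ridx]
                ko_set |= kos
                truth.chosen_variants[gid][vit] = route_id
            else:
                # exclude >=1 indispensable role of EVERY variant, then keep
                # a random subset of the remaining roles' KOs
                excluded: set[str] = set()
                for v in kb.variants_for(vit):
                    ind = sorted(v.indispensable_role_ids)
                    pick = ind[int(rng.integers(len(ind)))]
                    excluded.add(pick)
                allowed_kos: set[str] = set()
                for r in kb.roles_for(vit):
                    if r.role_id not in excluded and rng.random() < partial_rate:
                        allowed_kos |= r.ko_ids
                ko_set |= allowed_kos
                if vit == "COB" and allowed_kos:
                    cob_partial = True
        if "COB" in vitamins:
            if truth.capability[gid].get("COB"):
                truth.cobalamin_class[gid] = "complete"
            elif cob_partial:
                truth.cobalamin_class[gid] = "partial"
            else:
                truth.cobalamin_class[gid] = "absent"
        if dropout > 0:
            ko_sorted = sorted(ko_set)
            keep = rng.random(len(ko_sorted)) >= dropout
            ko_set = {ko for ko, k in zip(ko_sorted, keep) if k}

        phylum = phyla[int(rng.integers(len(phyla)))]
        genus = TAXA_ONTOLOGY[phylum][int(rng.integers(len(TAXA_ONTOLOGY[phylum])))]
        genomes.append(
            GenomeAnnotation(
                genome_id=gid,
                ko_set=frozenset(ko_set),
                completeness=float(np.round(rng.uniform(92.0, 100.0), 2)),
                contamination=float(np.round(rng.uniform(0.0, 4.5), 2)),
                taxonomy=("Bacteria" if phylum != "Euryarchaeota" else "Archaea",
                          phylum, "", "", "", genus),
                assembly_size=int(rng.integers(1_500_000, 5_000_000)),
                source_region=GIT_REGIONS[int(rng.integers(len(GIT_REGIONS)))],
            )
        )
    return genomes, truth


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _ko_vitamin_map(kb: KnowledgeBase) -> dict[str, str]:
    out: dict[str, str] = {}
    for r in kb.roles:
        for ko in r.ko_ids:
            out.setdefault(ko, r.vitamin)
    return out


def simulate_community(
    kb: KnowledgeBase,
    genomes: Sequence[GenomeAnnotation],
    n_groups: int = 2,
    samples_per_group: int = 12,
    effect_design: Optional[Mapping[str, Sequence[float] | float]] = None,
    sequencing_depth: int = 1_000_000,
    seed: int = 0,
    background_genes_per_genome: int = 100,
    background_weight: float = 30.0,
    genome_sigma: float = 0.3,
    group_labels: Optional[Sequence[str]] = None,
    genome_truth: Optional[PlantedTruth] = None,
) -> SyntheticDataset:
    """Build a multi-group metagenome dataset with planted fold changes.

    A gene catalog is derived from the genomes: one gene per (genome, KO in
    the KB universe) plus unannotated background genes, lengths uniform on
    [300, 3000] bp, taxonomy inherited from the genome.  Each genome gets a
    log-normal base abundance; in group g the per-base rate of a vitamin
    gene is multiplied by that vitamin's planted fold change, so the
    expected pathway TPM fold holds by construction.  Per sample, genome
    abundances receive group-independent log-normal jitter (sd
    ``genome_sigma``) and ``sequencing_depth`` reads are drawn
    multinomially.  Deterministic per seed.

    Background (non-vitamin) genes carry ``background_weight`` times the
    per-base rate of a vitamin gene, so that vitamin pathways make up only
    a small share of each sample — as in a whole-metagenome catalog, where
    vitamin genes are a tiny fraction of the gene content and the TPM
    denominator is dominated by everything else.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if sequencing_depth < 1000:
        raise ValueError("sequencing_depth must be >= 1000")
    labels = list(group_labels) if group_labels else [f"G{g + 1}" for g in range(n_groups)]
    if len(labels) != n_groups:
        raise ValueError("group_labels length must equal n_groups")
    effect_design = dict(effect_design or {})
    folds: dict[str, np.ndarray] = {}
    for vit in kb.vitamins:
        requested = effect_design.get(vit, 1.0)
        if np.isscalar(requested):
            arr = np.array([1.0] + [float(requested)] * (n_groups - 1))
        else:
            arr = np.asarray(requested, dtype=float)
            if arr.size != n_groups:
                raise ValueError(f"fold vector for {vit} must have {n_groups} entries")
        if (arr <= 0).any():
            raise ValueError(f"fold change <= 0 for vitamin {vit}")
        folds[vit] = arr

    rng = np.random.default_rng(seed)
    ko2vit = _ko_vitamin_map(kb)

    catalog: list[GeneRecord] = []
    gene_genome: list[int] = []
    gene_vitamin: list[str] = []
    base_weight = rng.lognormal(mean=0.0, sigma=1.0, size=len(genomes))
    for gi, g in enumerate(sorted(genomes, key=lambda x: x.genome_id)):
        vit_kos = sorted(ko for ko in g.ko_set if ko in ko2vit)
        for ko in vit_kos:
            catalog.append(
                GeneRecord(
                    gene_id=f"{g.genome_id}|{ko}",
                    length=int(rng.integers(300, 3001)),
                    ko_id=ko,
                    phylum=g.phylum,
                    genus=g.genus,
                )
            )
            gene_genome.append(gi)
            gene_vitamin.append(ko2vit[ko])
        for b in range(background_genes_per_genome):
            catalog.append(
                GeneRecord(
                    gene_id=f"{g.genome_id}|bg{b + 1:03d}",
                    length=int(rng.integers(300, 3001)),
                    ko_id="",
                    phylum=g.phylum,
                    genus=g.genus,
                )
            )
            gene_genome.append(gi)
            gene_vitamin.append("")

    n_genes = len(catalog)
    gene_genome_arr = np.array(gene_genome)
    lengths = np.array([g.length for g in catalog], dtype=float)
    # per-base rate per gene and group
    rate = np.empty((n_genes, n_groups))
    for g in range(n_groups):
        fold_vec = np.array(
            [folds[v][g] if v else background_weight for v in gene_vitamin],
            dtype=float,
        )
        rate[:, g] = base_weight[gene_genome_arr] * fold_vec

    truth = genome_truth if genome_truth is not None else PlantedTruth(seed=seed)
    truth.parameters.update(
        {
            "n_groups": n_groups,
            "samples_per_group": samples_per_group,
            "sequencing_depth": sequencing_depth,
            "genome_sigma": genome_sigma,
            "background_genes_per_genome": background_genes_per_genome,
            "background_weight": background_weight,
            "community_seed": seed,
        }
    )
    for vit in kb.vitamins:
        truth.pathway_fold_changes[vit] = {
            lab: float(folds[vit][g]) for g, lab in enumerate(labels)
        }
        truth.expected_pathway_tpm[vit] = {}
    # analytic expected TPM (no jitter): TPM share of gene = rate / sum(rate)
    for g, lab in enumerate(labels):
        denom = rate[:, g].sum()
        for vit in kb.vitamins:
            mask = np.array([v == vit for v in gene_vitamin])
            truth.expected_pathway_tpm[vit][lab] = float(
                rate[mask, g].sum() / denom * 1e6
            )
    # taxon-share truth in the first group
    phyla = np.array([g.phylum for g in catalog])
    for vit in kb.vitamins:
        mask = np.array([v == vit for v in gene_vitamin])
        vit_total = rate[mask, 0].sum()
        shares: dict[str, float] = {}
        if vit_total > 0:
            for ph in sorted(set(phyla[mask])):
                sel = mask & (phyla == ph)
                shares[ph or "unassigned"] = float(rate[sel, 0].sum() / vit_total)
        truth.expected_taxon_shares[vit] = shares

    sample_ids: list[str] = []
    columns: dict[str, np.ndarray] = {}
    for g, lab in enumerate(labels):
        for t in range(samples_per_group):
            sid = f"{lab}_{t + 1:02d}"
            sample_ids.append(sid)
            truth.sample_groups[sid] = lab
            jitter = rng.lognormal(0.0, genome_sigma, size=len(genomes)) if genome_sigma > 0 else np.ones(len(genomes))
            read_rate = rate[:, g] * jitter[gene_genome_arr] * lengths
            p = read_rate / read_rate.sum()
            columns[sid] = rng.multinomial(sequencing_depth, p)
    counts = pd.DataFrame(columns, index=[g.gene_id for g in catalog])
    counts.index.name = "gene_id"
    return SyntheticDataset(
        kb=kb,
        genomes=list(genomes),
        catalog=catalog,
        counts=counts,
        sample_groups=pd.Series(truth.sample_groups, name="group"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Producer fractions used by both presets: most genomes synthesize few
#: vitamins, cobalamin producers are rare.
_PRESET_CAPABILITY = {
    "THI": 0.30, "RIB": 0.30, "NIA": 0.25, "PAN": 0.20, "PYR": 0.10,
    "BIO": 0.20, "FOL": 0.20, "COB": 0.15, "MEN": 0.20,
}

#: Diet contrast (high-forage control vs high-grain): cobalamin synthesis
#: halved in the high-grain group, most other vitamins enhanced, pyridoxine
#: unchanged.
DIET_FOLDS = {
    "THI": 1.6, "RIB": 1.6, "NIA": 1.5, "PAN": 1.4, "PYR": 1.0,
    "BIO": 1.5, "FOL": 1.4, "COB": 0.5, "MEN": 1.5,
}

#: Regional contrast: thiamine, niacin, and pyridoxine elevated in the
#: large intestine (cecum, colon, rectum) relative to the forestomach.
_LARGE_INTESTINE = {"CEC", "COL", "REC"}
REGION_FOLDS = {
    vit: [2.0 if (r in _LARGE_INTESTINE and vit in {"THI", "NIA", "PYR"}) else 1.0
          for r in GIT_REGIONS]
    for vit in VITAMINS
}


def preset_dataset(preset: str, seed: int = 0, **overrides) -> SyntheticDataset:
    """Build the ``diet`` or ``region`` study preset.

    ``diet``: two groups (CON vs HG), 12 samples each, depth 10^6, planted
    cobalamin fold 0.5 and most other vitamins ≥ 1.4.  ``region``: ten GIT
    regions, 5 samples each, depth 10^5, thiamine/niacin/pyridoxine doubled
    in the large intestine.  Both simulate 60 genomes from the default
    producer-fraction design.  Keyword overrides are forwarded to
    :func:`simulate_community`.
    """
    from .knowledge import default_knowledge_base

    kb = overrides.pop("kb", None) or default_knowledge_base()
    n_genomes = overrides.pop("n_genomes", 60)
    genomes, truth = simulate_genomes(
        kb, n_genomes, _PRESET_CAPABILITY, dropout=0.0, seed=seed
    )
    if preset == "diet":
        params = dict(
            n_groups=2, samples_per_group=12, effect_design=DIET_FOLDS,
            sequencing_depth=1_000_000, group_labels=["CON", "HG"],
        )
    elif preset == "region":
        params = dict(
            n_groups=10, samples_per_group=5, effect_design=REGION_FOLDS,
            sequencing_depth=100_000, group_labels=list(GIT_REGIONS),
        )
    else:
        raise ValueError(f"unknown preset {preset!r} (expected 'diet' or 'region')")
    params.update(overrides)
    return simulate_community(
        kb, genomes, seed=seed + 1, genome_truth=truth, **params
    )
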