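"""Metagenome abundance profiling: read counts → TPM → KO / role / pathway /
taxon abundance tables.

TPM (transcripts per million) length-normalizes each gene's counts and
rescales every sample to a fixed total of 10^6, so abundances are
comparable across samples of different sequencing depth.  The denominator
runs over the whole gene catalog, not just vitamin genes: profiles of the
full catalog are computed first and vitamin genes are subset afterwards,
which changes absolute values relative to a vitamin-only normalization.

Aggregation is summation: a KO's abundance is the TPM sum of its genes, a
functional role's abundance is the sum over its KOs, and a vitamin pathway's
abundance is the sum over the vitamin's KO universe (each KO counted once,
however many variants reference it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .knowledge import KnowledgeBase, ko_universe

__all__ = [
    "GeneRecord",
    "ProfileTable",
    "compute_tpm",
    "aggregate_ko",
    "aggregate_role",
    "pathway_abundance",
    "taxon_breakdown",
    "UNASSIGNED",
]

#: Bucket label for genes lacking the requested taxonomic rank.
UNASSIGNED = "unassigned"

TPM_TOTAL = 1_000_000.0


@dataclass(frozen=True)
class GeneRecord:
    """One catalog gene: length plus optional KO and taxonomy labels."""

    gene_id: str
    length: int
    ko_id: str = ""
    phylum: str = ""
    genus: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id!r}: non-positive length {self.length}")


@dataclass(frozen=True)
class ProfileTable:
    """An entities × samples abundance table with provenance.

    ``level`` is one of ``KO``, ``role``, ``pathway``, ``taxon``.
    """

    level: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _catalog_frame(catalog: Sequence[GeneRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in catalog],
            "length": [g.length for g in catalog],
            "ko_id": [g.ko_id for g in catalog],
            "phylum": [g.phylum for g in catalog],
            "genus": [g.genus for g in catalog],
        }
    ).set_index("gene_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"gene catalog: duplicate gene_id {dup!r}")
    return df


def compute_tpm(counts: pd.DataFrame, catalog: Sequence[GeneRecord]) -> pd.DataFrame:
    """Length-normalize counts and scale each sample to 10^6.

    ``counts`` is genes × samples (non-negative).  Every counted gene must
    have a catalog length; the per-sample denominator is the rate sum over
    the *entire* catalog (genes absent from ``counts`` contribute zero).
    All-zero sample columns stay all-zero rather than raising.
    """
    cat = _catalog_frame(catalog)
    missing = counts.index.difference(cat.index)
    if len(missing):
        raise ValueError(f"counts reference genes missing from catalog: {list(missing[:5])}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    lengths = cat.loc[counts.index, "length"].to_numpy(dtype=float)
    rates = counts.to_numpy(dtype=float) / lengths[:, None]
    denom = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(denom > 0, rates / denom * TPM_TOTAL, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def aggregate_ko(tpm: pd.DataFrame, catalog: Sequence[GeneRecord]) -> ProfileTable:
    """Sum gene TPM per annotated KO; unannotated genes contribute nowhere."""
    cat = _catalog_frame(catalog)
    ko = cat.loc[tpm.index, "ko_id"]
    keep = ko != ""
    grouped = tpm.loc[keep].groupby(ko[keep]).sum()
    grouped.index.name = "ko_id"
    return ProfileTable(level="KO", data=grouped.sort_index(), provenance={})


def aggregate_role(ko_profile: ProfileTable, kb: KnowledgeBase) -> ProfileTable:
    """Role abundance = sum of the role's KO abundances."""
    data = ko_profile.data
    rows = {}
    for r in kb.roles:
        present = data.index.intersection(sorted(r.ko_ids))
        rows[r.role_id] = (
            data.loc[present].sum(axis=0) if len(present) else pd.Series(0.0, index=data.columns)
        )
    out = pd.DataFrame(rows).T
    out.index.name = "role_id"
    return ProfileTable(
        level="role", data=out, provenance={"kb_version": kb.version}
    )


def pathway_abundance(ko_profile: ProfileTable, kb: KnowledgeBase) -> ProfileTable:
    """Vitamin pathway abundance = sum over the vitamin's KO universe.

    Each KO is counted once per vitamin even if several variants (or roles
    shared between variants) reference it.
    """
    data = ko_profile.data
    rows = {}
    for vitamin in kb.vitamins:
        kos = sorted(ko_universe(kb, vitamin))
        present = data.index.intersection(kos)
        rows[vitamin] = (
            data.loc[present].sum(axis=0) if len(present) else pd.Series(0.0, index=data.columns)
        )
    out = pd.DataFrame(rows).T
    out.index.name = "vitamin"
    return ProfileTable(
        level="pathway", data=out, provenance={"kb_version": kb.version}
    )


def taxon_breakdown(
    tpm: pd.DataFrame,
    catalog: Sequence[GeneRecord],
    kb: KnowledgeBase,
    vitamin: str,
    rank: str = "phylum",
) -> ProfileTable:
    """Attribute one vitamin's gene TPM to taxa at the given rank.

    Genes of the vitamin (by KO universe) are grouped by their ``rank``
    label; genes lacking the label fall into the explicit ``unassigned``
    bucket.  Per sample, the taxon rows sum to the vitamin's pathway
    abundance, so normalized shares over taxa + unassigned sum to 1.
    """
    if rank not in ("phylum", "genus"):
        raise ValueError(f"unsupported rank {rank!r}")
    kos = ko_universe(kb, vitamin)  # raises KeyError on unknown vitamin
    cat = _catalog_frame(catalog)
    sub = cat.loc[tpm.index]
    mask = sub["ko_id"].isin(sorted(kos))
    labels = sub.loc[mask, rank].replace("", UNASSIGNED)
    grouped = tpm.loc[mask].groupby(labels).sum()
    grouped.index.name = rank
    return ProfileTable(
        level="taxon",
        data=grouped.sort_index(),
        provenance={"kb_version": kb.version, "vitamin": vitamin, "rank": rank},
    )
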