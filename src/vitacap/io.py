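"""Readers and writers for the TSV/JSON interchange dialects.

All tabular interchange is tab-separated UTF-8 with LF line endings and
documented headers; nested results (AMOVA, run manifests, planted truth)
are JSON.  Writers are bit-stable: the same inputs always produce the same
bytes.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .capability import GenomeAnnotation, LINEAGE_RANKS, CapabilityCall, CobalaminClass
from .profiling import GeneRecord, ProfileTable

_TSV = dict(sep="\t", lineterminator="\n", encoding="utf-8")

ANNOTATION_HEADER = ["genome_id", "ko_id"]
GENOME_METADATA_HEADER = [
    "genome_id", "completeness", "contamination",
    *LINEAGE_RANKS, "assembly_size_bp", "source_region",
]
CATALOG_HEADER = ["gene_id", "length_bp", "ko_id", "phylum", "genus"]


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def write_genomes(
    genomes: Sequence[GenomeAnnotation],
    annotations_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the (genome_id, ko_id) long table and the metadata table."""
    ann_rows = [
        {"genome_id": g.genome_id, "ko_id": ko}
        for g in genomes
        for ko in sorted(g.ko_set)
    ]
    pd.DataFrame(ann_rows, columns=ANNOTATION_HEADER).to_csv(
        annotations_path, index=False, **_TSV
    )
    meta_rows = []
    for g in genomes:
        row = {
            "genome_id": g.genome_id,
            "completeness": g.completeness,
            "contamination": g.contamination,
            "assembly_size_bp": g.assembly_size,
            "source_region": g.source_region or "",
        }
        for rank, value in zip(LINEAGE_RANKS, g.taxonomy):
            row[rank] = value
        meta_rows.append(row)
    pd.DataFrame(meta_rows, columns=GENOME_METADATA_HEADER).to_csv(
        metadata_path, index=False, **_TSV
    )


def read_genomes(
    annotations_path: str | Path, metadata_path: str | Path
) -> list[GenomeAnnotation]:
    """Read genome annotations + metadata back into GenomeAnnotation records.

    Duplicate (genome, KO) rows collapse; genomes present in the metadata
    but absent from the annotation table get an empty KO set.
    """
    ann = pd.read_csv(annotations_path, sep="\t", dtype=str, keep_default_na=False)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ANNOTATION_HEADER:
        if col not in ann.columns:
            raise ValueError(f"annotation table: missing column {col!r}")
    for col in ("genome_id", "completeness", "contamination"):
        if col not in meta.columns:
            raise ValueError(f"genome metadata: missing column {col!r}")
    ko_by_genome = ann.groupby("genome_id")["ko_id"].agg(lambda s: frozenset(s) - {""})
    genomes = []
    for _, row in meta.iterrows():
        gid = row["genome_id"]
        genomes.append(
            GenomeAnnotation(
                genome_id=gid,
                ko_set=ko_by_genome.get(gid, frozenset()),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                taxonomy=tuple(row.get(r, "") for r in LINEAGE_RANKS),
                assembly_size=int(float(row.get("assembly_size_bp", 0) or 0)) or 2_000_000,
                source_region=row.get("source_region") or None,
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# catalog & counts
# ---------------------------------------------------------------------------

def write_catalog(catalog: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "length_bp": g.length, "ko_id": g.ko_id,
             "phylum": g.phylum, "genus": g.genus}
            for g in catalog
        ],
        columns=CATALOG_HEADER,
    ).to_csv(path, index=False, **_TSV)


def read_catalog(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in CATALOG_HEADER:
        if col not in df.columns:
            raise ValueError(f"gene catalog: missing column {col!r}")
    return [
        GeneRecord(
            gene_id=row["gene_id"],
            length=int(row["length_bp"]),
            ko_id=row["ko_id"],
            phylum=row["phylum"],
            genus=row["genus"],
        )
        for _, row in df.iterrows()
    ]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=True, index_label="gene_id", **_TSV)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts table: wide (gene_id + sample columns) or sparse
    triplet (gene_id, sample_id, count)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) == ["gene_id", "sample_id", "count"] and df.shape[1] == 3:
        wide = df.pivot_table(
            index="gene_id", columns="sample_id", values="count", fill_value=0
        )
        wide.columns.name = None
        return wide.astype(int)
    return df.set_index("gene_id")


def read_sample_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("sample metadata: need columns sample_id, group")
    return df.set_index("sample_id")["group"]


def write_sample_groups(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").to_frame().to_csv(
        path, index=True, index_label="sample_id", **_TSV
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_profile(profile: ProfileTable | pd.DataFrame, path: str | Path) -> None:
    data = profile.data if isinstance(profile, ProfileTable) else profile
    data.to_csv(path, index=True, float_format="%.10g", **_TSV)


def read_profile(path: str | Path, level: str = "") -> ProfileTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProfileTable(level=level or "KO", data=df, provenance={"path": str(path)})


def write_capability_calls(calls: Iterable[CapabilityCall], path: str | Path) -> None:
    from .capability import capability_table

    capability_table(calls).to_csv(path, index=True, **_TSV)


def write_cobalamin_classes(classes: Iterable[CobalaminClass], path: str | Path) -> None:
    rows = [
        {
            "genome_id": c.genome_id,
            "biosynthesis_class": c.biosynthesis_class,
            "has_transporter": int(c.has_transporter),
            "has_dependent_enzyme": int(c.has_dependent_enzyme),
            "transporters": ",".join(c.present_transporters),
            "dependent_enzymes": ",".join(c.present_enzymes),
        }
        for c in classes
    ]
    pd.DataFrame(rows).to_csv(path, index=False, **_TSV)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    parameters: dict,
    inputs: Sequence[str | Path] = (),
    seed: Optional[int] = None,
) -> Path:
    """Write (or append a stage to) the run manifest in ``out_dir``.

    Records the stage name, parameters, seed, package version, and a
    sha256 of every input file — enough to reproduce the run.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text(encoding="utf-8"))
        if manifest_path.exists()
        else {"package": "vitacap", "version": __version__, "stages": []}
    )
    manifest["stages"].append(
        {
            "stage": stage,
            "seed": seed,
            "parameters": {k: str(v) for k, v in sorted(parameters.items())},
            "inputs": {
                str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()
            },
            "python": sys.version.split()[0],
        }
    )
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest_path


def write_dataset(dataset, out_dir: str | Path) -> None:
    """Write a SyntheticDataset in the exact dialects the pipeline reads."""
    from .knowledge import save_knowledge_base

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_knowledge_base(dataset.kb, out_dir / "kb.json")
    write_genomes(
        dataset.genomes, out_dir / "annotations.tsv", out_dir / "genome_metadata.tsv"
    )
    write_catalog(dataset.catalog, out_dir / "catalog.tsv")
    write_counts(dataset.counts, out_dir / "counts.tsv")
    write_sample_groups(dataset.sample_groups, out_dir / "sample_metadata.tsv")
    dataset.truth.save(out_dir / "truth.json")
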