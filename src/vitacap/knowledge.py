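"""Vitamin-pathway knowledge base: functional roles, pathway variants, and
cobalamin utilization gene lists.

The knowledge base (KB) encodes, for each of the eight B vitamins and
menaquinone (vitamin K2), the KEGG-orthology content of its de novo
biosynthesis pathway.  KOs that catalyse the same reaction step are grouped
into a *functional role*; alternative routes to the vitamin (e.g. the thiH
vs. thiO branches of thiamine synthesis, or the aerobic vs. anaerobic
corrin-ring pathways of cobalamin) are *pathway variants*, each carrying the
set of roles that are indispensable for calling a genome a de novo producer.

Cobalamin is special: its early corrin-ring segments (anaerobic, aerobic)
converge on cob(II)yrinate a,c-diamide, after which a shared
``post_cobyrinate`` segment completes adenosylcobalamin synthesis.  The KB
also carries the corrinoid *utilization* lists — transporters (btuBFCD,
cbrT/cbrV) and cobalamin-dependent enzymes (metH, MCM, nrdJ, ...) — used to
type consumer genomes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "VITAMINS",
    "FunctionalRole",
    "PathwayVariant",
    "CobalaminUtilizationLists",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "default_knowledge_base",
    "validate_knowledge_base",
    "ko_universe",
    "kb_from_dict",
    "kb_to_dict",
    "save_knowledge_base",
]

#: The nine vitamins covered: thiamine, riboflavin, niacin, pantothenate,
#: pyridoxine, biotin, folate, cobalamin, menaquinone.
VITAMINS = ("THI", "RIB", "NIA", "PAN", "PYR", "BIO", "FOL", "COB", "MEN")

_KO_PATTERN = re.compile(r"^K\d{5}$")
_ALIAS_PATTERN = re.compile(r"^[A-Za-z][A-Za-z0-9_.\-]*$")

_DEFAULT_KB_PATH = Path(__file__).parent / "data" / "default_kb.json"


class KnowledgeBaseError(ValueError):
    """Raised when a KB file is missing, malformed, or fails validation."""


def _valid_ko_token(token: str) -> bool:
    """A KB member is either a KEGG KO id (K#####) or a curated gene-symbol
    alias (e.g. ``MMAB``, ``cobNST``) standing in for one or more KOs."""
    return bool(_KO_PATTERN.match(token) or _ALIAS_PATTERN.match(token))


@dataclass(frozen=True)
class FunctionalRole:
    """A pathway step: the set of KOs performing one function.

    ``ko_ids`` may mix K-number ids with curated gene-symbol aliases; both
    are matched verbatim against genome annotations.
    """

    role_id: str
    vitamin: str
    ko_ids: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ko_ids", frozenset(self.ko_ids))


@dataclass(frozen=True)
class PathwayVariant:
    """One alternative route to a vitamin.

    ``indispensable_role_ids`` are the roles a genome must carry (at least
    one KO each) for this variant to count as satisfied.  ``segment_tag``
    marks branch identity — for cobalamin one of ``anaerobic`` / ``aerobic``
    (early corrin-ring segments) or ``post_cobyrinate`` (shared late steps);
    for menaquinone ``classical`` / ``futalosine``; free-form otherwise.
    """

    variant_id: str
    vitamin: str
    role_ids: tuple[str, ...]
    indispensable_role_ids: frozenset[str]
    segment_tag: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role_ids", tuple(self.role_ids))
        object.__setattr__(
            self, "indispensable_role_ids", frozenset(self.indispensable_role_ids)
        )


@dataclass(frozen=True)
class CobalaminUtilizationLists:
    """Corrinoid transporter and cobalamin-dependent-enzyme gene lists.

    Maps each role symbol (e.g. ``btuB``, ``metH``) to its KO-id set.  These
    mark cobalamin *consumers* and are disjoint from the biosynthesis roles.
    """

    transporter_roles: Mapping[str, frozenset[str]]
    dependent_enzyme_roles: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "transporter_roles",
            {k: frozenset(v) for k, v in dict(self.transporter_roles).items()},
        )
        object.__setattr__(
            self,
            "dependent_enzyme_roles",
            {k: frozenset(v) for k, v in dict(self.dependent_enzyme_roles).items()},
        )

    @property
    def transporter_kos(self) -> frozenset[str]:
        return frozenset().union(*self.transporter_roles.values()) if self.transporter_roles else frozenset()

    @property
    def dependent_enzyme_kos(self) -> frozenset[str]:
        return frozenset().union(*self.dependent_enzyme_roles.values()) if self.dependent_enzyme_roles else frozenset()


@dataclass(frozen=True)
class KnowledgeBase:
    """The full vitamin-pathway knowledge base."""

    version: str
    roles: tuple[FunctionalRole, ...]
    variants: tuple[PathwayVariant, ...]
    cobalamin_utilization: CobalaminUtilizationLists
    _roles_by_id: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "_roles_by_id", {r.role_id: r for r in self.roles})

    # -- lookups -----------------------------------------------------------
    def role(self, role_id: str) -> FunctionalRole:
        return self._roles_by_id[role_id]

    def has_role(self, role_id: str) -> bool:
        return role_id in self._roles_by_id

    @property
    def vitamins(self) -> tuple[str, ...]:
        """Vitamins present, in canonical order."""
        present = {r.vitamin for r in self.roles}
        return tuple(v for v in VITAMINS if v in present) + tuple(
            sorted(present - set(VITAMINS))
        )

    def variants_for(self, vitamin: str) -> tuple[PathwayVariant, ...]:
        return tuple(v for v in self.variants if v.vitamin == vitamin)

    def roles_for(self, vitamin: str) -> tuple[FunctionalRole, ...]:
        return tuple(r for r in self.roles if r.vitamin == vitamin)

    def post_cobyrinate_variants(self, vitamin: str = "COB") -> tuple[PathwayVariant, ...]:
        return tuple(
            v for v in self.variants_for(vitamin) if v.segment_tag == "post_cobyrinate"
        )

    def early_variants(self, vitamin: str) -> tuple[PathwayVariant, ...]:
        """Variants other than the shared post-cobyrinate segment."""
        return tuple(
            v for v in self.variants_for(vitamin) if v.segment_tag != "post_cobyrinate"
        )

    def ko_universe(self, vitamin: Optional[str] = None) -> frozenset[str]:
        return ko_universe(self, vitamin)


def ko_universe(kb: KnowledgeBase, vitamin: Optional[str] = None) -> frozenset[str]:
    """Union of KO ids over all roles, or over one vitamin's roles.

    Defines which gene-catalog entries count as "vitamin genes".
    Raises ``KeyError`` for an unknown vitamin id.
    """
    if vitamin is not None:
        if vitamin not in {r.vitamin for r in kb.roles}:
            raise KeyError(f"unknown vitamin id: {vitamin!r}")
        roles: Iterable[FunctionalRole] = (r for r in kb.roles if r.vitamin == vitamin)
    else:
        roles = kb.roles
    out: set[str] = set()
    for r in roles:
        out |= r.ko_ids
    return frozenset(out)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_knowledge_base(kb: KnowledgeBase) -> list[str]:
    """Check every KB invariant; return a list of human-readable violations.

    An empty list means the KB is valid.  Each violation names the offending
    entity (role id, variant id, KO id, or vitamin).
    """
    violations: list[str] = []

    seen_roles: set[str] = set()
    ko_owner: dict[tuple[str, str], str] = {}
    for r in kb.roles:
        if r.role_id in seen_roles:
            violations.append(f"role {r.role_id!r}: duplicate role_id")
        seen_roles.add(r.role_id)
        if r.vitamin not in VITAMINS:
            violations.append(f"role {r.role_id!r}: unknown vitamin {r.vitamin!r}")
        if not r.ko_ids:
            violations.append(f"role {r.role_id!r}: empty ko_ids")
        for ko in r.ko_ids:
            if not _valid_ko_token(ko):
                violations.append(f"role {r.role_id!r}: malformed KO token {ko!r}")
            key = (r.vitamin, ko)
            if key in ko_owner and ko_owner[key] != r.role_id:
                violations.append(
                    f"KO {ko!r}: assigned to two roles of vitamin {r.vitamin} "
                    f"({ko_owner[key]!r} and {r.role_id!r})"
                )
            ko_owner.setdefault(key, r.role_id)

    vitamins_with_roles = {r.vitamin for r in kb.roles}
    seen_variants: set[str] = set()
    for v in kb.variants:
        if v.variant_id in seen_variants:
            violations.append(f"variant {v.variant_id!r}: duplicate variant_id")
        seen_variants.add(v.variant_id)
        for rid in v.role_ids:
            if not kb.has_role(rid):
                violations.append(
                    f"variant {v.variant_id!r}: dangling role reference {rid!r}"
                )
        if not set(v.indispensable_role_ids) <= set(v.role_ids):
            extra = sorted(set(v.indispensable_role_ids) - set(v.role_ids))
            violations.append(
                f"variant {v.variant_id!r}: indispensable roles {extra} not in role_ids"
            )
        if not v.indispensable_role_ids:
            violations.append(
                f"variant {v.variant_id!r}: empty indispensable_role_ids"
            )

    for vit in vitamins_with_roles:
        if not any(v.vitamin == vit for v in kb.variants):
            violations.append(f"vitamin {vit}: no pathway variant defined")

    if "COB" in vitamins_with_roles:
        tags = {v.segment_tag for v in kb.variants if v.vitamin == "COB"}
        for needed in ("anaerobic", "aerobic", "post_cobyrinate"):
            if needed not in tags:
                violations.append(f"vitamin COB: missing {needed!r} segment variant")

    util = kb.cobalamin_utilization
    if not util.transporter_roles:
        violations.append("cobalamin_utilization: empty transporter_roles")
    if not util.dependent_enzyme_roles:
        violations.append("cobalamin_utilization: empty dependent_enzyme_roles")
    cob_biosynth_kos: set[str] = set()
    for r in kb.roles:
        if r.vitamin == "COB":
            cob_biosynth_kos |= r.ko_ids
    overlap = (util.transporter_kos | util.dependent_enzyme_kos) & cob_biosynth_kos
    for ko in sorted(overlap):
        violations.append(
            f"cobalamin_utilization: KO {ko!r} overlaps COB biosynthesis roles"
        )

    return violations


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def kb_from_dict(data: Mapping) -> KnowledgeBase:
    """Build a KB from the documented config mapping (see data/kb.schema.json)."""
    for key in ("version", "roles", "variants", "cobalamin_utilization"):
        if key not in data:
            raise KnowledgeBaseError(f"KB config: missing top-level key {key!r}")
    try:
        roles = tuple(
            FunctionalRole(
                role_id=str(r["role_id"]),
                vitamin=str(r["vitamin"]),
                ko_ids=frozenset(r["ko_ids"]),
                label=str(r.get("label", "")),
            )
            for r in data["roles"]
        )
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(f"KB config: malformed roles entry ({exc})") from exc
    try:
        variants = tuple(
            PathwayVariant(
                variant_id=str(v["variant_id"]),
                vitamin=str(v["vitamin"]),
                role_ids=tuple(v["role_ids"]),
                indispensable_role_ids=frozenset(v["indispensable_role_ids"]),
                segment_tag=v.get("segment_tag"),
            )
            for v in data["variants"]
        )
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(f"KB config: malformed variants entry ({exc})") from exc
    util = data["cobalamin_utilization"]
    try:
        cobalamin_utilization = CobalaminUtilizationLists(
            transporter_roles={
                k: frozenset(v) for k, v in util["transporter_roles"].items()
            },
            dependent_enzyme_roles={
                k: frozenset(v) for k, v in util["dependent_enzyme_roles"].items()
            },
        )
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(
            f"KB config: malformed cobalamin_utilization ({exc})"
        ) from exc
    return KnowledgeBase(
        version=str(data["version"]),
        roles=roles,
        variants=variants,
        cobalamin_utilization=cobalamin_utilization,
    )


def kb_to_dict(kb: KnowledgeBase) -> dict:
    """Serialize a KB to a JSON-compatible mapping (deterministic ordering)."""
    return {
        "version": kb.version,
        "roles": [
            {
                "role_id": r.role_id,
                "vitamin": r.vitamin,
                "ko_ids": sorted(r.ko_ids),
                "label": r.label,
            }
            for r in kb.roles
        ],
        "variants": [
            {
                "variant_id": v.variant_id,
                "vitamin": v.vitamin,
                "role_ids": list(v.role_ids),
                "indispensable_role_ids": sorted(v.indispensable_role_ids),
                "segment_tag": v.segment_tag,
            }
            for v in kb.variants
        ],
        "cobalamin_utilization": {
            "transporter_roles": {
                k: sorted(v)
                for k, v in sorted(kb.cobalamin_utilization.transporter_roles.items())
            },
            "dependent_enzyme_roles": {
                k: sorted(v)
                for k, v in sorted(
                    kb.cobalamin_utilization.dependent_enzyme_roles.items()
                )
            },
        },
    }


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and validate a KB config file (JSON, or YAML superset).

    Loading is pure: the same file always yields an identical KB.  Raises
    :class:`KnowledgeBaseError` on a missing file, schema violation, or any
    invariant violation (e.g. a variant citing an undefined role).
    """
    path = Path(path)
    if not path.exists():
        raise KnowledgeBaseError(f"KB file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise KnowledgeBaseError(f"KB file {path}: parse error: {exc}") from exc
    if not isinstance(data, Mapping):
        raise KnowledgeBaseError(f"KB file {path}: top level must be a mapping")
    kb = kb_from_dict(data)
    violations = validate_knowledge_base(kb)
    if violations:
        raise KnowledgeBaseError(
            f"KB file {path}: {len(violations)} violation(s): " + "; ".join(violations)
        )
    return kb


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(kb_to_dict(kb), indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )


def default_knowledge_base() -> KnowledgeBase:
    """The bundled curated KB covering all nine vitamins."""
    return load_knowledge_base(_DEFAULT_KB_PATH)
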