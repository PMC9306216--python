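"""Call genome-level vitamin producer capability and cobalamin typology.

Builds three archetypal cobalamin genomes — a complete producer, a genome
missing the five anaerobic-segment genes most Prevotella-affiliated
genomes lack, and one missing the two post-cobyrinate kinases — and shows
how the classifier reports them.  Finally it demonstrates community-level
complementarity: two genomes whose missing genes are disjoint jointly
cover a complete route.
"""

from vitacap import (
    GenomeAnnotation,
    classify_cobalamin,
    complementarity_matrix,
    default_knowledge_base,
    predict_capability,
)

kb = default_knowledge_base()


def cob_genome(gid, missing_roles):
    """All KOs of the anaerobic + post-cobyrinate route, minus some roles."""
    kos = set()
    for v in kb.variants_for("COB"):
        if v.segment_tag in ("anaerobic", "post_cobyrinate"):
            for rid in v.role_ids:
                if rid not in missing_roles:
                    kos |= kb.role(rid).ko_ids
    return GenomeAnnotation(genome_id=gid, ko_set=frozenset(kos))


archetypes = {
    "complete_producer": cob_genome("complete_producer", set()),
    "prevotella_like": cob_genome(
        "prevotella_like", {"cysG", "cbiL", "cbiJ", "cbiT", "cbiE"}
    ),
    "methanobrevibacter_like": cob_genome("methanobrevibacter_like", {"MMAB", "cobP"}),
}

for name, genome in archetypes.items():
    verdict = predict_capability(genome, kb).verdicts["COB"]
    cls = classify_cobalamin(genome, kb)
    missing = verdict.missing_by_variant["COB_anaerobic"] or \
        verdict.missing_by_variant["COB_post_cobyrinate"]
    print(f"{name}: producer={verdict.producer}, class={cls.biosynthesis_class}, "
          f"missing={list(missing) or 'nothing'}")

# complementarity: the two partial genomes miss disjoint role sets, so their
# pooled gene content completes the anaerobic route
classes = [
    classify_cobalamin(archetypes["prevotella_like"], kb),
    classify_cobalamin(
        cob_genome("complement",
                   {"cbiK", "cbiH", "cbiG", "cbiF", "cbiD", "cbiC", "cbiA"}), kb
    ),
]
table, report = complementarity_matrix(classes, kb)
print(f"\npooled cover: covered={report.covered}, "
      f"routes={list(report.satisfied_route_tags)}")
print("Interpretation: neither genome alone synthesizes cobalamin, but their"
      " gene complements are complementary — a cross-feeding candidate pair.")
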