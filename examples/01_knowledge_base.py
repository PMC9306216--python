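"""Explore the bundled vitamin-pathway knowledge base.

Loads the curated KB, validates it, and prints the branch structure of each
vitamin's de novo biosynthesis pathway.  The numbers are role and KO-token
counts: a "role" is one reaction step (possibly several interchangeable
KOs), and a variant's indispensable roles are what a genome must carry to
be called a producer through that route.
"""

from vitacap import default_knowledge_base, ko_universe, validate_knowledge_base

kb = default_knowledge_base()
violations = validate_knowledge_base(kb)
print(f"knowledge base {kb.version}: {len(violations)} violations")
print(f"{len(kb.roles)} roles, {len(kb.variants)} variants, "
      f"{len(ko_universe(kb))} KO tokens\n")

for vitamin in kb.vitamins:
    variants = kb.variants_for(vitamin)
    print(f"{vitamin}: {len(kb.roles_for(vitamin))} roles, "
          f"{len(ko_universe(kb, vitamin))} KOs")
    for v in variants:
        tag = f" [{v.segment_tag}]" if v.segment_tag else ""
        print(f"  {v.variant_id}{tag}: {len(v.indispensable_role_ids)} "
              f"indispensable of {len(v.role_ids)} roles")

print("\nCobalamin is branch-structured: a producer needs one early "
      "corrin-ring segment (anaerobic or aerobic) plus the shared "
      "post-cobyrinate segment.")
print("corrinoid transporters:",
      ", ".join(sorted(kb.cobalamin_utilization.transporter_roles)))
print("cobalamin-dependent enzymes:",
      ", ".join(sorted(kb.cobalamin_utilization.dependent_enzyme_roles)))
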