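"""Parse an axiom file and close it under the saturation rules.

The fixture mirrors a classic motif: two biological processes that are far
apart in their own hierarchy but both linked to the same external chemical
class, plus a genus-differentia definition that saturation decomposes.
"""

import tempfile
from pathlib import Path

from ontoembed import parse_ontology, saturate

AXIOMS = """\
GO:0019556 SubClassOf GO:0006547
GO:0006547 SubClassOf GO:0008152
GO:0043606 SubClassOf GO:0008152
GO:0019556 SubClassOf has_participant some CHEBI:16397
GO:0043606 SubClassOf has_participant some CHEBI:16397
CHEBI:16397 SubClassOf CHEBI:33014
GO:0099999 EquivalentTo GO:0008152 and has_participant some CHEBI:16397
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.axioms"
    path.write_text(AXIOMS)
    onto = parse_ontology(path)

sat = saturate(onto)
inferred = sorted((ax for ax in sat.axioms if ax.origin == "inferred"),
                  key=lambda ax: ax.tokens())

print(f"asserted axioms: {len(onto)}")
print(f"after saturation: {len(sat)} ({len(inferred)} inferred)\n")
for ax in inferred:
    print(" ", ax.serialize())

# The inferred set contains the lifted existential
# `GO:0019556 SubClassOf has_participant some CHEBI:33014` (the chemical's
# parent), the transitive hierarchy edges, and the two conjuncts of the
# genus-differentia definition of GO:0099999 — exactly the completions a
# hierarchy-aware embedding corpus needs.
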