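"""Score CRAC anchor conservation across a synthetic 24-species ortholog panel.

Generates a panel whose anchor sites stay in-class with probability 0.9 while
background sites mutate at rate 0.1, then measures per-anchor conservation —
the fraction of species whose aligned residue still belongs to the anchor's
class.  The recovered fractions sit near the planted fidelity.
"""

from raftcrac import (
    Alignment,
    CRAC_EXTENDED,
    OrthologSetSpec,
    anchor_conservation,
    gen_ortholog_set,
)
from raftcrac.motifs import TM_PRESETS
from raftcrac.pipeline import DEMO_TEMPLATE, DEMO_TEMPLATE_OFFSET

spec = OrthologSetSpec(
    template_sequence=DEMO_TEMPLATE,     # synthetic TM2/TM4-region stand-in
    template_offset=DEMO_TEMPLATE_OFFSET,
    topology=TM_PRESETS["mTRPA1-fig"],
    n_species=24,
    substitution_rate=0.1,
    anchor_fidelity=0.9,
    seed=42,
)
panel = gen_ortholog_set(spec)
aln = Alignment(panel.ids, panel.sequences, panel.reference_id,
                reference_offset=panel.reference_offset)

print(f"panel: {len(panel.ids)} species, {len(panel.matches)} planted motifs")
for ac in anchor_conservation(aln, list(panel.matches), CRAC_EXTENDED):
    a, b, c = ac.match.anchors
    print(f"motif {a}-{b}-{c}: apolar {ac.apolar_fraction:.2f}, "
          f"aromatic {ac.aromatic_fraction:.2f}, basic {ac.basic_fraction:.2f}")

print("\nFractions near 0.9 mean anchors survive in-class in ~90% of species,")
print("matching the planted fidelity; 1.0 would be perfect conservation.")
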