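"""Design a splice-overlap-extension fusion with a junction mutation.

Two template regions are fused into one product while a copy-up point
mutation is planted in the overlap, mirroring how a broad-host-range
replication origin is amplified in two halves and fused with mutagenic
inner primers that are mutual reverse complements.
"""

from bglbrick import DnaSequence, revcomp_str
from bglbrick.primers import design_soe_fusion, simulate_soe
from bglbrick import synthdata
import numpy as np

rng = np.random.default_rng(11)
half_a = DnaSequence(synthdata.random_clean_seq(400, rng))
half_b = DnaSequence(synthdata.random_clean_seq(450, rng))

alt = "T" if half_a.bases[-8] != "T" else "A"
plan = design_soe_fusion(
    [(half_a, (0, 400)), (half_b, (0, 450))],
    junction_mutations={0: (8, alt)},   # 8 bases before the junction
    fwd_tail="GATCACCTAGG",             # adds an AvrII site
    rev_tail="AGATCAACTAGT",            # adds a SpeI site
)

for step in plan.steps:
    print(f"{step.forward.name}: {step.forward.bases[:40]}...")
    print(f"{step.reverse.name}: {step.reverse.bases[:40]}...")
print("inner primers are mutual reverse complements:",
      plan.steps[0].reverse.bases == revcomp_str(plan.steps[1].forward.bases))

product = simulate_soe(plan)
print(f"fusion product: {len(product)} bp "
      f"(= 400 + 450 + tails), mutation carried once")
print("matches sequence-algebra expectation:",
      product.bases == plan.expected_product.bases)
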