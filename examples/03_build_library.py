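"""Generate the full combinatorial pBb vector set and swap a module.

Four origins x eight promoter systems x three markers gives 96 vectors,
each named by the pBb grammar.  Any module can then be exchanged with a
single digest/ligate cycle at its two boundary sites.
"""

from bglbrick import build_library, circular_equal, format_name, swap_module
from bglbrick.library import ar_ori_combinations, synthetic_catalog

catalog = synthetic_catalog()
vectors = {format_name(v.name): v for v in build_library(catalog=catalog)}

print(f"vectors built      : {len(vectors)}")
print(f"AR-ori intermediates: {len(ar_ori_combinations())}")
print("examples           :", ", ".join(sorted(vectors)[:4]), "...")

# swap the PlacUV5 expression module of pBbE5a for the Ptet module (code 2)
swapped = swap_module(vectors["pBbE5a-rfp"], catalog.expressions[2], code=2)
print(f"swap pBbE5a-rfp expression -> promoter 2: {format_name(swapped.name)}")
print("identical to directly built pBbE2a-rfp:",
      circular_equal(swapped.seq, vectors["pBbE2a-rfp"].seq))
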