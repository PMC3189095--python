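"""Compose two BglBrick parts and inspect the junction scar.

Every part is an insert flanked by EcoRI/BglII upstream and BamHI/XhoI
downstream.  Assembly cuts the upstream construct at BamHI/XhoI and the
downstream part at BglII/XhoI; the compatible GATC ends fuse into the
GGATCT scar, and the composite is again a valid part.
"""

from bglbrick import DnaSequence, find_sites, BGLBRICK_ENZYMES
from bglbrick.parts import SCAR, assemble, make_part, validate_part

rbs_orf = make_part(DnaSequence("TTTAAGAAGGAGATATACAT" + "ATGGCTAGCAAAGGTGAA"))
tag = make_part(DnaSequence("ATGCATCACCATCACCATCAC"))

composite = assemble(rbs_orf, tag)
print(f"upstream insert : {len(rbs_orf.insert)} bp")
print(f"downstream insert: {len(tag.insert)} bp")
print(f"composite insert : {len(composite.insert)} bp "
      f"(= {len(rbs_orf.insert)} + 6 + {len(tag.insert)})")
print(f"junction scar    : {SCAR} (Gly-Ser when read in frame)")
print(f"composite valid  : {validate_part(composite.full_sequence).valid}")
print("internal standard sites:",
      find_sites(composite.insert, BGLBRICK_ENZYMES) or "none")
# The length law |A| + 6 + |B| and the clean validation report show that
# the scar is cut by neither BglII nor BamHI, so assembly can iterate.
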