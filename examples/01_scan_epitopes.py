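"""Scan a peptide for celiac-disease DQ2.5 epitopes and assign its Alpha type.

The α-gliadin 33-mer carries six overlapping DQ2.5 epitope copies; the
downstream DQ2.5_glia_α3 motif brings the total to seven, which defines the
Alpha7 archetype (the fully immunogenic family member).
"""

from ampedit import classify_alpha_type, scan_epitopes
from ampedit.epitopes import DQ25_MOTIFS, THIRTY_THREE_MER

profile = scan_epitopes(THIRTY_THREE_MER)
print(f"33-mer peptide: {THIRTY_THREE_MER}")
for name, count in profile.motif_hits.items():
    print(f"  {name}: {count} overlapping cop{'ies' if count != 1 else 'y'}")
print(f"  total DQ2.5 hits: {profile.total_hits}")

full = scan_epitopes(THIRTY_THREE_MER + DQ25_MOTIFS["DQ2.5_glia_a3"])
print(f"33-mer + downstream α3 -> total hits {full.total_hits}, "
      f"Alpha type {classify_alpha_type(full)}")
# The hit counts (1 x α1a, 2 x α1b, 3 x α2, then +1 α3) are what make this
# region the primary excision target: removing one 129-bp fragment deletes
# seven epitope copies at once.
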