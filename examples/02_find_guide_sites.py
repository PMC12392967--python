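"""Locate guide binding sites and cut windows on a reference panel.

Builds a small synthetic α-gliadin-like panel and scans the two default
Cas9 guides against every family member: each reference carries one
upstream (minus-strand) and one downstream (plus-strand) perfect-seed site
flanking the epitope-coding block.
"""

from ampedit import build_reference_panel, default_guides
from ampedit.guides import sites_with_windows

panel = build_reference_panel({0: 1, 5: 1, 7: 1}, seed=42)
guides = default_guides()

for ref in panel:
    print(f"{ref.id} ({len(ref.sequence)} bp, Alpha type {ref.alpha_type}, "
          f"epitope block {ref.epitope_region})")
    for guide in guides:
        for site in sites_with_windows(guide, ref, pad=5):
            w = site.cut_window
            print(
                f"  {guide.name}: strand {site.strand}, protospacer "
                f"[{site.protospacer_start},{site.protospacer_end}), "
                f"cut at {w.expected_cut}, window "
                f"[{w.window_start},{w.window_end})"
            )
# The distance between the two expected cuts is the excision size; for the
# Alpha7 archetype it is 129 bp — an in-frame deletion removing the complete
# 33-mer plus the α3 epitope.
a7 = panel.get("Alpha7.01")
lo, hi = a7.epitope_region
print(f"Alpha7 inter-cut distance: {hi - lo} bp (divisible by 3: {(hi-lo) % 3 == 0})")
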