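"""Design contour lengths of the 6-helix bundle from its segment layout.

A 6-hb monomer is 32 segments of 42 bp; the dimer joins two monomer halves
through a 2/3-segment splint for 64 2/3 segments in total. At 0.34 nm rise
per base pair these give the lengths quoted for the structures.
"""

import origamiqc as oq

monomer = oq.predict_contour_length(n_segments=32, bp_per_segment=42)
dimer = oq.predict_contour_length(n_segments=64 + 2 / 3, bp_per_segment=42)

print(f"monomer: 32 x 42 bp x 0.34 nm = {monomer:.2f} nm "
      f"(quoted: {oq.round_sig(monomer):.0f} nm)")
print(f"dimer: 64 2/3 x 42 bp x 0.34 nm = {dimer:.2f} nm "
      f"(quoted: {oq.round_sig(dimer):.0f} nm)")
print("-> these are the reference lengths the monomer/dimer classifier "
      "is built around (boundary at their midpoint).")
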