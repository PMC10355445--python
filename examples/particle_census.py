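"""Monomer/dimer census of a synthetic AFM field with bootstrap error.

Simulates a field of 6-hb nanotubes, detects and measures each rod,
classifies by contour length (~460 nm monomer vs ~920 nm dimer), and
attaches a half-subset bootstrap standard error to the dimer content.
"""

import origamiqc as oq

spec = oq.SceneSpec(width_px=512, height_px=512, n_monomers=6, n_dimers=2,
                    n_staples=0, seed=5)
hm, truth = oq.generate_afm_scene(spec)
particles, cen = oq.analyze_map(hm, height_threshold_nm=1.0)

print(f"detected {len(particles)} particles "
      f"(truth: {len(truth.particles)} rods)")
for p in particles:
    print(f"  length {p.contour_length_nm:7.1f} nm -> {p.label}")
print(f"census: {cen.n_monomer} monomers, {cen.n_dimer} dimers, "
      f"{cen.n_other} other")

binary = [1] * cen.n_dimer + [0] * cen.n_monomer
boot = oq.half_subset_se(binary, n_resamples=10_000, seed=5)
print(f"dimer content = {100 * boot.point_estimate:.1f}% "
      f"+- {100 * boot.se:.1f}% (half-subset bootstrap SE, "
      f"n={boot.n}, subsets of {boot.subset_size})")
print("-> lengths cluster at the two design lengths; the SE quantifies the "
      "counting uncertainty of the dimer fraction.")
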