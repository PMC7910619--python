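"""Build table layouts and refine them coarse-to-fine.

Every table starts from a small node set in the latent space (so the
first-stage fit is cheap and stable) and is refined to more nodes than
items before the one-to-one assignment.
"""

from ptgen import expand_layout, make_cone, make_cylinder, make_grid

square = make_grid([5, 5])
print(f"square 5x5:     K={square.K}  L={square.L}  spacing 0.5 on [-1,1]^2")
fine = expand_layout(square)
print(f"  refined:      K={fine.K}  ({fine.structure[0]} per side)")

rect = make_grid([5, 18])
print(f"rectangle 5x18: K={rect.K}  (the standard periodic-table template)")

cone = make_cone([1, 4, 8, 12])
cone_fine = expand_layout(cone)
print(f"cone [1,4,8,12]: K={cone.K} -> refined slice counts "
      f"{cone_fine.structure}, K={cone_fine.K}")

cyl = make_cylinder(3, 18)
print(f"cylinder 3x18:  K={cyl.K} nodes on the unit-radius surface")

# Refinement always keeps the original nodes in place, so a model fitted
# on the coarse set can be transferred by GP interpolation.
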