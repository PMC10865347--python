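"""Stationary points and the minimum-energy path of the reference surface.

Builds the 2D free-energy surface calibrated to the phosphoryl-transfer
reaction step (reactant channel, sharp saddle, elongated product basin),
tabulates it on a 0.02 Å grid, and extracts basins, saddle and the
minimax minimum-energy path.
"""

from fespath import (reference_mechanism_surface, fes_from_grid,
                     find_minima, find_saddles, minimum_energy_path)

surface = reference_mechanism_surface()
grid = fes_from_grid(surface, [(1.4, 5.2, 0.02), (0.8, 5.6, 0.02)])

minima = find_minima(grid)
saddle = find_saddles(grid)[0]
reactant = max(minima, key=lambda m: m.free_energy)
product = min(minima, key=lambda m: m.free_energy)
mep = minimum_energy_path(grid, reactant, product)

print(f"reactant minimum  CV = ({reactant.location[0]:.2f}, "
      f"{reactant.location[1]:.2f}) Å   dG_r = {reactant.free_energy:.1f} kcal/mol")
print(f"saddle point      CV = ({saddle.location[0]:.2f}, "
      f"{saddle.location[1]:.2f}) Å   dG_t = {saddle.free_energy:.1f} kcal/mol")
print(f"product minimum   CV = ({product.location[0]:.2f}, "
      f"{product.location[1]:.2f}) Å   dG_p = {product.free_energy:.1f} kcal/mol")
print(f"activation free energy dG_act = {mep.barrier:.1f} kcal/mol")
print(f"reaction free energy   dRG    = {mep.reaction_free_energy:.1f} kcal/mol")
print("dG_act is the MEP maximum above the reactant basin; dRG is the "
      "product-minus-reactant basin difference.")
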