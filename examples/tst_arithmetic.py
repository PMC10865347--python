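"""Transition-state-theory and bias-factor arithmetic.

Converts the experimentally measured dephosphorylation rate into an
activation free energy through the Eyring equation, and relates the
well-tempered bias factor to its tempering energy.
"""

from fespath import (bias_factor_from_energy, energy_from_bias_factor,
                     eyring_barrier, eyring_rate, celsius_to_kelvin)

temperature = celsius_to_kelvin(3.5)   # the kinetics were measured cold
rate = 270.0                           # 1/s
dg = eyring_barrier(rate, temperature)
print(f"k = {rate:g} 1/s at {temperature:.2f} K  ->  "
      f"dG_act = {dg:.1f} kcal/mol (Eyring)")
print(f"back-conversion: dG_act = {dg:.1f} kcal/mol  ->  "
      f"k = {eyring_rate(dg, temperature):.0f} 1/s")

gamma = bias_factor_from_energy(20.0, 298.0)
print(f"tempering energy 20 kcal/mol at 298 K  ->  bias factor {gamma:.2f}")
print(f"bias factor {gamma:.2f}  ->  "
      f"{energy_from_bias_factor(gamma, 298.0):.1f} kcal/mol")
print("the bias factor caps how much bias well-tempered metadynamics "
      "deposits; 20 kcal/mol comfortably covers the reaction barrier.")
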