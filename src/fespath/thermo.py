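"""Transition-state-theory and well-tempered-metadynamics arithmetic.

The Eyring equation links a unimolecular rate constant ``k`` to an
activation free energy through the thermal prefactor ``kB*T/h``:

    k = (kB*T/h) * exp(-dG_act / (kB*T))

with the transmission coefficient fixed at 1.  The bias factor of
well-tempered metadynamics relates to a tempering energy ``E`` (the
amount of bias the scheme is allowed to accumulate) via

    gamma = 1 + E / (kB*T)

All energies are kcal mol⁻¹, temperatures Kelvin, rates s⁻¹.
"""

import math

from .constants import KB, KB_MOLECULAR, H_MOLECULAR, celsius_to_kelvin

__all__ = [
    "bias_factor_from_energy",
    "energy_from_bias_factor",
    "eyring_barrier",
    "eyring_rate",
    "celsius_to_kelvin",
]


def bias_factor_from_energy(energy: float, temperature: float) -> float:
    """Bias factor γ = 1 + E/(kB·T) for a tempering energy E (kcal/mol)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if energy < 0:
        raise ValueError(f"tempering energy must be non-negative, got {energy}")
    return 1.0 + energy / (KB * temperature)


def energy_from_bias_factor(bias_factor: float, temperature: float) -> float:
    """Tempering energy E = (γ−1)·kB·T; inverse of :func:`bias_factor_from_energy`."""
    if bias_factor < 1:
        raise ValueError(f"bias factor must be >= 1, got {bias_factor}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return (bias_factor - 1.0) * KB * temperature


def eyring_barrier(rate: float, temperature: float) -> float:
    """Activation free energy (kcal/mol) from a rate constant (s⁻¹).

    ΔG‡ = −kB·T·ln(k·h/(kB·T)) with h and kB taken per molecule, so the
    argument of the logarithm is dimensionless.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    prefactor = KB_MOLECULAR * temperature / H_MOLECULAR
    return -KB * temperature * math.log(rate / prefactor)


def eyring_rate(barrier: float, temperature: float) -> float:
    """Rate constant (s⁻¹) from an activation free energy (kcal/mol)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    prefactor = KB_MOLECULAR * temperature / H_MOLECULAR
    return prefactor * math.exp(-barrier / (KB * temperature))
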