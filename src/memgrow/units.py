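"""Unit conversions between absolute copy numbers and concentrations.

Omics measurements of mRNA and protein abundance typically arrive as
molecules per cell (mpc), while reaction-network models operate on
concentrations.  The bridge is the volume of the compartment the species
lives in: ``nM = mpc * 1e9 / (N_A * V)`` with ``V`` in liters.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol, exact (2019 SI)

SECONDS_PER_HOUR = 3600.0


def mpc_to_nm(count: float, volume_l: float) -> float:
    """Convert molecules per cell to nanomolar for a compartment volume in liters."""
    if volume_l <= 0:
        raise ValueError(f"compartment volume must be positive, got {volume_l}")
    return count * 1e9 / (AVOGADRO * volume_l)


def nm_to_mpc(conc_nm: float, volume_l: float) -> float:
    """Convert a nanomolar concentration back to molecules per cell."""
    if volume_l <= 0:
        raise ValueError(f"compartment volume must be positive, got {volume_l}")
    return conc_nm * AVOGADRO * volume_l / 1e9


def per_hour_to_per_second(rate_per_h: float) -> float:
    return rate_per_h / SECONDS_PER_HOUR


def hours_to_seconds(t_h: float) -> float:
    return t_h * SECONDS_PER_HOUR
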