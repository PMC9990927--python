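"""Unit conversions for the internal mm / s / Pa / mm^3 system.

All physical quantities inside the package live in a single coherent unit
system: lengths in mm, times in s, pressures in Pa, volumes in mm^3 (hence
flows in mm^3/s and velocities in mm/s).  Literature values arrive in mmHg,
uL/min, mL/min or mL/100g/min and are converted at the boundary of the
parameter module; report-level quantities are converted back to the units the
physiology literature prints (um/s, uL/min).
"""

from __future__ import annotations

import math

#: 1 mmHg in Pa (CODATA-consistent).
PA_PER_MMHG: float = 133.322


def mmhg_to_pa(p: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    if not math.isfinite(p):
        raise ValueError(f"pressure must be finite, got {p!r}")
    return p * PA_PER_MMHG


def pa_to_mmhg(p: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    if not math.isfinite(p):
        raise ValueError(f"pressure must be finite, got {p!r}")
    return p / PA_PER_MMHG


def ul_per_min_to_mm3_per_s(q: float) -> float:
    """Convert a flow from uL/min to mm^3/s (1 uL = 1 mm^3)."""
    return q / 60.0


def mm3_per_s_to_ul_per_min(q: float) -> float:
    """Convert a flow from mm^3/s to uL/min."""
    return q * 60.0


def ml_per_min_to_mm3_per_s(q: float) -> float:
    """Convert a flow from mL/min to mm^3/s (1 mL = 1000 mm^3)."""
    return q * 1000.0 / 60.0


def perfusion_to_mm3_per_s(rate_ml_per_100g_min: float, brain_mass_g: float) -> float:
    """Convert a perfusion rate in mL/100g/min to a total flow in mm^3/s.

    A cerebral blood flow of 116 mL/100g/min for a 2 g rat brain gives
    2.32 mL/min = 38.67 mm^3/s.
    """
    return ml_per_min_to_mm3_per_s(rate_ml_per_100g_min * brain_mass_g / 100.0)


def mm_per_s_to_um_per_s(u: float) -> float:
    """Convert a velocity from mm/s to um/s."""
    return u * 1000.0
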