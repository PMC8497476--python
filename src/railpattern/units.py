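"""Unit conventions and exact conversion helpers.

All core modules work in SI units: metres for lengths, N/m for surface
tension, Pa for pressures, Pa·s for viscosity.  Device config files and
the factory functions in :mod:`railpattern.synthetic` use the units the
field prints on device drawings — micrometres and mN/m — and convert at
the boundary.  Conversion factors are exact powers of ten, so round
trips incur no error beyond binary floating-point representation.
"""

M_PER_UM = 1e-6
UM_PER_M = 1e6

NM_PER_MNM = 1e-3  # N/m per mN/m
MNM_PER_NM = 1e3

PAS_PER_MPAS = 1e-3  # Pa·s per mPa·s


def um_to_m(value_um: float) -> float:
    return value_um * M_PER_UM


def m_to_um(value_m: float) -> float:
    return value_m * UM_PER_M


def mn_per_m_to_n_per_m(value_mnm: float) -> float:
    return value_mnm * NM_PER_MNM


def n_per_m_to_mn_per_m(value_nm: float) -> float:
    return value_nm * MNM_PER_NM
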