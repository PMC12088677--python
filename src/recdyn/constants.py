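"""Physical constants and default acquisition designs.

Defaults reflect standard backbone-amide ¹⁵N relaxation practice: an N-H
bond length of 1.02 Å and an axially symmetric ¹⁵N CSA tensor of −160 ppm.
Both are overridable through :class:`PhysicalConstants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹
GAMMA_H = 2.6752218744e8
#: ¹⁵N gyromagnetic ratio, rad s⁻¹ T⁻¹ (negative)
GAMMA_N = -2.7126e7
#: reduced Planck constant, J s
HBAR = 1.054571817e-34
#: vacuum permeability, T² m³ J⁻¹
MU_0 = 4.0e-7 * math.pi
#: gas constant in kcal mol⁻¹ K⁻¹ (van't Hoff fits)
R_GAS_KCAL = 1.987e-3
#: 0 °C in kelvin
T_KELVIN_0C = 273.15

#: |γN/γH|: ratio of the ¹⁵N to ¹H Larmor frequencies
N15_FREQ_RATIO = abs(GAMMA_N) / GAMMA_H

#: constant-time CPMG relaxation period, s
T_RELAX_CPMG = 0.020
#: reference static field (¹H MHz) at which φ is parameterised
REF_FIELD_MHZ = 600.0
#: static fields used for dual-field relaxation work, ¹H MHz
DEFAULT_FIELDS_MHZ = (600.0, 850.0)

#: CPMG refocusing frequencies, Hz; 0 is the reference plane.
NU_CPMG_HZ = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 250.0, 500.0, 750.0,
              800.0, 900.0, 1000.0)
#: νCPMG values recorded in duplicate for uncertainty estimation
NU_CPMG_DUPLICATES_HZ = (50.0, 500.0, 800.0)

#: T1 inversion-recovery delays, s (duplicates at 20, 60, 600 ms)
T1_DELAYS_S = (0.0, 0.020, 0.060, 0.100, 0.200, 0.600, 0.800, 1.200)
T1_DUPLICATES_S = (0.020, 0.060, 0.600)
#: T2 (CPMG-train) delays, s (duplicates at 33.9, 50.9, 67.8, 101.8 ms)
T2_DELAYS_S = (0.0, 0.0169, 0.0339, 0.0509, 0.0678, 0.0848, 0.1018)
T2_DUPLICATES_S = (0.0339, 0.0509, 0.0678, 0.1018)

#: CD melt temperature grid, °C
MELT_T_MIN_C = 20.0
MELT_T_MAX_C = 90.0
MELT_T_STEP_C = 1.0

#: MST isotherm design: 16-point two-fold serial dilution from 200 µM,
#: fluorescently labelled target fixed at 20 nM.
MST_N_POINTS = 16
MST_TOP_CONC_UM = 200.0
MST_TARGET_CONC_NM = 20.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Spin-pair constants entering the ¹⁵N dipolar/CSA rate expressions."""

    r_nh_m: float = 1.02e-10          # N-H bond length, m
    csa_ppm: float = -160.0           # ¹⁵N CSA, ppm
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    @property
    def dipolar_coupling(self) -> float:
        """Dipolar coupling constant d = (µ0/4π)·ħ·γH·γN / r³, rad s⁻¹."""
        return (MU_0 / (4.0 * math.pi) * HBAR * self.gamma_h * self.gamma_n
                / self.r_nh_m**3)

    def larmor_rad_s(self, field_mhz: float) -> tuple[float, float]:
        """(ωH, ωN) magnitudes in rad/s at a ¹H field given in MHz."""
        omega_h = 2.0 * math.pi * field_mhz * 1e6
        return omega_h, omega_h * N15_FREQ_RATIO

    def csa_coupling(self, field_mhz: float) -> float:
        """CSA interaction constant c = ωN·Δσ/√3 in rad s⁻¹ (magnitude)."""
        _, omega_n = self.larmor_rad_s(field_mhz)
        return omega_n * abs(self.csa_ppm) * 1e-6 / math.sqrt(3.0)


def dw_ppm_to_rad_s(dw_ppm: float, field_mhz: float) -> float:
    """Convert a ¹⁵N shift difference in ppm to rad/s at a ¹H field in MHz."""
    nu_n_hz = field_mhz * 1e6 * N15_FREQ_RATIO
    return 2.0 * math.pi * nu_n_hz * dw_ppm * 1e-6
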