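"""Default excitonic parameters for the three LH2 complexes.

Site energies and the two largest B850 couplings (with their per-frame
standard deviations) for the high-light (HL) and low-light (LL) forms of
*Rps. acidophila* LH2 and the homology-modelled PucD complex of
*Rps. palustris*.  Values are MD/QM-derived averages over 50 frames, in
cm^-1.  ``V1`` couples the beta-BChl of one alpha/beta unit to the
alpha-BChl of the next unit (inter-chain); ``V2`` couples the two BChls of
the same unit (intra-chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

ROLES = ("alpha", "beta", "b800")

#: Wavenumber added to every CT diabatic energy so that the CT functional's
#: LE energies line up with the reference functional used for site energies.
CT_ALIGNMENT_SHIFT = -1008.0

#: Rigid shift applied to simulated spectra to match the experimental B800
#: band (typical systematic error of the underlying excited-state method).
GLOBAL_SPECTRUM_SHIFT = -1247.0

#: Lorentzian half-widths at half maximum (cm^-1) used for the simulated
#: lineshapes: per-complex low-energy (B850/B820) band width and the common
#: high-energy (B800) band width.
HWHM_LOW_BAND = {"HL": 150.0, "LL": 280.0, "PucD": 280.0}
HWHM_HIGH_BAND = 180.0

#: Extra blue-shift (cm^-1) of the Q_y site energies accounting for the
#: out-of-plane acetyl torsion missed by the classical trajectories.
ACETYL_CORRECTIONS = {"alpha": 220.0, "beta": 120.0}


@dataclass(frozen=True)
class ComplexParameters:
    """Mean excitonic parameters of one LH2 complex (cm^-1)."""

    name: str
    site_energies: Mapping[str, float]      # role -> mean site energy
    site_energy_sd: Mapping[str, float]     # role -> per-frame SD
    v1_inter: float                         # |V1_ab|, inter-chain
    v2_intra: float                         # |V2_ab|, intra-chain
    v1_sd: float
    v2_sd: float


COMPLEX_PARAMS: dict[str, ComplexParameters] = {
    "HL": ComplexParameters(
        name="HL",
        site_energies={"alpha": 13527.0, "beta": 13556.0, "b800": 13783.0},
        site_energy_sd={"alpha": 276.0, "beta": 279.0, "b800": 326.0},
        v1_inter=266.0, v2_intra=298.0, v1_sd=55.0, v2_sd=35.0,
    ),
    "LL": ComplexParameters(
        name="LL",
        site_energies={"alpha": 13639.0, "beta": 13693.0, "b800": 13735.0},
        site_energy_sd={"alpha": 290.0, "beta": 297.0, "b800": 312.0},
        v1_inter=149.0, v2_intra=281.0, v1_sd=89.0, v2_sd=37.0,
    ),
    "PucD": ComplexParameters(
        name="PucD",
        site_energies={"alpha": 13790.0, "beta": 13715.0, "b800": 13767.0},
        site_energy_sd={"alpha": 266.0, "beta": 286.0, "b800": 328.0},
        v1_inter=127.0, v2_intra=285.0, v1_sd=74.0, v2_sd=35.0,
    ),
}
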