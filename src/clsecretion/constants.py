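"""Physical constants and default tissue-scale values.

Constants are CODATA values.  The defaults describe the renal A6-cell
monolayer preparation the model was calibrated against: a confluent
epithelium on a 0.33 cm^2 permeable support with a total cell volume of
about 5e-10 m^3, bathed on both sides in an amphibian Ringer whose total
Cl- content is 127.5 mM (120 NaCl + 3.5 KCl + 1 CaCl2 + 1 MgCl2).
"""

from dataclasses import dataclass

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
Z_CL = -1

#: Default absolute temperature (K).  Chosen inside the 24-25 degC
#: amphibian-physiological band so that exp(F*V/RT) evaluates to 0.2104
#: at V = -40 mV and 0.0654 at -70 mV (to ~4 decimals).
DEFAULT_TEMPERATURE = 297.8

#: Bath Cl- concentration on both sides under short circuit (mM = mol/m^3).
DEFAULT_CL_OUT = 127.5

#: Tissue area of the permeable support (cm^2).
DEFAULT_AREA_CM2 = 0.33

#: Total secreting cell volume over that area (m^3).
DEFAULT_CELL_VOLUME = 5.0e-10

#: Baseline apical Cl- conductance (S, whole tissue), measured value.
DEFAULT_G_A0 = 12.87e-6

#: Baseline membrane potential under short circuit (V).
DEFAULT_V0 = -40e-3

#: Baseline apical Cl- current magnitude (uA/cm^2, secretion positive).
DEFAULT_I_A0_UA_PER_CM2 = 0.08


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday and gas constants plus the Cl- valence.

    Exists mainly so alternative unit systems can be injected in tests;
    production code uses the module-level CODATA values.
    """

    faraday: float = FARADAY
    gas: float = GAS_CONSTANT
    z_cl: int = Z_CL

    def __post_init__(self) -> None:
        if self.z_cl != -1:
            raise ValueError("z_cl must be -1 for chloride")
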