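"""Physical constants, van der Waals radii and atomic masses."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the Boltzmann activation model.

    F in C/mol, R in J/(mol K), T in K.  The default temperature is
    room temperature; it is configurable because the steepness term
    zdelta*F/(R*T) scales inversely with T.
    """

    F: float = 96485.0
    R: float = 8.314
    T: float = 295.0

    @property
    def kT_over_e_mV(self) -> float:
        """R*T/F expressed in mV."""
        return self.R * self.T / self.F * 1000.0


#: van der Waals radii (Å) of the apolar atoms entering hydrophobic tethers.
VDW_RADII = {"C": 1.70, "S": 1.80}

#: Distance offset (Å) added to the sum of vdW radii for tether detection.
HYDROPHOBIC_DCUT = 0.25

#: Heavy-atom distance (Å) defining a residue-residue contact.
CONTACT_CUTOFF = 4.5

#: Atomic masses (u) for mass-weighted centers of mass.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.011)
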