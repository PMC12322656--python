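"""Domain types and unit conversions shared by all stages.

Canonical internal units
------------------------
concentrations  mM
time            min
rates           mM/min
kcat            s⁻¹ (converted with the factor 60 at the rate-law boundary)

An enzyme activity unit (U) is 1 µmol/min of product released or substrate
consumed; specific activity is U per mg of protein.  Enzyme molarities are
per subunit: kinetic constants are expressed per catalytic subunit, so the
oligomeric state (the wild-type nucleosidase is a tetramer, the RY variant a
monomer) does not enter the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "EnzymeSpec",
    "ExtinctionCoefficient",
    "ActivityUnit",
    "subunit_molarity",
    "specific_activity_to_kcat",
    "kcat_to_specific_activity",
    "absorbance_to_conc",
]

#: seconds per minute — the kcat (s⁻¹) ↔ rate (mM/min) boundary factor
S_PER_MIN = 60.0


@dataclass(frozen=True)
class EnzymeSpec:
    """One catalyst: identity, subunit molar mass and mass concentration.

    Parameters
    ----------
    name:
        Free-text identifier, e.g. ``"RY"``.
    subunit_molar_mass:
        Molar mass of one catalytic subunit in g/mol.
    mass_conc:
        Protein mass concentration in g/L (≡ mg/mL).
    epsilon_280:
        Optional molar extinction coefficient at 280 nm in 1/(M·cm), used
        for protein quantification.
    """

    name: str
    subunit_molar_mass: float
    mass_conc: float = 0.0
    epsilon_280: float | None = None

    def __post_init__(self) -> None:
        if self.subunit_molar_mass <= 0:
            raise InvalidInputError(
                f"subunit molar mass must be positive, got {self.subunit_molar_mass}"
            )
        if self.mass_conc < 0:
            raise InvalidInputError(f"mass_conc must be >= 0, got {self.mass_conc}")

    def with_mass_conc(self, mass_conc: float) -> "EnzymeSpec":
        """Return a copy at a different loading (g/L)."""
        return EnzymeSpec(self.name, self.subunit_molar_mass, mass_conc, self.epsilon_280)


@dataclass(frozen=True)
class ExtinctionCoefficient:
    """Molar extinction coefficient, ε in 1/(mM·cm) at a given wavelength."""

    wavelength_nm: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise InvalidInputError(f"epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class ActivityUnit:
    """Specific activity in U/mg (1 U = 1 µmol/min)."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidInputError(f"specific activity must be >= 0, got {self.value}")


def subunit_molarity(enzyme: EnzymeSpec) -> float:
    """Molar subunit concentration of an enzyme preparation, in mM.

    mass_conc [g/L] / subunit_molar_mass [g/mol] gives mol/L; the factor
    1000 converts to mM.  Linear in ``mass_conc``.
    """
    return enzyme.mass_conc / enzyme.subunit_molar_mass * 1000.0


def specific_activity_to_kcat(
    sa: ActivityUnit | float,
    enzyme: EnzymeSpec,
    substrate_conc: float,
    km: float = 0.0,
) -> float:
    """Convert a specific activity measured at finite substrate to kcat (s⁻¹).

    The observed per-subunit turnover is ``sa · M / 60000`` (U/mg × g/mol →
    s⁻¹); the Michaelis correction ``(Km + S)/S`` extrapolates it to
    saturation.  With ``km=0`` (or S ≫ Km) the observed turnover is returned
    unchanged.

    Parameters
    ----------
    sa:
        Specific activity, U/mg.
    substrate_conc:
        Assay substrate concentration S in mM; must be positive when a
        Michaelis correction is requested.
    km:
        Michaelis constant in mM (0 ⇒ assume saturation).
    """
    value = sa.value if isinstance(sa, ActivityUnit) else float(sa)
    if value < 0:
        raise InvalidInputError("specific activity must be >= 0")
    if km < 0:
        raise InvalidInputError("Km must be >= 0")
    if substrate_conc <= 0:
        if km > 0:
            raise InvalidInputError("substrate_conc must be > 0 when Km > 0")
        raise InvalidInputError("substrate_conc must be > 0")
    kcat_observed = value * enzyme.subunit_molar_mass / (S_PER_MIN * 1000.0)
    return kcat_observed * (km + substrate_conc) / substrate_conc


def kcat_to_specific_activity(
    kcat: float,
    enzyme: EnzymeSpec,
    substrate_conc: float,
    km: float = 0.0,
) -> ActivityUnit:
    """Inverse of :func:`specific_activity_to_kcat`; round-trips for any S > 0."""
    if kcat < 0:
        raise InvalidInputError("kcat must be >= 0")
    if substrate_conc <= 0:
        raise InvalidInputError("substrate_conc must be > 0")
    kcat_observed = kcat * substrate_conc / (km + substrate_conc)
    sa = kcat_observed * S_PER_MIN * 1000.0 / enzyme.subunit_molar_mass
    return ActivityUnit(sa)


def absorbance_to_conc(
    absorbance: float,
    eps: ExtinctionCoefficient,
    path_cm: float = 1.0,
    dilution: float = 1.0,
) -> float:
    """Beer–Lambert concentration (mM) from an absorbance reading.

    ``c = A · dilution / (ε · path)`` with ε in 1/(mM·cm).
    """
    if absorbance < 0:
        raise InvalidInputError(f"absorbance must be >= 0, got {absorbance}")
    if path_cm <= 0:
        raise InvalidInputError("path length must be positive")
    if dilution <= 0:
        raise InvalidInputError("dilution factor must be positive")
    return absorbance * dilution / (eps.epsilon * path_cm)
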