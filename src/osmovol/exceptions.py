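"""Exception hierarchy for osmovol."""


class OsmovolError(Exception):
    """Base class for all osmovol errors."""


class InsufficientDataError(OsmovolError):
    """Too few points / cells / pairs to carry out the requested fit."""


class NoPlateauError(OsmovolError):
    """The equilibrium-detection criterion was never met."""


class InconsistentPairError(OsmovolError):
    """A volume pair straddles the equilibrium volume or is mis-ordered."""


class NearEquilibriumError(OsmovolError):
    """A volume lies inside the guard band around Ve where the log term blows up."""


class GridAlignmentError(OsmovolError):
    """Per-cell time grids disagree beyond tolerance and cannot be averaged."""


class InfeasibleShiftError(OsmovolError):
    """Shift bounds exclude every candidate overlay of simulation on data."""


class SchemaError(OsmovolError):
    """An input table fails schema validation."""
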