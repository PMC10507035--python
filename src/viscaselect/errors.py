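"""Exception hierarchy for viscaselect."""


class ViscaError(Exception):
    """Base class for all viscaselect errors."""


class FormatError(ViscaError):
    """A structure or spectrum file could not be parsed."""


class ConfigurationError(ViscaError):
    """Invalid configuration, parameters or unsupported option."""


class TopologyError(ViscaError):
    """Topology/coordinate mismatch or missing atoms."""


class GeometryError(ViscaError):
    """Physically impossible geometry (clashing chromophores etc.)."""


class GridMismatchError(ViscaError):
    """Operands do not share a common wavenumber grid."""
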