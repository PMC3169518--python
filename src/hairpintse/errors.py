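"""Exception hierarchy for the hairpin TSE analysis pipeline."""


class HairpinError(Exception):
    """Base class for all package errors."""


class FormatError(HairpinError):
    """Malformed input file (e.g. inconsistent atom counts between PDB models)."""


class EmptyInputError(HairpinError):
    """Input contains no usable data (e.g. fewer than two trajectory frames)."""


class ParseError(HairpinError):
    """Malformed tabular row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


class StructureError(HairpinError):
    """A required atom or residue is missing from a frame."""


class DegenerateGeometryError(HairpinError):
    """Geometry makes an order parameter undefined (zero distance, collinear set)."""


class ConfigurationError(HairpinError):
    """Invalid analysis configuration (empty contact list, M < 2 subsets, ...)."""


class DegenerateAxisError(HairpinError):
    """A landscape axis has zero width (all pooled frames identical)."""


class AssignmentError(HairpinError):
    """A frame falls outside the landscape axis ranges."""


class SingleBasinError(HairpinError):
    """No second free-energy basin: the system is not two-state in these coordinates."""


class UndefinedOverlapError(HairpinError):
    """TSE overlap is undefined because the reference TSE is empty."""


class InsufficientEventsError(HairpinError):
    """Too few TS excursions to fit a lifetime distribution."""


class FitError(HairpinError):
    """Residence-time histogram is degenerate (single occupied bin)."""


class EmptyEnsembleError(HairpinError):
    """A structural ensemble selector matched no frames."""


class ResolutionError(HairpinError):
    """Frame interval too coarse to resolve the configured basin kinetics."""


class ConstructionError(HairpinError):
    """Synthetic template geometry targets are mutually infeasible in 3D."""
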