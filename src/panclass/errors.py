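"""Exception types shared across the toolkit."""


class PanclassError(Exception):
    """Base class for all toolkit errors."""


class VcfParseError(PanclassError):
    """A VCF record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class EmptyPanelError(PanclassError):
    """The VCF declares no genotyped samples."""


class UndefinedFrequencyError(PanclassError):
    """Allele frequency requested for a marker with no non-missing calls."""


class InsufficientDataError(PanclassError):
    """Too few pairwise-complete observations for the statistic."""


class RankError(PanclassError):
    """Design matrix is degenerate (constant or n <= parameters)."""


class LookupError_(PanclassError):
    """Unknown marker id or chromosome."""


class CoordinateError(PanclassError):
    """A feature lies outside its chromosome bounds."""


class CapacityError(PanclassError):
    """Synthetic genome cannot pack the requested gene count."""


class PlanningError(PanclassError):
    """A planted mutation could not be placed (e.g. no synonymous site)."""


class ScalingError(PanclassError):
    """Phenotype noise scaling impossible (zero genetic variance)."""
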