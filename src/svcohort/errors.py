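"""Exception types shared across svcohort modules."""


class SvcohortError(Exception):
    """Base class for all svcohort errors."""


class ConfigurationError(SvcohortError):
    """Invalid or inconsistent configuration (bad thresholds, empty whitelist...)."""


class PedigreeError(SvcohortError):
    """Structurally invalid pedigree (unknown parent, cycle, ordering)."""


class CapacityError(SvcohortError):
    """A request exceeds what the inputs can supply (loci, chromosome space)."""


class VcfParseError(SvcohortError):
    """A VCF record could not be interpreted under the expected conventions."""


class EmptyResultError(SvcohortError):
    """An operation retained zero items; carries diagnostic counts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateInputError(SvcohortError):
    """Input is technically parseable but numerically unusable (e.g. zero depth)."""


class UndefinedConcordanceError(SvcohortError):
    """Genotype concordance requested with no comparable samples."""


class UnsupportedInputError(SvcohortError):
    """Input falls outside the supported problem class (e.g. gene with <2 introns)."""
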