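"""Exception hierarchy shared across the pipeline."""


class NPCohortError(Exception):
    """Base class for all package errors."""


class InputDomainError(NPCohortError, ValueError):
    """A value lies outside its scientific domain (e.g. negative nutrient)."""


class ConfigurationError(NPCohortError, ValueError):
    """Invalid configuration: non-monotone cut-point table, unknown enum label."""


class ValidationError(NPCohortError, ValueError):
    """Structural problem in an input table (duplicates, unresolvable keys)."""


class UndefinedExposureError(NPCohortError, ValueError):
    """An exposure measure is undefined for a participant (e.g. zero
    non-alcoholic energy for the energy-weighted mean score)."""


class ConvergenceError(NPCohortError, RuntimeError):
    """Model fitting failed to converge; carries the fitter's diagnostics."""
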