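"""Exception hierarchy used across the package."""


class VarcalibError(Exception):
    """Base class for all package errors."""


class ValidationError(VarcalibError, ValueError):
    """An input value violates a documented precondition or invariant."""


class ClassificationError(VarcalibError, ValueError):
    """A consequence term cannot be mapped to a coding consequence class."""


class GenerationError(VarcalibError, RuntimeError):
    """A synthetic-cohort configuration is infeasible at generation time."""


class ComputationError(VarcalibError, ValueError):
    """A statistic cannot be computed from the given data (e.g. single-class input)."""


class PipelineError(VarcalibError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
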