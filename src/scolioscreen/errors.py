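"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` subclasses exit with
code 2 (malformed input), :class:`PipelineError` subclasses with code 1
(valid input the method cannot measure, e.g. no bimodal contour).
"""


class ScolioscreenError(Exception):
    """Base class for all package errors."""


class InputError(ScolioscreenError):
    """Malformed or contract-violating input (CLI exit code 2)."""


class SchemaError(InputError):
    """Keypoint file violates the documented schema."""


class DomainError(InputError):
    """Numeric argument outside its documented domain."""


class ConfigError(InputError):
    """Invalid configuration value."""


class SingularFitError(InputError):
    """Polynomial fit system is singular (duplicate abscissae)."""


class InconsistentInputError(InputError):
    """Mutually inconsistent intermediate results (e.g. C label with 2 apexes)."""


class DegenerateTriangleError(InputError):
    """Scapular-triangle vertices are collinear."""


class UndefinedMetricError(InputError):
    """A metric is undefined for the given input (e.g. OKS with no visible point)."""


class PipelineError(ScolioscreenError):
    """Measurement failure on otherwise valid input (CLI exit code 1)."""


class EmptyProfileError(PipelineError):
    """Mask or edge map contains no foreground to profile."""


class BimodalPeakError(PipelineError):
    """Fewer than two admissible scapular peaks; the photo is unusable."""
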