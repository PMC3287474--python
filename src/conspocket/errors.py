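"""Exception hierarchy for the pocket-prediction pipeline."""


class ConspocketError(Exception):
    """Base class for all package errors."""


class InputError(ConspocketError):
    """Missing or unreadable input file."""


class FormatError(ConspocketError):
    """Unparseable or internally inconsistent input content."""


class EmptyStructureError(FormatError):
    """A structure file with no usable ATOM records."""


class ParameterError(ConspocketError, ValueError):
    """An out-of-range or nonsensical parameter value."""


class ConfigError(ConspocketError):
    """An unknown configuration name (e.g. radius set, ranking method)."""


class GeometryError(ConspocketError):
    """Degenerate geometry (too few points, coplanar input, ...)."""


class EvaluationError(ConspocketError):
    """Benchmark evaluation cannot proceed (no ligand, all skipped, ...)."""


class FixtureSpecError(ConspocketError):
    """Infeasible synthetic-fixture geometry."""
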