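"""Exception hierarchy.

Three broad families map onto the CLI's nonzero exit codes: configuration
problems (exit 2), malformed or inconsistent input data (exit 3), and
computation failures (exit 4).
"""


class PPIScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(PPIScreenError):
    """Invalid configuration, option grid, or split fractions."""


class DataError(PPIScreenError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """A structure or confidence file could not be parsed."""


class StructuralError(DataError):
    """A structure violates a structural precondition (e.g. <2 chains)."""


class PairingError(DataError):
    """Confidence data does not pair with its structure (dimension mismatch)."""


class DialectError(DataError):
    """Confidence JSON lacks a required key."""


class ValidationError(DataError):
    """A value violates a type invariant (range, shape)."""


class EntitySpecError(DataError):
    """An entity grouping does not cover the model's chains or is degenerate."""


class RecordError(DataError):
    """A sequence record is empty or contains non-amino-acid characters."""


class ComputationError(PPIScreenError):
    """A numeric procedure could not produce a result."""


class GeometryError(ComputationError):
    """Missing or degenerate coordinates."""


class SuperpositionError(ComputationError):
    """Rigid superposition impossible (too few or collinear points)."""


class QualityError(ComputationError):
    """Docking-quality score undefined (e.g. native without contacts)."""


class LengthError(ComputationError):
    """Chain too short for the requested statistic."""


class AnalogError(ComputationError):
    """No admissible structural analog exists in the library."""


class GenerationError(ComputationError):
    """Synthetic-structure placement failed after bounded retries."""


class UndefinedStatisticError(ComputationError):
    """A statistic is undefined on the given input (e.g. empty value set)."""


class MetricError(ComputationError):
    """An evaluation metric is undefined (e.g. single-class labels)."""


class GroupingError(DataError):
    """Rows passed to a per-complex operation span multiple complexes."""


class StratificationError(ComputationError):
    """Cross-validation folds cannot be stratified (single-class fold)."""
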