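"""Structured exception hierarchy.

Every failure mode named in a module contract maps onto one of these
classes so callers (and the CLI) can categorize errors without string
matching.
"""


class AttnprobeError(Exception):
    """Base class for all package errors."""


class ParseError(AttnprobeError):
    """Malformed input text (dot-bracket, CT, FASTA...)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class ShapeError(AttnprobeError):
    """Array with the wrong shape (non-square map, channel mismatch...)."""


class AlignmentError(AttnprobeError):
    """Objects that must be aligned by molecule id / length disagree."""


class RangeError(AttnprobeError):
    """An index is outside the valid range for the molecule."""


class DegenerateInputError(AttnprobeError):
    """Input is structurally valid but numerically degenerate (e.g. all-zero map fed to APC)."""


class StateError(AttnprobeError):
    """Operation called on an object in the wrong state (e.g. unprocessed stack)."""


class ConfigError(AttnprobeError):
    """Invalid configuration value or unknown option."""


class BalanceError(AttnprobeError):
    """Dataset cannot be class-balanced (single class present)."""


class SplitError(AttnprobeError):
    """Molecule split cannot be constructed."""


class TrainingError(AttnprobeError):
    """Classifier training failed (empty dataset, bad state)."""


class FeatureError(AttnprobeError):
    """Feature layout mismatch between a model and an attention stack."""


class GenerationError(AttnprobeError):
    """Synthetic-data generation could not satisfy its constraints."""


class ValidationError(AttnprobeError):
    """A loaded artifact violates its type invariants."""


class LoadError(AttnprobeError):
    """A persisted artifact could not be read back (corruption, version skew)."""


class MissingCoordinateError(AttnprobeError):
    """A residue needed for a distance computation has no usable atoms."""

    def __init__(self, residue_index: int, message: str | None = None):
        self.residue_index = residue_index
        super().__init__(
            message or f"residue {residue_index} has no usable atom coordinates"
        )
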