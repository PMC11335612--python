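"""Exception hierarchy and CLI exit codes."""

from __future__ import annotations


class PsnstratError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PsnstratError):
    """Invalid or missing configuration."""

    exit_code = 2


class InputError(PsnstratError):
    """Missing or unreadable input file."""

    exit_code = 3


class StageError(PsnstratError):
    """A pipeline stage failed.

    Carries the stage name and a machine-readable code so callers can
    report which stage aborted the run.
    """

    exit_code = 4

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"stage '{stage}' failed [{code}]: {message}")
        self.stage = stage
        self.code = code


class NormalizationError(PsnstratError):
    """A raw term could not be mapped under strict policy."""


class ClassificationError(PsnstratError):
    """A term mapped to a feature class inconsistent with its field."""


class UndefinedSimilarityError(PsnstratError):
    """Jaccard similarity requested for two empty sets."""


class UndefinedRelativeRiskError(PsnstratError):
    """Relative risk undefined (empty module or module covering the cohort)."""


class DegenerateTableError(PsnstratError):
    """A 2x2 contingency table has a zero marginal."""


class CoverageError(PsnstratError):
    """A partition does not cover every network node."""


class ParameterError(PsnstratError):
    """An operation parameter is out of range."""
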