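"""Exception hierarchy for kinomechip.

All package errors derive from :class:`KinomeChipError` so callers can catch
everything with one clause; most also derive from ``ValueError`` because they
signal bad inputs rather than internal faults.
"""


class KinomeChipError(Exception):
    """Base class for all kinomechip errors."""


class InvalidParameterError(KinomeChipError, ValueError):
    """A scalar parameter is outside its documented domain."""


class ConsistencyError(KinomeChipError, ValueError):
    """Identifiers disagree between annotation, ground truth, cohort or panel."""


class StructuralError(KinomeChipError, ValueError):
    """A table is missing rows required by its documented grid structure."""


class AllSaturatedError(KinomeChipError, ValueError):
    """Fewer than two unsaturated exposure points survive for a slope fit."""


class PairingError(KinomeChipError, ValueError):
    """A patient lacks one tissue of a tumor/adjacent pair."""


class ContrastError(KinomeChipError, ValueError):
    """A requested contrast label is absent from the matrix."""


class UnscorableError(KinomeChipError, ValueError):
    """A kinase has no usable substrates for the requested statistic."""


class DegenerateNullError(KinomeChipError, ValueError):
    """A permutation/sampling null collapsed to zero variance."""


class SizeError(KinomeChipError, ValueError):
    """A combinatorial bound was exceeded or a subset size is degenerate."""


class ConfigError(KinomeChipError, ValueError):
    """A configuration file is invalid (unknown keys, missing seed, ...)."""


class AnnotationError(KinomeChipError, ValueError):
    """A substrate→kinase annotation table violates its invariants."""


class PipelineStageError(KinomeChipError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
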