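"""Exception hierarchy for the methylscreen pipeline.

Every error raised by the library derives from :class:`MethylscreenError`,
so callers (and the CLI) can catch pipeline failures uniformly while the
specific classes keep unit-level diagnostics precise.
"""


class MethylscreenError(Exception):
    """Base class for all library errors."""


# --- trace processing ---------------------------------------------------

class TraceError(MethylscreenError):
    """Base class for electropherogram-processing errors."""


class NoNormalizationSignal(TraceError):
    """The normalization-tag signal could not be detected in a trace."""


class ShiftOutOfRange(TraceError):
    """A requested alignment shift would discard the tag or a CpG window."""


class ZeroNormalization(TraceError):
    """The integrated tag area is zero or negative; division is undefined."""


class PeakCountMismatch(TraceError):
    """Fewer reference peaks than CpG sites exceed the detection floor."""


class EmptyMeasurementSet(TraceError):
    """A methylation score was requested from zero CpG measurements."""


# --- survival statistics ------------------------------------------------

class SurvivalError(MethylscreenError):
    """Base class for survival-statistics errors."""


class EmptyCohort(SurvivalError):
    """An estimator was called on zero records."""


class DegenerateGroups(SurvivalError):
    """Log-rank groups are empty or contain no events."""


class DegenerateCutpoint(SurvivalError):
    """All marker values are equal; median dichotomization yields one group."""


class NonIdentifiable(SurvivalError):
    """Cox model cannot be fit: constant covariate or no events."""


class NonConvergence(SurvivalError):
    """Newton-Raphson failed to converge within the iteration budget."""


class NoEventsByHorizon(SurvivalError):
    """No events occurred on or before the requested ROC horizon."""


class UndefinedSurvival(SurvivalError):
    """Overall survival is zero at the horizon; specificity is undefined."""


# --- screening cascade --------------------------------------------------

class ScreenError(MethylscreenError):
    """Base class for marker-screen errors."""


class InsufficientPilotData(ScreenError):
    """A locus has fewer than two non-missing pilot scores."""


class InvalidP(ScreenError):
    """A p-value outside [0, 1] or a non-positive test count."""


class CohortOverlap(ScreenError):
    """A patient appears in both the training and the validation set."""


# --- simulation and I/O -------------------------------------------------

class InvalidParams(MethylscreenError):
    """Simulation parameters violate their declared invariants."""


class MissingRequiredColumn(MethylscreenError):
    """A cohort table lacks a required column."""


class EmptyTable(MethylscreenError):
    """A cohort table contains no patient rows."""


class IOFailure(MethylscreenError):
    """A report or table could not be written."""
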