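"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`FlowSPPSError`, so callers (and the CLI) can distinguish
domain errors from programming mistakes.
"""


class FlowSPPSError(ValueError):
    """Base class for all flowspps domain errors."""

    code = "error"


class FormatError(FlowSPPSError):
    """Malformed input file (missing columns, bad characters, ...)."""

    code = "format_error"


class TraceError(FlowSPPSError):
    """Invalid UV trace or chromatogram (non-monotone time, too short)."""

    code = "trace_error"


class ScheduleError(FlowSPPSError):
    """Invalid cycle schedule (overlap, non-contiguous indices)."""

    code = "schedule_error"


class PeakError(FlowSPPSError):
    """Peak measurement failure (truncated peak, unresolved half-width)."""

    code = "peak_error"


class SequenceError(FlowSPPSError):
    """Invalid peptide sequence or tag operation."""

    code = "sequence_error"


class SimulationError(FlowSPPSError):
    """Invalid simulation configuration or infeasible geometry."""

    code = "simulation_error"


class AnalysisError(FlowSPPSError):
    """Run-level analysis failure (bad reference, too many failed windows)."""

    code = "analysis_error"


class IntegrationError(FlowSPPSError):
    """Chromatogram integration failure (no peaks, ambiguous product)."""

    code = "integration_error"
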