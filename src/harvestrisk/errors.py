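"""Exception types shared across the assessment pipeline."""


class HarvestRiskError(Exception):
    """Base class for all package-specific errors."""


class InputError(HarvestRiskError, ValueError):
    """Malformed or inconsistent input data (duplicate years, bad values)."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending row."""


class UnfillableRangeError(HarvestRiskError):
    """No documented catch precedes the first missing year, so it cannot be filled."""


class ForcingGapError(HarvestRiskError):
    """The removals series does not cover every year the simulation needs."""


class CoverageError(HarvestRiskError):
    """A survey year falls outside the simulated trajectory."""


class DegeneratePosteriorError(HarvestRiskError):
    """All importance weights are zero: no prior draw is compatible with the surveys."""


class PipelineStageError(HarvestRiskError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
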