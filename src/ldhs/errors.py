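"""Exception hierarchy for ldhs."""


class LdhsError(Exception):
    """Base class for all ldhs errors."""


class FormatError(LdhsError, ValueError):
    """A file does not conform to the expected layout (missing columns, empty file, ...)."""


class ParseError(LdhsError, ValueError):
    """A value inside an otherwise well-formed file is invalid (e.g. genotype not in {0,1,2})."""


class AllocationError(LdhsError, ValueError):
    """Harmony allocation requested from an empty SNP universe."""


class SimulationError(LdhsError, RuntimeError):
    """The simulator could not satisfy its contract (unfillable quota, no acceptable table)."""


class ExhaustiveCapError(LdhsError, RuntimeError):
    """An exhaustive enumeration would exceed the configured evaluation cap."""
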