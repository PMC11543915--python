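"""Exception hierarchy for blastcomp."""


class BlastcompError(Exception):
    """Base class for all blastcomp errors."""


class SpecError(BlastcompError, ValueError):
    """A cohort or run specification violates its invariants."""


class FormatError(BlastcompError, ValueError):
    """An input file could not be parsed or its pieces disagree."""


class DataError(BlastcompError, ValueError):
    """Input data violate a contract (e.g. negative expression values)."""


class EmptyDatasetError(BlastcompError, ValueError):
    """A filtering step removed every cell of a dataset."""


class DependencyError(BlastcompError, RuntimeError):
    """A pipeline stage was requested before its upstream stage ran."""
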