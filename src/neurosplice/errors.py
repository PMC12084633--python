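"""Typed exceptions raised by the neurosplice library."""


class NeurospliceError(Exception):
    """Base class for all neurosplice errors."""


class EventDefinitionError(NeurospliceError):
    """A splicing event violates its structural invariants."""


class UnknownEventTypeError(EventDefinitionError):
    """An event type outside the six supported categories."""


class CountTableError(NeurospliceError):
    """A junction-count or expression table is malformed."""


class InsufficientDataError(NeurospliceError):
    """An operation was asked to run on an all-missing or empty input."""


class SequenceError(NeurospliceError):
    """A nucleotide sequence is malformed or lacks required flanking bases."""


class ConfigError(NeurospliceError):
    """A simulation or pipeline configuration is invalid."""


class AnalysisError(NeurospliceError):
    """A downstream analysis precondition is not met."""
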