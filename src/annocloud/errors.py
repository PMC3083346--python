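"""Exception hierarchy for annocloud."""


class CloudError(Exception):
    """Base class for all annocloud errors."""


class ParseError(CloudError):
    """An input file could not be parsed; carries line/element context."""


class UnsupportedFormat(CloudError):
    """Requested file format is not one of the supported dialects."""


class DuplicateNode(CloudError):
    """The same node id occurred more than once in an attribute table."""


class EmptySelection(CloudError):
    """The node selection is empty."""


class UnknownNode(CloudError):
    """A selected or attributed node id does not exist in the network/corpus."""


class UnknownWord(CloudError):
    """A word was requested that is absent from the statistics table."""


class InvalidCoefficient(CloudError):
    """Network normalization coefficient k outside [0, 1]."""


class InvalidRange(CloudError):
    """Font range invalid (non-positive or min > max)."""


class InvalidThreshold(CloudError):
    """Cluster merge threshold must be strictly positive."""


class InvalidParameters(CloudError):
    """Fixture generator parameters out of their legal range."""


class ConfigError(CloudError):
    """A run configuration failed validation; message lists every violation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
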