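"""Exception types shared across the package."""


class SeizurekitError(Exception):
    """Base class for package errors."""


class RecordFormatError(SeizurekitError, ValueError):
    """A record file (EDF/CSV) is malformed; the message names the field/row."""


class CapacityError(SeizurekitError, ValueError):
    """A sampling request exceeds what the record can supply.

    ``achievable`` carries the largest count that would have succeeded.
    """

    def __init__(self, message: str, achievable: int):
        super().__init__(message)
        self.achievable = achievable


class SchemaMismatchError(SeizurekitError, ValueError):
    """A feature table does not carry the columns a model was fitted on."""


class ConfigurationError(SeizurekitError, ValueError):
    """An invalid option value (e.g. unknown classifier name)."""
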