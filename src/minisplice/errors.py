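"""Exception hierarchy shared across the package."""


class MinispliceError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MinispliceError):
    """A transcript coordinate falls outside the gene model."""


class LabelParseError(MinispliceError):
    """A transcript label does not match the event grammar."""

    def __init__(self, label: str, token: str, message: str = ""):
        self.label = label
        self.token = token
        detail = f": {message}" if message else ""
        super().__init__(f"cannot parse {label!r} at token {token!r}{detail}")


class HgvsParseError(MinispliceError):
    """A variant description does not match the supported HGVS c. subset."""


class SequenceRequiredError(MinispliceError):
    """The requested analysis needs nucleotide sequences the model lacks."""


class QuantificationError(MinispliceError):
    """Peak quantification cannot proceed (e.g. nothing above threshold)."""


class EvidenceError(MinispliceError):
    """Evidence assignment is impossible for the given inputs."""


class InputError(MinispliceError):
    """Tabular or configuration input violates its contract."""
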