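"""Exception hierarchy."""


class OmicsCharError(Exception):
    """Base class for all package errors."""


class FormatError(OmicsCharError):
    """A file or cell does not conform to its declared format."""


class NegativeValuesError(OmicsCharError):
    """A matrix contains strictly negative values before log transformation,
    suggesting the data were already log-transformed upstream."""


class QuantTypeError(OmicsCharError):
    """The requested MaxQuant quantification type has no per-sample columns."""


class InclusionError(OmicsCharError):
    """A matrix fails the inclusion filters; carries the report."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "matrix fails inclusion filters: " + ", ".join(report.reasons)
        )
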