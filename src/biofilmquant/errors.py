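"""Exception hierarchy shared across the pipeline.

Validation errors signal a misconfigured request (bad parameters, bad
metadata); data errors signal that the inputs themselves are unusable
(missing files, degenerate images). The CLI maps them to exit codes 2
and 3 respectively.
"""


class BiofilmQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(BiofilmQuantError):
    """A parameter, config value or metadata field violates its contract."""


class DataError(BiofilmQuantError):
    """Input data is missing, unreadable or degenerate."""


class DegenerateHistogramError(DataError):
    """The intensity histogram has fewer than two occupied levels, so no
    threshold can be derived; the field must be flagged invalid."""
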