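"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit code 2);
``StatisticalError`` covers statistical preconditions such as samples too small
for a test (CLI exit code 3).
"""


class CodbenchError(Exception):
    """Base class for all package errors."""


class ValidationError(CodbenchError):
    """Invalid input data or configuration."""


class StatisticalError(CodbenchError):
    """A statistical procedure's preconditions are not met."""
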