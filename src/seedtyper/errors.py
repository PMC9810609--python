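"""Exception hierarchy.

``InputError`` covers malformed or inconsistent input files and arguments;
``QCError`` covers data that parse fine but fail quality control (e.g. no
informative markers left after filtering). The CLI maps these to distinct
exit codes.
"""


class SeedtyperError(Exception):
    """Base class for all package errors."""


class InputError(SeedtyperError):
    """Malformed, missing, or inconsistent input."""


class QCError(SeedtyperError):
    """Data passed parsing but failed a quality-control rule."""
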