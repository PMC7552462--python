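"""Exception hierarchy for glucospec."""


class GlucospecError(Exception):
    """Base class for all package errors."""


class FormatError(GlucospecError, ValueError):
    """A file violates the expected dialect (e.g. non-uniform wavelength header)."""


class SpectraParseError(GlucospecError, ValueError):
    """A cell could not be parsed; carries row/column context in the message."""


class DegenerateInputError(GlucospecError, ValueError):
    """Input is formally valid but degenerate for the operation (e.g. constant spectrum)."""


class AllocationError(GlucospecError, ValueError):
    """A stratified split could not allocate test samples to every stratum."""
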