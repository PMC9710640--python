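"""Exception hierarchy shared across the package."""


class RibresolveError(Exception):
    """Base class for all errors raised by ribresolve."""


class InputFormatError(RibresolveError):
    """A FASTA/GFF3/TSV input is malformed; the message names file and line."""


class EmptyResultError(RibresolveError):
    """A run produced no amplicons and the configuration forbids that."""
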