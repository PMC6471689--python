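"""Exception hierarchy shared across the package."""


class KmerflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KmerflowError):
    """Malformed FASTA/FASTQ or count-table input."""


class InvalidSymbolError(KmerflowError):
    """A character outside {A, C, G, T} where only unambiguous DNA is valid."""


class CorruptionError(KmerflowError):
    """A packed sequence whose word count disagrees with its stated length."""


class ParameterError(KmerflowError):
    """An out-of-range configuration or operation parameter."""


class PartitionViolationError(KmerflowError):
    """Two partition count tables share a k-mer: signature routing is broken."""
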