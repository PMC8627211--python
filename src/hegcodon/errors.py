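"""Exception hierarchy shared across the pipeline stages."""


class HegcodonError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedTableError(HegcodonError):
    """Requested NCBI translation table is not supported."""


class FrameError(HegcodonError):
    """Sequence length is not a multiple of three."""


class FastaParseError(HegcodonError):
    """Malformed FASTA input; message carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ReferenceDbError(HegcodonError):
    """Invalid reference protein database."""


class ExternalHitsError(HegcodonError):
    """Malformed external aligner tabular output."""


class ZeroHegError(HegcodonError):
    """No HEG family survived the homology search."""


class InsufficientOverlapError(HegcodonError):
    """Too few comparable codons between two usage profiles."""


class ConstantVectorError(HegcodonError):
    """Pearson correlation is undefined for a constant vector."""
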