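"""Exception hierarchy for fatal pipeline errors."""


class HtsqcError(Exception):
    """Base class for all fatal errors raised by this package."""


class FastqParseError(HtsqcError):
    """Malformed FASTQ input: truncated record, bad header, length mismatch,
    or a base outside the {A, C, G, T, N} alphabet."""


class GzipCorruptError(HtsqcError):
    """A file carries the gzip magic number but cannot be decompressed."""


class PairSyncError(HtsqcError):
    """Paired files are out of lockstep: mismatched ids or unequal lengths."""


class EncodingDetectionError(HtsqcError):
    """Quality-encoding detection failed (no quality characters sampled)."""


class QualityRangeError(HtsqcError):
    """A quality character falls below the legal range of the assumed encoding."""


class ConfigError(HtsqcError):
    """Invalid or mutually exclusive configuration values."""
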