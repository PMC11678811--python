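"""Exception types shared across the package."""


class CtdnaSignalError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(CtdnaSignalError):
    """Input file does not follow the expected VCF/TSV layout."""


class TableValidationError(CtdnaSignalError):
    """Parsed values violate a domain invariant (e.g. AD > DP)."""


class ManifestError(CtdnaSignalError):
    """Sample-role manifest is inconsistent with the data."""


class NoiseModelError(CtdnaSignalError):
    """Noise model cannot be built (fewer than two control plasmas)."""


class DegenerateNoiseError(CtdnaSignalError):
    """sigma_noise is zero, so the z-score is undefined."""


class UndefinedSignalError(CtdnaSignalError):
    """No variants survive filtering; signal statistics are undefined."""
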