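"""Exception hierarchy for the readthrough-quantification pipeline.

Every failure mode raised by the library derives from :class:`TrquantError`
so callers (and the CLI) can catch pipeline errors without masking bugs.
"""


class TrquantError(Exception):
    """Base class for all pipeline errors."""


class ContextError(TrquantError):
    """The codon at the requested position is not a stop codon."""


class BoundsError(TrquantError):
    """A stop-codon-context window exceeds the sequence bounds."""


class FormatError(TrquantError):
    """An input file is malformed or lacks required columns/channels."""


class LayoutError(TrquantError):
    """Event data references a well missing from the plate layout."""


class NormalizationError(TrquantError):
    """A plate lacks usable background or 100%-control wells."""


class RatioError(TrquantError):
    """A fluorescence or band-intensity ratio has a zero denominator."""


class AggregationError(TrquantError):
    """A replicate group is empty or too small to aggregate."""


class StatError(TrquantError):
    """A statistic is undefined for the given data (degenerate input)."""


class PairingError(TrquantError):
    """Paired vectors have mismatched lengths."""


class BlotPairingError(TrquantError):
    """Lanes from different blots were compared."""


class MaskError(TrquantError):
    """No nuclear region can be derived from the DAPI profile."""


class EnrichmentError(TrquantError):
    """The nuclear mask leaves no outside region to compare against."""


class ConfigError(TrquantError):
    """A simulation or pipeline configuration value is invalid."""
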