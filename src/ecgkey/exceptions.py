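"""Named error conditions raised across the pipeline."""


class EcgKeyError(Exception):
    """Base class for all package errors."""


class ParameterError(EcgKeyError, ValueError):
    """Invalid or out-of-range parameter; the message names the parameter."""


class NoBeatsError(EcgKeyError):
    """Delineation found no QRS complexes in the record."""


class InsufficientBeatsError(EcgKeyError):
    """Fewer beats survived than a stage requires (e.g. < 3 for an ensemble)."""


class DegenerateSectionError(EcgKeyError):
    """A beat section to be time-normalized has zero or negative length."""


class MissingLandmarkError(EcgKeyError):
    """A feature cannot be computed because a fiducial landmark is absent."""


class QuantizerBuildError(EcgKeyError):
    """No feature pair survived screening and cluster-model fitting."""


class CodeParameterError(EcgKeyError):
    """No BCH parameter set achieves the requested correction capacity."""


class ReproductionError(EcgKeyError):
    """The fuzzy extractor could not reproduce a key (decoding failure)."""


class ConfigError(EcgKeyError, ValueError):
    """Configuration validation failure; the message enumerates bad keys."""
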