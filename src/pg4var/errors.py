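"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """Invalid or inconsistent analysis / simulation configuration."""


class ParameterError(ValueError):
    """Invalid algorithm parameter (e.g. non-positive window size)."""


class MalformedAnnotationError(ValueError):
    """Gene annotation violates structural assumptions (e.g. CDS outside exons)."""


class PlacementError(ValueError):
    """An interval cannot be placed anywhere in the permitted space."""


class UndefinedDensityError(ValueError):
    """Density requested over a zero-length interval set."""


class DataInconsistencyError(ValueError):
    """Cross-file inconsistency, e.g. VCF REF allele disagrees with the FASTA."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""
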