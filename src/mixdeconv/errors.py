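"""Exception types shared across the pipeline."""


class MixdeconvError(Exception):
    """Base class for package errors."""


class AmbiguousPanelError(MixdeconvError):
    """Two loci cannot be distinguished by their amplicon flanks."""


class InsufficientReadsError(MixdeconvError):
    """A mixture requested more reads from a source than it contains."""


class InsufficientDataError(MixdeconvError):
    """Too few samples or data points to estimate a model."""


class MissingTruthError(MixdeconvError):
    """An observed locus has no genotype in the supplied truth profile."""


class NoRepeatError(MixdeconvError):
    """A repeat region too short to contain a single motif copy."""


class UnknownAlleleError(MixdeconvError):
    """An allele is outside the panel/frequency universe."""


class ModelSchemaError(MixdeconvError):
    """A persisted calibration model cannot be loaded."""
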