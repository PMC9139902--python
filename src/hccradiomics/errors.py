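"""Named exceptions raised across the package."""


class HCCRadiomicsError(Exception):
    """Base class for all package errors."""


class FeatureNameError(HCCRadiomicsError, ValueError):
    """A feature name token could not be interpreted."""


class FeatureTableError(HCCRadiomicsError, ValueError):
    """A feature table violates its structural contract."""


class MissingValueError(FeatureTableError):
    """A feature table cell is empty or non-numeric."""


class PairingError(HCCRadiomicsError, ValueError):
    """Lesion/healthy-tissue rows cannot be matched one-to-one by subject."""


class ConstantFeatureError(HCCRadiomicsError, ValueError):
    """A feature column has zero sample variance where variation is required."""


class SingleClassError(HCCRadiomicsError, ValueError):
    """Both outcome classes are required but only one is present."""


class InsufficientFeaturesError(HCCRadiomicsError, ValueError):
    """Too few features survive univariate screening to build a model."""


class DegenerateVarianceError(HCCRadiomicsError, ValueError):
    """A variance estimate is zero where a test statistic requires it."""
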