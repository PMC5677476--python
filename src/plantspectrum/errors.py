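"""Exception types shared across the pipeline."""


class PlantSpectrumError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(PlantSpectrumError, ValueError):
    """A raw organ measurement violates its physical constraints."""


class InvalidIntervalError(PlantSpectrumError, ValueError):
    """A repeated-measurement record has a non-positive time interval."""


class MissingAllometryError(PlantSpectrumError, KeyError):
    """No diameter-height allometry parameters exist for a species."""


class PhylogenyError(PlantSpectrumError, ValueError):
    """Tree parsing or tree-based computation failed."""


class ZeroVarianceContrastError(PhylogenyError):
    """An independent contrast has zero expected variance (both branches zero)."""


class DegenerateInputError(PlantSpectrumError, ValueError):
    """Input has zero variance or is otherwise statistically degenerate."""


class InsufficientDataError(PlantSpectrumError, ValueError):
    """Too few observations for the requested statistic."""


class TraitMismatchError(PlantSpectrumError, ValueError):
    """Trait names disagree between two tables or specifications."""
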