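"""Exception hierarchy shared by the whole package."""


class ColloidSpotError(Exception):
    """Base class for all package-specific errors."""


class InputError(ColloidSpotError):
    """A required input (file, directory, ground-truth frame) is missing."""


class FormatError(ColloidSpotError):
    """An input decodes but violates a structural invariant (shape, CSV row)."""


class DegenerateInputError(ColloidSpotError):
    """The data cannot support the requested operation (e.g. a constant
    frame offered to Otsu, or fewer distinct intensities than clusters)."""


class ConfigError(ColloidSpotError):
    """A scene or detector configuration is unsatisfiable."""


class UndefinedMetricError(ColloidSpotError):
    """A metric whose denominator is zero for reasons other than the 0/0
    convention (e.g. TCR on a frame with no targets and no detections)."""
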