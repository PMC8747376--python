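"""Exception hierarchy for maizephen."""


class MaizephenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MaizephenError):
    """Invalid scene or pipeline configuration (e.g. overlapping plots)."""


class FormatError(MaizephenError):
    """A raster file does not match the expected 4-band integer layout."""


class WindowError(MaizephenError):
    """A crop window falls outside the raster bounds."""


class ExtractionError(MaizephenError):
    """A plot footprint does not intersect the raster."""


class NamingError(MaizephenError):
    """A sample name cannot be built or parsed."""


class GraphError(MaizephenError):
    """A neighbour graph cannot be built (empty mask)."""


class DegenerateInputError(MaizephenError):
    """An indicator received input it is undefined for (e.g. constant plane)."""


class SchemaError(MaizephenError):
    """A feature table does not cover the requested schema."""


class SelectionError(MaizephenError):
    """Feature selection cannot run (e.g. single-class table)."""


class SplitError(MaizephenError):
    """A stratified split is impossible (class with a single sample)."""


class ParameterError(MaizephenError):
    """An estimator parameter is out of range (e.g. k > training size)."""


class MetricError(MaizephenError):
    """Metrics requested on an empty confusion matrix."""
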