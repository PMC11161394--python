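"""Exception hierarchy shared by all surfload modules."""


class SurfloadError(Exception):
    """Base class for all package errors."""


class FormatError(SurfloadError):
    """A file does not conform to its declared on-disk format."""


class IntegrityError(SurfloadError):
    """Inputs are internally inconsistent (e.g. map length != vertex count)."""


class DesignError(SurfloadError):
    """A GLM design matrix is unusable (rank deficiency, too few rows)."""


class PipelineError(SurfloadError):
    """A pipeline stage cannot proceed (e.g. reference group too small)."""
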