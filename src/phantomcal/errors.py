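"""Exception hierarchy shared across the package."""


class PhantomCalError(Exception):
    """Base class for all phantomcal errors."""


class MetadataError(PhantomCalError):
    """A volume file is missing required physical metadata (e.g. spacing)."""


class ParameterError(PhantomCalError, ValueError):
    """An argument violates a documented precondition."""


class SpecError(PhantomCalError, ValueError):
    """A phantom / generator specification is internally inconsistent."""


class GeometryError(PhantomCalError):
    """A geometric construction is impossible (implant outside canal, ...)."""


class GenerationError(PhantomCalError):
    """Synthetic-data generation could not satisfy its target."""


class SegmentationError(PhantomCalError):
    """Segmentation found fewer/other structures than expected."""
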