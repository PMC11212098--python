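"""Exception hierarchy shared across the pipeline stages."""


class GlioFusionError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GlioFusionError, ValueError):
    """A configuration or specification value is out of its legal range."""


class GridConsistencyError(GlioFusionError):
    """Modality volumes and/or mask do not share the same voxel grid."""


class LabelError(GlioFusionError):
    """A segmentation mask contains a label outside {0, 1, 2, 4}."""


class EmptyTumorError(GlioFusionError):
    """The whole-tumor mask has no foreground voxels."""


class DegenerateMeshError(GlioFusionError):
    """A surface mesh encloses (numerically) zero volume."""


class UndefinedMetricError(GlioFusionError):
    """A metric is undefined for the given inputs (e.g. one-class AUC)."""


class StateError(GlioFusionError):
    """An object was used before being fitted/trained."""


class CapabilityError(GlioFusionError):
    """The model does not expose what the operation needs (e.g. no spatial maps)."""
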