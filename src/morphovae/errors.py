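"""Exception types shared across the package."""


class MorphoVAEError(Exception):
    """Base class for package-specific errors."""


class InvalidLandmarkError(MorphoVAEError, ValueError):
    """Anatomical landmark configuration is degenerate (e.g. condyle midpoint == tip)."""


class EmptyHalfError(MorphoVAEError, ValueError):
    """A sagittal split produced an empty half-volume."""


class CanvasOverflowError(MorphoVAEError, ValueError):
    """Scaled silhouette does not fit on the output canvas."""

    def __init__(self, required: int, canvas: int):
        self.required = required
        self.canvas = canvas
        super().__init__(
            f"scaled shape needs a {required}x{required} canvas, have {canvas}x{canvas}"
        )


class EmptyCropError(MorphoVAEError, ValueError):
    """A crop removed every occupied voxel."""


class DivergenceError(MorphoVAEError, RuntimeError):
    """Training produced a non-finite loss."""


class ShapeError(MorphoVAEError, ValueError):
    """Array does not have the geometry a model or op expects."""
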