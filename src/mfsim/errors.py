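"""Exception hierarchy for the mfsim pipeline."""


class MFSimError(Exception):
    """Base class for all mfsim errors."""


class SamplingError(MFSimError):
    """Grid spacing violates a sampling (Nyquist) requirement."""


class DimensionError(MFSimError):
    """Array shape or bounds are degenerate or inconsistent."""


class VoxelMismatchError(MFSimError):
    """Two gridded objects do not share voxel sizes."""


class PackingError(MFSimError):
    """Random placement with a minimum-separation constraint failed."""


class LayoutError(MFSimError):
    """Tile layout does not fit the camera frame, or tiles overlap."""


class CalibrationError(MFSimError):
    """Tile-map calibration could not locate a reliable correlation peak."""


class EstimationError(MFSimError):
    """Illumination-pattern parameter estimation failed."""


class ReconstructionError(MFSimError):
    """SIM reconstruction received inconsistent or incomplete input."""


class FormatError(MFSimError):
    """A file on disk could not be parsed as the expected format."""


class ConfigError(MFSimError):
    """Invalid or unknown configuration values."""
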