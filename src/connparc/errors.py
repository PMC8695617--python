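"""Exception hierarchy shared across connparc modules."""


class ConnparcError(Exception):
    """Base class for all connparc errors."""


class ConfigurationError(ConnparcError):
    """A configuration object violates one of its invariants."""


class GridMismatchError(ConnparcError):
    """Two volumes that must share a grid do not."""


class VolumeFormatError(ConnparcError):
    """A file could not be parsed as a volumetric image."""


class NormalizationError(ConnparcError):
    """Grand-mean scaling is undefined (mean indistinguishable from zero)."""


class ZeroVarianceError(ConnparcError):
    """One or more time series have zero variance where correlation is needed."""

    def __init__(self, voxel_indices, message=None):
        self.voxel_indices = list(voxel_indices)
        super().__init__(
            message
            or f"zero-variance series at flat voxel indices {self.voxel_indices[:20]}"
            + ("..." if len(self.voxel_indices) > 20 else "")
        )


class LabelLookupError(ConnparcError, KeyError):
    """A requested ROI name is not present in the atlas."""


class DegenerateNullError(ConnparcError):
    """Permutation null distribution has zero spread; z is undefined."""


class DegenerateTestError(ConnparcError):
    """A permutation test's inputs make the statistic trivially constant."""
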