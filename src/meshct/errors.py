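"""Exception hierarchy shared across the package."""


class MeshCTError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(MeshCTError):
    """File could not be parsed as an STL/OBJ triangle mesh."""


class DegenerateMeshError(MeshCTError):
    """Mesh carries no usable geometry (empty, or zero-area faces only)."""


class EmptySceneError(MeshCTError):
    """An operation requiring at least one structure received none."""


class ParameterError(MeshCTError):
    """A numeric parameter is outside its valid range."""


class EncodingError(MeshCTError):
    """HU values cannot be represented in the stored-pixel encoding."""


class SeriesInconsistencyError(MeshCTError):
    """DICOM slices/phases do not form one consistent series."""


class AmbiguousSeriesError(MeshCTError):
    """A directory mixes instances from more than one series."""


class ConfigError(MeshCTError):
    """Run configuration failed schema or referential validation."""
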