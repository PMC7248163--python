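"""Exception hierarchy shared across facesym modules."""


class FacesymError(Exception):
    """Base class for all facesym errors."""


class ParseError(FacesymError):
    """Input could not be parsed (malformed row, bad field, wrong header)."""


class ValidationError(FacesymError):
    """Input parsed but violates the landmark-set contract."""


class GeometryError(FacesymError):
    """Degenerate geometry (collinear reference points, coplanar witnesses)."""


class AnalysisError(FacesymError):
    """A computation's preconditions are not met (missing landmark, n too small)."""
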