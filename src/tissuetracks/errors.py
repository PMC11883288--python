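"""Exception hierarchy shared across the pipeline."""


class TissueTracksError(Exception):
    """Base class for all package errors."""


class ValidationError(TissueTracksError):
    """An input object violates one of its documented invariants."""


class MeshFormatError(TissueTracksError):
    """A mesh or manifest file could not be parsed."""


class StructuralError(TissueTracksError):
    """The lineage graph is missing a required predecessor/successor edge."""
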