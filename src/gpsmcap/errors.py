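"""Exception types shared across the package."""


class GpsmError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(GpsmError):
    """Input sequences do not form a valid alignment (e.g. ragged lengths)."""


class EncodingError(GpsmError):
    """A residue character is outside the alphabet."""


class SizeError(GpsmError):
    """A requested computation exceeds its enumerability / size cap."""
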