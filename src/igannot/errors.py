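"""Exception hierarchy for igannot.

Every error raised deliberately by the package derives from
:class:`IgannotError`, so callers embedding the library can catch one type.
"""


class IgannotError(Exception):
    """Base class for all igannot errors."""


class InvalidAlphabetError(IgannotError):
    """Requested reduced-alphabet size is outside the supported range."""


class InvalidResidueError(IgannotError):
    """A sequence contains a character that is not a valid residue.

    Carries ``position`` (0-based) and ``character`` attributes.
    """

    def __init__(self, position: int, character: str, context: str = ""):
        self.position = position
        self.character = character
        where = f" in {context}" if context else ""
        super().__init__(
            f"invalid residue {character!r} at position {position}{where}"
        )


class EmptyInputError(IgannotError):
    """An operation received an empty sequence set or file."""


class ModelBuildError(IgannotError):
    """A germline segment or alignment cannot be turned into a model."""


class AlignmentFormatError(IgannotError):
    """An alignment file is unreadable, garbled or non-rectangular."""


class RegistryError(IgannotError):
    """Model registry problem: bad name, duplicate, missing entry."""


class ModelNotFoundError(RegistryError):
    """The named model is not present in the registry."""


class DegenerateModelError(IgannotError):
    """Training produced a profile with no usable match states."""
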