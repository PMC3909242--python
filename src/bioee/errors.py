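"""Exception hierarchy shared across the package."""


class BioeeError(Exception):
    """Base class for all package-specific errors."""


class StandoffParseError(BioeeError):
    """A standoff (.a1/.a2) or parse line could not be interpreted."""


class IntegrityError(BioeeError):
    """An annotation disagrees with the document text or with an invariant."""


class AlignmentError(BioeeError):
    """Parse output does not align with the document it claims to describe."""


class SerializationError(BioeeError):
    """A document cannot be written (dangling or cyclic references)."""


class UndefinedScoreError(BioeeError):
    """A coupling score is undefined for the given counts."""


class MappingError(BioeeError):
    """A feature has no entry in the root concept map."""


class AssemblyError(BioeeError):
    """Event assembly encountered a dangling reference."""


class TrainingError(BioeeError):
    """Classifier training received unusable input."""
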