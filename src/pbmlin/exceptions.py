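"""Exception hierarchy for pbmlin."""


class PBMError(Exception):
    """Base class for all pbmlin errors."""


class SampleParseError(PBMError):
    """A sample or design table could not be parsed."""


class SequenceAlphabetError(PBMError):
    """A probe sequence contains characters outside {A, C, G, T}."""


class GridIntegrityError(PBMError):
    """Duplicate or invalid array grid coordinates."""


class ModelFormatError(PBMError):
    """An affinity-model file is malformed or has an unsupported version."""


class DomainError(PBMError):
    """Input values violate a mathematical precondition (e.g. log of a
    negative intensity)."""
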