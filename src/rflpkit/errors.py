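"""Exception hierarchy shared by all rflpkit modules."""


class RflpKitError(Exception):
    """Base class for all rflpkit errors."""


class AlphabetError(RflpKitError, ValueError):
    """A sequence letter falls outside the permitted alphabet.

    ``position`` is the 0-based offset of the offending character;
    the message reports it 1-based.
    """

    def __init__(self, char: str, position: int, context: str = "sequence"):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position + 1} in {context}"
        )


class SpecificationError(RflpKitError, ValueError):
    """Input sequence does not conform to the declared input dialect."""


class BracketParseError(SpecificationError):
    """A bracketed variation group is malformed."""


class TransformUnsupportedError(RflpKitError, ValueError):
    """No IUPAC code can represent the requested variation (indel or
    multi-base allele)."""


class CombinatorialLimitError(RflpKitError, ValueError):
    """An allele or pattern expansion would exceed the configured cap."""

    def __init__(self, count: int, cap: int, what: str = "expansion"):
        self.count = count
        self.cap = cap
        super().__init__(f"{what} would produce {count} sequences (cap {cap})")


class RebaseParseError(RflpKitError, ValueError):
    """The enzyme catalog flat file cannot be parsed."""


class RecognitionParseError(RebaseParseError):
    """A recognition sequence contains characters outside IUPAC letters
    and cut-site notation."""


class NoVariationError(RflpKitError, ValueError):
    """An RFLP judgment was requested on a template without variation."""


class ReportJoinError(RflpKitError, KeyError):
    """A verdict references an enzyme name absent from the catalog."""
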