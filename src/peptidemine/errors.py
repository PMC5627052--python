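"""Exception hierarchy shared by all pipeline stages."""


class PeptideMineError(Exception):
    """Base class for all errors raised by this package."""


class EmptyInput(PeptideMineError):
    pass


class DuplicateId(PeptideMineError):
    pass


class AlphabetError(PeptideMineError):
    pass


class TooShort(PeptideMineError):
    pass


class InvalidHit(PeptideMineError):
    pass


class BadFrame(PeptideMineError):
    pass


class InvalidSites(PeptideMineError):
    pass


class PredicateSyntaxError(PeptideMineError):
    pass


class AmbiguousInput(PeptideMineError):
    pass


class MissingReference(PeptideMineError):
    pass


class Inconsistent(PeptideMineError):
    pass


class TooFew(PeptideMineError):
    pass


class LayoutDiverged(PeptideMineError):
    def __init__(self, iteration: int):
        super().__init__(f"layout diverged (non-finite coordinates) at iteration {iteration}")
        self.iteration = iteration


class RaggedAlignment(PeptideMineError):
    pass


class BadFormat(PeptideMineError):
    pass


class BadSpec(PeptideMineError):
    pass


class BadIndex(PeptideMineError):
    pass
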