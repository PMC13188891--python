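"""Exception hierarchy shared across the package."""


class BtmapError(Exception):
    """Base class for all btmap errors."""


class InvalidParameterError(BtmapError, ValueError):
    """A parameter is outside its documented range."""


class GenomeMapError(BtmapError, ValueError):
    """Malformed genome map (lengths, marker order, positions)."""


class EmptyPopulationError(BtmapError, ValueError):
    """An operation that needs individuals received an empty population."""


class SelectionModelError(BtmapError, KeyError):
    """The selection model does not cover a genotype present in the population."""


class UndefinedAlleleFrequencyError(BtmapError, ZeroDivisionError):
    """Allele frequency requested at a site with zero total depth."""


class InsufficientDataError(BtmapError, ValueError):
    """Too few (or degenerate) values for a density estimate or test."""


class UndefinedDominanceError(BtmapError, ZeroDivisionError):
    """Dominance coefficient undefined (no homozygous survivors, or w_RR == w_SS)."""


class UnrecognizedAlleleError(BtmapError, ValueError):
    """A diagnostic PCR fragment size does not match any registered allele."""


class FormatError(BtmapError, ValueError):
    """A file does not conform to the expected tabular format.

    Carries the offending line numbers when they are known.
    """

    def __init__(self, message, lines=None):
        self.lines = list(lines) if lines else []
        if self.lines:
            message = f"{message} (lines: {', '.join(map(str, self.lines))})"
        super().__init__(message)
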