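"""Exception hierarchy shared across the package."""


class TaxovoteError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TaxovoteError):
    """A structured text input (dump, CSV, TSV) violates its dialect.

    Carries the offending source name and 1-based line number when known.
    """

    def __init__(self, message, source=None, line=None):
        loc = ""
        if source is not None:
            loc += f"{source}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.source = source
        self.line = line


class TaxonomyError(TaxovoteError):
    """The taxonomy violates a structural invariant (orphan, cycle, rank order)."""


class UnknownTaxonError(TaxovoteError, KeyError):
    """A taxon ID was queried that is not a node of the tree at hand."""


class ConsistencyError(TaxovoteError):
    """Two inputs that must describe the same read set disagree."""


class UndefinedMetricError(TaxovoteError):
    """A metric's denominator is zero; raised rather than returning 0."""


class UnsupportedFormatError(TaxovoteError):
    """An input format this package deliberately does not convert."""
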