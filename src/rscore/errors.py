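"""Exception types shared across the package."""


class RscoreError(Exception):
    """Base class for all package errors."""


class UndefinedMetricError(RscoreError, ValueError):
    """A metric has no defined value for the given input.

    Raised e.g. for a VAF with zero total template, a MAPD with no valid
    adjacent amplicon pair, or an R-score with non-positive MAPD or VAF.
    """


class ValidationError(RscoreError, ValueError):
    """Malformed input: bad config fields, bad table rows, duplicates."""


class EmptyResultError(RscoreError, ValueError):
    """An analysis stage produced no records to work with."""
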