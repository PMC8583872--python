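"""Exception hierarchy shared across the package."""


class CrosswalkError(Exception):
    """Base class for all rpqscat errors."""


class ValidationError(CrosswalkError, ValueError):
    """Input failed a scale, cohort, or equation precondition.

    The message always names the offending item, cell, or value so that the
    CLI can surface it directly.
    """


class UndefinedStatisticError(CrosswalkError, ValueError):
    """A statistic is mathematically undefined for the given input.

    Raised instead of silently returning 0 or NaN, e.g. a rank correlation on
    a constant vector or a concordance statistic with only one class present.
    """
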