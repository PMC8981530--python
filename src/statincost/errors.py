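"""Exception hierarchy. Every error raised by the package derives from
:class:`StatinCostError` so pipelines can catch one type at the boundary."""


class StatinCostError(Exception):
    """Base class for all package errors."""


class SchemaError(StatinCostError):
    """A delimited input file is missing a required column."""


class RowValidationError(StatinCostError):
    """A data row violates a domain invariant.

    ``row`` is the 1-based index of the offending data row (header excluded).
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DuplicateKeyError(StatinCostError):
    """A table contains two rows with the same unique key."""


class MissingDataError(StatinCostError):
    """A computation was asked for a (drug, year) with no price cells."""


class MissingPriceError(StatinCostError):
    """No price cell exists for a (statin, strength, year) needed to cost a record."""


class MissingDeflatorError(StatinCostError):
    """The deflator series has no index for a requested year."""


class EquivalenceLookupError(StatinCostError):
    """A (statin, dose) pair is absent from the equivalence table."""


class OutOfBandError(StatinCostError):
    """An LDL reduction below 20% falls under every defined intensity band."""
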