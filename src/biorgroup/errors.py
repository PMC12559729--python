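"""Exception hierarchy shared across the package."""


class BioRGroupError(Exception):
    """Base class for all errors raised by this package."""


class MoleculeParseError(BioRGroupError):
    """A SMILES or InChI string could not be parsed or validated.

    Carries the offending text so batch callers can report it verbatim.
    """

    def __init__(self, text: str, reason: str = "unparsable input"):
        self.text = text
        self.reason = reason
        super().__init__(f"{reason}: {text!r}")


class StructureError(BioRGroupError):
    """A parsed molecule violates a structural precondition (e.g. an isolated wildcard)."""


class IdentifierCollisionError(BioRGroupError):
    """The same compound identifier was supplied with two different structures."""


class QueryFileError(BioRGroupError):
    """The query TSV could not be read."""


class DatasetSchemaError(BioRGroupError):
    """A dataset file does not carry the expected eight-column schema."""

    def __init__(self, missing, extra):
        self.missing = tuple(missing)
        self.extra = tuple(extra)
        super().__init__(
            f"bad dataset schema: missing columns {list(self.missing)}, "
            f"unexpected columns {list(self.extra)}"
        )


class DatasetRowError(BioRGroupError):
    """A dataset row failed to decode; carries the zero-based data-row index."""

    def __init__(self, row_index: int, column: str, reason: str):
        self.row_index = row_index
        self.column = column
        super().__init__(f"row {row_index}, column {column!r}: {reason}")


class OracleSizeError(BioRGroupError):
    """The brute-force oracle refuses instances above its size bound."""


class FixtureError(BioRGroupError):
    """A fixture specification cannot be satisfied (e.g. substituent pool exhausted)."""
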