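"""Exception hierarchy shared across the package."""


class MolvaultError(Exception):
    """Base class for all package errors."""


class EntryRejected(MolvaultError):
    """A single input entry could not be turned into a molecule.

    Carries enough context (source path / entry index) to log and skip the
    record; imports never abort on one bad entry.
    """

    def __init__(self, reason: str, entry_index: int | None = None,
                 source: str | None = None):
        self.reason = reason
        self.entry_index = entry_index
        self.source = source
        where = ""
        if source is not None:
            where += f" source={source!r}"
        if entry_index is not None:
            where += f" entry={entry_index}"
        super().__init__(f"entry rejected:{where} reason: {reason}")


class SmartsError(MolvaultError):
    """A SMARTS pattern failed to parse.

    ``position`` is a best-effort character offset of the first point at
    which the pattern stops being parseable.
    """

    def __init__(self, pattern: str, position: int | None = None):
        self.pattern = pattern
        self.position = position
        at = f" at position {position}" if position is not None else ""
        super().__init__(f"malformed SMARTS{at}: {pattern!r}")


class NotFound(MolvaultError):
    """A molecule / instance / set / source key does not exist."""


class SchemaError(MolvaultError):
    """The database file is not a store or has an incompatible schema."""


class NameClash(MolvaultError):
    """A molecule-set name is already taken."""
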