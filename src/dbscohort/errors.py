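"""Exception hierarchy for the DBS data-management toolkit.

Every error the package raises deliberately derives from :class:`DbsCohortError`
so callers (and the CLI) can distinguish data/validation failures (exit code 1)
from genuine bugs.
"""


class DbsCohortError(Exception):
    """Base class for all errors raised by this package."""


class SchemaMismatchError(DbsCohortError):
    """The file at the given path is not a database created by this package."""


class MappingError(DbsCohortError):
    """A mapping file is malformed or references unknown schema targets."""


class FormatError(DbsCohortError):
    """An input file does not conform to the expected dialect."""


class BidsNameError(DbsCohortError):
    """A filename cannot be parsed as, or formatted into, a valid BIDS name."""


class LayoutError(DbsCohortError):
    """A subject/category/path combination violates the tree layout rules."""


class IntegrityError(DbsCohortError):
    """A write would violate referential integrity (dangling or cyclic link)."""


class ConflictError(DbsCohortError):
    """Same path registered with conflicting metadata or content."""


class NotFoundError(DbsCohortError):
    """A referenced record does not exist."""


class CriteriaError(DbsCohortError):
    """A query criterion uses an unknown enumeration value."""
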