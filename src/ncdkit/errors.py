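"""Exception hierarchy for the toolkit.

Every raised condition named in an operation contract has a dedicated class so
callers can catch precisely; all inherit from :class:`NCDKitError`.
"""


class NCDKitError(Exception):
    """Base class for all toolkit errors."""


class UnknownSystemError(NCDKitError, KeyError):
    """A code-system identifier is not in the packaged registry."""


class UnknownCodeError(NCDKitError, KeyError):
    """A code token does not exist in the named code system."""


class InvalidLevelError(NCDKitError, ValueError):
    """A DIN metadata level outside 1-3 was requested."""


class InvalidPeriodError(NCDKitError, ValueError):
    """An export period whose start lies after its end."""


class CodeCategoryMismatchError(NCDKitError, ValueError):
    """A game/lifestyle entry carries a code from the wrong code system."""


class DuplicatePractitionerError(NCDKitError, ValueError):
    """A second practitioner link on a document that already has one."""


class UnknownArchetypeError(NCDKitError, KeyError):
    """An application archetype id outside G1-G8."""


class InvalidParamsError(NCDKitError, ValueError):
    """Generator parameters violating their invariants."""


class UnknownFaultError(NCDKitError, KeyError):
    """A fault kind not present in the fault catalogue."""


class UnknownIssueCodeError(NCDKitError, KeyError):
    """A validation issue code not present in the issue catalogue."""


class MalformedDocumentError(NCDKitError, ValueError):
    """Input that is structurally not an NCD document bundle."""


class ParseError(NCDKitError, ValueError):
    """Input text that is not well-formed JSON."""


class SerializationError(NCDKitError, ValueError):
    """A document violating model invariants cannot be serialized."""


class InvalidManifestError(NCDKitError, ValueError):
    """An application manifest violating its invariants."""


class CatalogCorruptError(NCDKitError, ValueError):
    """The packaged requirement catalog fails its own invariants."""
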