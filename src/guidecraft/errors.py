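"""Exception hierarchy.

Every error raised on a documented contract derives from
:class:`GuidecraftError`, so callers (and the CLI) can catch one type.
``ContractError`` additionally derives from :class:`ValueError` because
precondition violations are, at bottom, bad argument values.
"""


class GuidecraftError(Exception):
    """Base class for all guidecraft errors."""


class ContractError(GuidecraftError, ValueError):
    """A documented precondition was violated by the caller."""


class RegistryError(GuidecraftError, KeyError):
    """An unknown name was requested from a model/template registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class ConfigurationError(GuidecraftError):
    """A packaged or user-supplied parameter table is incomplete or invalid."""


class ProvenanceError(GuidecraftError):
    """An index and a genome (or model) do not belong together."""


class IndexFormatError(GuidecraftError):
    """An on-disk uniqueness index is corrupt or has the wrong version."""


class AnnotationError(GuidecraftError):
    """A GFF3 annotation is malformed or inconsistent with the genome."""
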