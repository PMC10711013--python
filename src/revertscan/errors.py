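"""Exception hierarchy shared across the package."""


class RevertscanError(Exception):
    """Base class for all package errors."""


class ConfigError(RevertscanError):
    """Malformed or inconsistent configuration (names the offending field)."""


class ModelError(RevertscanError):
    """Gene-model invariant violation (CDS structure, sequence alphabet, ...)."""


class VariantConflictError(RevertscanError):
    """Two variants with overlapping reference footprints cannot share a haplotype."""


class ReferenceMismatchError(RevertscanError):
    """A variant's REF field disagrees with the reference sequence."""


class ContractError(RevertscanError):
    """An operation received input violating its documented contract."""
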