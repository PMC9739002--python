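"""Exception hierarchy for cohort I/O and pipeline orchestration."""


class MutclockError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(MutclockError):
    """A table is malformed: missing columns, unparseable values."""


class LinkageError(MutclockError):
    """A mutation or segment references a sample absent from the metadata."""


class DataIntegrityError(MutclockError):
    """Internally inconsistent data, e.g. overlapping segments at one locus."""


class ConfigError(MutclockError):
    """Invalid or incomplete run configuration."""
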