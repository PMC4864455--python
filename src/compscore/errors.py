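"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`CompscoreError` so the CLI can map
failures to a stage-named exit status without catching bare exceptions.
"""


class CompscoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CompscoreError):
    """A simulation or run configuration violates its invariants.

    The message names the offending field.
    """


class InputError(CompscoreError):
    """Malformed input data (bad column, bad token, bad row)."""


class AssayInvalidError(CompscoreError):
    """The assay's internal controls fail, so scores are undefined.

    Raised e.g. when the wild-type-allele reference strain shows no growth
    (relative rates need a positive denominator) or when the GFP control grows
    as fast as the wild-type strain (no complementation signal window).
    """


class ModeInapplicableError(CompscoreError):
    """Reversed-mode scoring requested for a gene with no faster-than-wild-type
    variants."""


class DegenerateSetError(CompscoreError):
    """A reference set or score/label vector has an empty class."""
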