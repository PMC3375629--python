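"""Exception types shared across the package."""


class ModrpError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ModrpError):
    """An input table is missing required columns or contains malformed rows."""


class MergeError(ModrpError):
    """Studies and annotation share no SNPs, or merge preconditions fail."""


class ConstraintError(ModrpError):
    """A MAF bin cannot yield a valid iteration under the LD constraint.

    Raised when the rejection sampler exceeds its per-draw rejection budget,
    which signals a bin that is too small or too physically clustered for the
    configured LD distance.
    """
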