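"""Exception hierarchy shared across the package."""


class CCVError(Exception):
    """Base class for package errors."""


class FormatError(CCVError):
    """A file does not match the expected dialect (missing columns, bad header)."""


class IntegrityError(CCVError):
    """Parsed content violates a data invariant (duplicates, negative values)."""


class ShapeError(CCVError):
    """A vector or matrix has an unexpected dimension."""


class ParameterError(CCVError, ValueError):
    """A user-supplied parameter is outside its allowed range."""


class EmptySampleError(CCVError):
    """A sample has no qualifying MS/MS peaks; averaging is undefined."""


class MassAssignmentError(CCVError):
    """A precursor m/z falls outside every mass-group bin."""


class NoInformativeFeaturesError(CCVError):
    """Every column is uniform; nothing is left after filtering."""


class ZeroVarianceError(CCVError):
    """Within-cluster variance is zero; a ratio index is undefined."""


class FoldError(CCVError):
    """Cross-validation folds cannot be constructed for the given labels."""


class ConfigError(CCVError):
    """A configuration value is invalid or inconsistent."""
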