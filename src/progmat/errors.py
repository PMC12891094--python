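"""Exception hierarchy.

Every error raised by this package derives from :class:`ProgmatError` so
callers can catch generation failures with a single ``except`` clause while
still being able to discriminate the failure mode.
"""


class ProgmatError(Exception):
    """Base class for all package errors."""


class RegistryError(ProgmatError, KeyError):
    """Unknown primitive or rule name."""


class ValidationError(ProgmatError, ValueError):
    """A value violates a structural invariant (field range, bad override, ...)."""


class FeasibilityError(ProgmatError):
    """A rule or manipulation cannot be applied to a figure (missing tag)."""


class ArityError(ProgmatError):
    """Wrong number of figures/constituents for an operation."""


class RuleRangeError(ProgmatError):
    """Step index ``n`` outside the admissible range of a rule."""


class UnsupportedRuleError(ProgmatError):
    """A rule variant that is deliberately not available (e.g. reverse shade)."""


class RuleCombinationError(ProgmatError):
    """A logical rule combined with a visuospatial rule in one call."""


class MatrixDimensionError(ProgmatError):
    """Matrix size incompatible with the requested operation."""


class RuleConflictError(ProgmatError):
    """Two logical rules applied concurrently with conflicting direction."""


class SelectionError(ProgmatError, KeyError):
    """Unknown response-option name in a rendering subset."""


class ConfigError(ProgmatError):
    """Malformed or unsatisfiable configuration."""
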