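"""Exception hierarchy for map/coverage I-O and validation."""


class MapGapError(Exception):
    """Base class for all package errors."""


class FormatError(MapGapError):
    """A file fails to parse: missing column, unrecognized cell token, bad header."""


class IntegrityError(MapGapError):
    """Cross-references are inconsistent: unknown node ids, duplicate rows."""


class ValidationError(MapGapError):
    """A domain invariant is violated: empty level set, unknown level name."""


class ConfigurationError(MapGapError):
    """A generator or matcher configuration is infeasible."""
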