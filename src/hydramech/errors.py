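"""Exception types shared across the pipeline."""


class HydramechError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HydramechError):
    """A source container is missing a required field or has the wrong layout."""


class IntegrityError(HydramechError):
    """Lengths or values inside a container are mutually inconsistent."""


class DegenerateInputError(HydramechError, ValueError):
    """An input is formally valid but carries no usable signal (e.g. empty mask)."""


class UndefinedStatisticError(HydramechError, ValueError):
    """A statistic is requested on an empty sample (e.g. zero trials)."""


class CannotInferError(HydramechError, ValueError):
    """Frame rate cannot be inferred and no fallback was supplied."""
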