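"""Exception hierarchy shared across analysis stages."""


class CohesionError(Exception):
    """Base class for all package errors."""


class DomainError(CohesionError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UnsupportedRegimeError(CohesionError, ValueError):
    """Parameters fall outside the regime a closed form is valid for.

    The analytic population model assumes a single replication round per
    cycle and cohesion resolved before division; anything else must go
    through the numeric simulator instead.
    """


class DataError(CohesionError, ValueError):
    """Malformed or insufficient input data."""
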