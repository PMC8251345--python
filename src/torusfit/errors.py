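"""Exception hierarchy.

All argument/contract violations raise subclasses of :class:`TorusFitError`
so callers can catch pipeline failures in one clause; the classes also
subclass ``ValueError`` where the failure is an invalid input.
"""


class TorusFitError(Exception):
    """Base class for all torusfit errors."""


class InvalidArgumentError(TorusFitError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDataError(TorusFitError, ValueError):
    """Input data are malformed (missing errors, non-positive sigma, ...)."""


class ShapeMismatchError(TorusFitError, ValueError):
    """Two objects that must be congruent (same bead count / grid) are not."""


class DegenerateGeometryError(TorusFitError, ValueError):
    """A geometric operation is ill-posed (too few points, rank deficiency)."""


class GrowthFailureError(TorusFitError, RuntimeError):
    """Self-avoiding tail growth exhausted its restart budget."""

    def __init__(self, chain_id: str, conformer: int, attempts: int):
        self.chain_id = chain_id
        self.conformer = conformer
        self.attempts = attempts
        super().__init__(
            f"tail growth failed for chain {chain_id!r} in conformer "
            f"{conformer} after {attempts} restarts"
        )


class NoGuinierRegionError(TorusFitError, RuntimeError):
    """No low-q window with a negative Guinier slope could be found."""


class MethodInapplicableError(TorusFitError, RuntimeError):
    """A molecular-weight estimator's applicability condition failed."""


class NoConsistentSeriesError(TorusFitError, RuntimeError):
    """Charge-state deconvolution found no self-consistent peak series."""
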