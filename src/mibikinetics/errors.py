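"""Exception hierarchy shared across the package.

Plain input-validation problems raise :class:`ValueError`; the classes here
mark conditions that carry scientific meaning and that the CLI maps onto
dedicated exit codes.
"""


class MibiKineticsError(Exception):
    """Base class for domain-specific errors."""


class DegenerateDataError(MibiKineticsError):
    """Raised when data carry no usable signal.

    Examples: non-positive tumor-over-background contrast at the early time
    point (the washout coefficient is undefined), an all-zero observation set,
    or a zero area under the curve in a clearance computation.
    """


class IdentifiabilityError(MibiKineticsError):
    """Raised when the requested free parameters cannot be separated by the
    available observations (e.g. freeing all five transport rates against a
    single-compartment curve)."""


class RegimeViolationError(MibiKineticsError):
    """Raised by the optional tumor-imaging regime check when a parameter set
    does not satisfy beta_xz < beta_yz (retentive tumor cells) and
    beta_zy < beta_zx (weak normal-cell uptake)."""
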