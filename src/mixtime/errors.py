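"""Exception hierarchy shared across the library."""


class MixtimeError(Exception):
    """Base class for all library errors."""


class InvalidStateError(MixtimeError):
    """A state object violates its structural invariants."""


class UnsupportedInstanceError(MixtimeError):
    """The chain cannot be run on this instance (e.g. no perfect matching)."""


class NotRealizableError(UnsupportedInstanceError):
    """A degree-sequence pair has no bipartite realization."""


class CapacityError(MixtimeError):
    """A state-count or iteration cap was exceeded."""


class NonErgodicError(MixtimeError):
    """The chain is not ergodic (disconnected, periodic, or non-reversible)."""


class NonReversibleError(NonErgodicError):
    """Detailed balance fails beyond tolerance."""

    def __init__(self, residual: float):
        self.residual = residual
        super().__init__(
            f"detailed balance violated: max |pi_i P_ij - pi_j P_ji| = {residual:.3e}"
        )
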