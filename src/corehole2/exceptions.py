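"""Exception hierarchy.

Every error raised by the library derives from :class:`CoreholeError`, so
callers (in particular the CLI) can attach stage context and exit cleanly.
"""


class CoreholeError(Exception):
    """Base class for all library errors."""


class BackendUnavailableError(CoreholeError):
    """A named SCF backend is not registered or its engine is not importable."""


class ScfNotConvergedError(CoreholeError):
    """The external SCF engine reported non-convergence."""


class BundleFormatError(CoreholeError):
    """A reference bundle is malformed, truncated, or internally inconsistent."""


class ShapeMismatchError(CoreholeError):
    """Array shapes disagree with the declared orbital partition sizes."""


class PartitionError(CoreholeError):
    """An orbital-partition selector is invalid or violates CVS ordering."""


class ScalingRegistryError(CoreholeError):
    """A spin-scaling method tag or double-hybrid name is not registered."""


class SingularDenominatorError(CoreholeError):
    """A doubles denominator fell below the guard threshold.

    Carries the offending (core, inactive, virtual) index triple.
    """

    def __init__(self, message, triple=None):
        super().__init__(message)
        self.triple = triple


class ConvergenceError(CoreholeError):
    """The self-consistent eigenvalue iteration did not converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
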