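"""Exception types shared across the package."""


class SpecDCMError(Exception):
    """Base class for package errors."""


class UnstableModelError(SpecDCMError):
    """The neural-mass system has eigenvalues with non-negative real part."""


class SpectralSolveError(SpecDCMError):
    """A frequency-domain solve failed (singular transfer matrix)."""

    def __init__(self, freq_hz: float, msg: str | None = None):
        self.freq_hz = freq_hz
        super().__init__(msg or f"singular transfer-function solve at {freq_hz:g} Hz")


class SubjectExcludedError(SpecDCMError):
    """A subject failed an inclusion rule (e.g. too few clean epochs)."""


class ConvergenceError(SpecDCMError):
    """An iterative scheme failed to converge within its budget."""
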