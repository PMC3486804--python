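"""Exception hierarchy.

Input-format problems and numerical problems are kept on separate branches
so callers (and the CLI) can map them to distinct exit codes.
"""


class HSPKernelError(Exception):
    """Base class for all package errors."""


class InputError(HSPKernelError):
    """A problem with user-supplied data or configuration."""


class CorpusFormatError(InputError):
    """Malformed corpus XML."""


class DanglingReferenceError(CorpusFormatError):
    """A pair element references an entity id that does not exist."""


class OffsetMismatchError(CorpusFormatError):
    """Entity text does not match the sentence substring at its offsets."""


class ParseFormatError(InputError):
    """Malformed dependency-parse table."""


class GraphValidationError(InputError):
    """A sentence graph violates its structural invariants."""


class VocabularyOverflowError(InputError):
    """The label vocabulary exceeded the capacity of the bit width D."""


class NumericalError(HSPKernelError):
    """A numerical failure during kernel computation."""


class DivergenceError(NumericalError):
    """The Neumann walk series diverges: spectral_radius(gamma * A) >= 1."""

    def __init__(self, radius: float, gamma: float):
        self.radius = radius
        self.gamma = gamma
        super().__init__(
            f"walk series diverges: gamma * spectral_radius(A) = "
            f"{gamma * radius:.6g} >= 1 (rho(A)={radius:.6g}, gamma={gamma})"
        )
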