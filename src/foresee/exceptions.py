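"""Exception hierarchy shared across the package.

Two broad classes matter to callers (and set the CLI exit codes):
malformed *data* (`InputError`, exit 2) versus violated protocol
*preconditions* (`ParameterError`, exit 3).
"""


class ForeseeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(ForeseeError):
    """Malformed or out-of-range input data."""

    exit_code = 2


class ParameterError(ForeseeError):
    """A protocol parameter violates a mathematical precondition."""

    exit_code = 3


class ModulusTooSmallError(ParameterError):
    """The ciphertext modulus is too small for injective decoding.

    Raised when building a fraction lookup table detects two distinct
    irreducible fractions mapping to the same residue, i.e. the
    one-to-one-mapping precondition p > m_max * w_max is violated.
    """


class IncompatibleCipherError(ParameterError):
    """Binary ciphertext operation on mismatched moduli or slot counts."""
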