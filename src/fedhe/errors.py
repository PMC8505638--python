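"""Exception hierarchy shared by all fedhe modules.

Error classes mirror the failure modes of a multiparty-HE deployment:
configuration problems, ciphertext packing limits, depth-budget
exhaustion, access-control violations, and protocol-level bugs
(key mismatches, missing contributions, schema drift across sites).
"""


class FedheError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedheError):
    """Invalid crypto/topology/pipeline configuration."""


class PackingError(FedheError):
    """Vector does not fit the ciphertext slot count; caller must split."""


class DepthError(FedheError):
    """Multiplicative depth budget exhausted; a collective refresh is required."""


class AccessControlError(FedheError):
    """Decryption/refresh/key-switch attempted without the required key material."""


class ProtocolError(FedheError):
    """Pipeline-level invariant violated (key mismatch, missing DP contribution)."""


class ValidationError(FedheError):
    """Input data failed schema or consistency validation."""


class NumericalError(FedheError):
    """Numerical consistency check failed (e.g. negative residual sum of squares)."""
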