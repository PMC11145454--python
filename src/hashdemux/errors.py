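"""Exception hierarchy shared across the package."""


class HashdemuxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HashdemuxError):
    """Input data violates a container invariant (negative counts, duplicate barcodes, ...)."""


class SchemaError(HashdemuxError):
    """A table is missing a mandatory column or a hashtag is missing from a cutoff set."""


class JoinError(HashdemuxError):
    """Two per-cell tables share no barcodes, so they cannot be reconciled."""


class DegenerateFitError(HashdemuxError):
    """Two-component mixture fit collapsed (vanishing component weight or variance).

    Carries the single-Gaussian fallback parameters so callers can still
    place a conservative cutoff.
    """

    def __init__(self, message: str, mu: float, sigma: float):
        super().__init__(message)
        self.mu = float(mu)
        self.sigma = float(sigma)
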