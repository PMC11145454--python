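"""Per-hashtag normalization of raw UMI counts.

Two transforms are offered, both taken column-wise (one hashtag's counts
across all cells form the vector being normalized):

* **CLR** (centered log-ratio): ``log((w_i + p) / g(w + p))`` where ``g`` is
  the geometric mean of the hashtag's (pseudocounted) vector. The CLR of a
  vector sums to zero by construction.
* **log**: ``log1p(w_i) = log(w_i + 1)``, element-wise.

Natural logarithms throughout. Raw count matrices routinely contain zeros,
for which the CLR geometric mean is undefined, so a pseudocount (default 1)
is added first; it is recorded on the output so downstream defaults can see
it. Both transforms are strictly increasing in the raw count, so rank order
within a hashtag is preserved.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix, NormalizedMatrix
from .errors import ValidationError


def clr_normalize(counts: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio transform, computed per hashtag across cells.

    Parameters
    ----------
    counts
        Raw UMI counts.
    pseudocount
        Non-negative offset added to every count before the transform.
        With ``pseudocount=0`` every count must be strictly positive.

    Raises
    ------
    ValidationError
        If ``pseudocount < 0``, or ``pseudocount == 0`` while some count is
        zero (the geometric mean would vanish and the log diverge).
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    w = counts.counts.astype(float) + pseudocount
    if pseudocount == 0 and (counts.counts == 0).any():
        raise ValidationError(
            "CLR with pseudocount=0 requires strictly positive counts: "
            "the geometric mean of a vector containing 0 is 0 and log(w/0) "
            "is undefined; use a positive pseudocount"
        )
    logw = np.log(w)
    # log(w_i / g(w)) == log(w_i) - mean(log(w)) per hashtag column
    values = logw - logw.mean(axis=0, keepdims=True)
    return NormalizedMatrix(
        values=values,
        barcodes=counts.barcodes,
        hashtag_names=counts.hashtag_names,
        method="clr",
        pseudocount=float(pseudocount),
    )


def log_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Element-wise ``log(w + 1)``; zero counts map to exactly zero."""
    values = np.log1p(counts.counts.astype(float))
    return NormalizedMatrix(
        values=values,
        barcodes=counts.barcodes,
        hashtag_names=counts.hashtag_names,
        method="log",
        pseudocount=0.0,
    )


def normalize(
    counts: CountMatrix, method: str = "clr", pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Dispatch to :func:`clr_normalize` or :func:`log_normalize` by name."""
    if method == "clr":
        return clr_normalize(counts, pseudocount=pseudocount)
    if method == "log":
        return log_normalize(counts)
    raise ValidationError(f"unknown normalization method {method!r}")
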