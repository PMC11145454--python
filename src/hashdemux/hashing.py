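"""Per-cell label assignment from per-hashtag positivity.

A cell positive for exactly one hashtag is a singlet of that sample; a cell
positive for several hashtags is a ``Doublet``; a cell positive for none is
``Negative``. A signal exactly equal to its hashtag's cutoff counts as
positive (the boundary is inclusive and tests pin that convention).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import DOUBLET, NEGATIVE, CountMatrix, HashingAssignment, NormalizedMatrix
from .errors import SchemaError, ValidationError
from .normalization import normalize
from .signal_model import CutoffSet, call_cutoffs


def call_positives(norm: NormalizedMatrix, cutoffs: CutoffSet) -> np.ndarray:
    """Boolean cells x hashtags matrix: signal at or above that hashtag's cutoff."""
    missing = [h for h in norm.hashtag_names if h not in cutoffs]
    if missing:
        raise SchemaError(f"no cutoff for hashtags: {missing}")
    thresholds = np.array([cutoffs[h].cutoff for h in norm.hashtag_names])
    return norm.values >= thresholds[None, :]


def assign_hashing_labels(
    positives: np.ndarray,
    hashtag_names: Sequence[str],
    barcodes: Sequence[str],
) -> HashingAssignment:
    """Collapse the positivity matrix into one label per cell."""
    positives = np.asarray(positives, dtype=bool)
    if positives.ndim != 2 or positives.shape[1] != len(hashtag_names):
        raise ValidationError("positivity matrix shape does not match hashtag names")
    if positives.shape[0] != len(barcodes):
        raise ValidationError("positivity matrix shape does not match barcodes")
    n_pos = positives.sum(axis=1)
    labels = []
    names = list(hashtag_names)
    for i, k in enumerate(n_pos):
        if k == 0:
            labels.append(NEGATIVE)
        elif k == 1:
            labels.append(names[int(np.flatnonzero(positives[i])[0])])
        else:
            labels.append(DOUBLET)
    return HashingAssignment(
        barcodes=tuple(barcodes), labels=tuple(labels), n_positive=tuple(int(k) for k in n_pos)
    )


def doublet_detail(positives: np.ndarray, hashtag_names: Sequence[str]) -> list[str]:
    """Slash-joined contributing hashtags per cell (e.g. ``"H1/H2"`` for a doublet)."""
    names = np.asarray(list(hashtag_names), dtype=object)
    return ["/".join(names[row]) for row in np.asarray(positives, dtype=bool)]


def singlet_rate(assign: HashingAssignment) -> float:
    """Fraction of cells called as singlets."""
    if len(assign) == 0:
        raise ValidationError("empty assignment")
    return assign.n_singlet / len(assign)


def demultiplex(
    counts: CountMatrix,
    method: str = "clr",
    pseudocount: float = 1.0,
    rank: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[HashingAssignment, CutoffSet, NormalizedMatrix]:
    """Full hashing-only pipeline: normalize, call cutoffs, label cells."""
    norm = normalize(counts, method=method, pseudocount=pseudocount)
    cutoffs = call_cutoffs(norm, rank=rank, seed=seed, **fit_kwargs)
    positives = call_positives(norm, cutoffs)
    assignment = assign_hashing_labels(positives, norm.hashtag_names, norm.barcodes)
    return assignment, cutoffs, norm
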