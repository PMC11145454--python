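"""Core in-memory containers for hashing and genotype demultiplexing data.

All containers are thin, validated wrappers around numpy arrays and python
lists. Barcode and hashtag order is always preserved exactly as given; no
container ever sorts or deduplicates silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Reserved non-singlet labels on the hashing side.
DOUBLET = "Doublet"
NEGATIVE = "Negative"
#: Reserved labels on the genotype side / in final hybrid output.
UNASSIGNED = "Unassigned"

GENO_SINGLET = "singlet"
GENO_DOUBLET = "doublet"
GENO_UNASSIGNED = "unassigned"
_GENO_STATUSES = (GENO_SINGLET, GENO_DOUBLET, GENO_UNASSIGNED)


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        dupes = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Raw UMI counts, cells x hashtags.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per cell barcode and one
        column per hashtag.
    barcodes
        Unique cell identifiers, in row order.
    hashtag_names
        Unique hashtag identifiers, in column order.
    """

    counts: np.ndarray
    barcodes: tuple[str, ...]
    hashtag_names: tuple[str, ...]

    def __init__(self, counts, barcodes, hashtag_names):
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {arr.shape}")
        if arr.size and (np.issubdtype(arr.dtype, np.floating) or arr.dtype == object):
            farr = arr.astype(float)
            if np.isnan(farr).any():
                raise ValidationError("counts contain NaN")
            if not np.allclose(farr, np.round(farr)):
                raise ValidationError("counts must be integral")
            arr = farr
        arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise ValidationError("counts must be non-negative")
        barcodes = tuple(str(b) for b in barcodes)
        hashtag_names = tuple(str(h) for h in hashtag_names)
        if len(barcodes) != arr.shape[0]:
            raise ValidationError(
                f"{len(barcodes)} barcodes for {arr.shape[0]} rows"
            )
        if len(hashtag_names) != arr.shape[1]:
            raise ValidationError(
                f"{len(hashtag_names)} hashtag names for {arr.shape[1]} columns"
            )
        _check_unique(barcodes, "barcodes")
        _check_unique(hashtag_names, "hashtag names")
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "barcodes", barcodes)
        object.__setattr__(self, "hashtag_names", hashtag_names)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_hashtags(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.barcodes), columns=list(self.hashtag_names)
        )


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized hashtag signal, same shape and ordering as the source counts.

    ``method`` records which transform produced the values ("clr" or "log")
    and ``pseudocount`` the offset added before the CLR geometric mean, so
    downstream defaults (empirical floors) can be chosen automatically.
    """

    values: np.ndarray
    barcodes: tuple[str, ...]
    hashtag_names: tuple[str, ...]
    method: str
    pseudocount: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("normalized values must be 2-D")
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("normalized values must be finite")
        if self.method not in ("clr", "log"):
            raise ValidationError(f"unknown normalization method {self.method!r}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        object.__setattr__(self, "hashtag_names", tuple(self.hashtag_names))

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_hashtags(self) -> int:
        return self.values.shape[1]

    def column(self, hashtag: str) -> np.ndarray:
        return self.values[:, self.hashtag_names.index(hashtag)]


@dataclass(frozen=True)
class LabelTable:
    """A per-cell label column keyed by barcode (ground truth or predictions)."""

    barcodes: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        barcodes = tuple(str(b) for b in self.barcodes)
        labels = tuple(str(x) for x in self.labels)
        if len(barcodes) != len(labels):
            raise ValidationError("one label per barcode required")
        _check_unique(barcodes, "barcodes")
        object.__setattr__(self, "barcodes", barcodes)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.barcodes)

    def to_series(self) -> pd.Series:
        return pd.Series(list(self.labels), index=list(self.barcodes), name="label")


@dataclass(frozen=True)
class HashingAssignment:
    """Per-cell hashing call: a hashtag name, ``Doublet`` or ``Negative``.

    ``n_positive`` is the number of hashtags whose normalized signal met
    that hashtag's cutoff; it fully determines the label class.
    """

    barcodes: tuple[str, ...]
    labels: tuple[str, ...]
    n_positive: tuple[int, ...]

    def __post_init__(self):
        barcodes = tuple(str(b) for b in self.barcodes)
        labels = tuple(str(x) for x in self.labels)
        npos = tuple(int(k) for k in self.n_positive)
        if not (len(barcodes) == len(labels) == len(npos)):
            raise ValidationError("barcodes, labels and n_positive must align")
        _check_unique(barcodes, "barcodes")
        for lab, k in zip(labels, npos):
            if k == 0 and lab != NEGATIVE:
                raise ValidationError(f"0 positives must be {NEGATIVE}, got {lab!r}")
            if k == 1 and lab in (NEGATIVE, DOUBLET):
                raise ValidationError("1 positive must carry a hashtag name")
            if k >= 2 and lab != DOUBLET:
                raise ValidationError(f">=2 positives must be {DOUBLET}, got {lab!r}")
        object.__setattr__(self, "barcodes", barcodes)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "n_positive", npos)

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def n_singlet(self) -> int:
        return sum(k == 1 for k in self.n_positive)

    @property
    def n_doublet(self) -> int:
        return sum(k >= 2 for k in self.n_positive)

    @property
    def n_negative(self) -> int:
        return sum(k == 0 for k in self.n_positive)

    def to_label_table(self) -> LabelTable:
        return LabelTable(self.barcodes, self.labels)


@dataclass(frozen=True)
class GenotypeAssignment:
    """Per-cell SNP-cluster call in the souporcell idiom.

    ``status`` is one of ``singlet``/``doublet``/``unassigned``; ``cluster``
    holds the cluster identifier for singlets and ``None`` otherwise.
    """

    barcodes: tuple[str, ...]
    status: tuple[str, ...]
    cluster: tuple[str | None, ...]

    def __post_init__(self):
        barcodes = tuple(str(b) for b in self.barcodes)
        status = tuple(str(s) for s in self.status)
        cluster = tuple(None if c is None else str(c) for c in self.cluster)
        if not (len(barcodes) == len(status) == len(cluster)):
            raise ValidationError("barcodes, status and cluster must align")
        _check_unique(barcodes, "barcodes")
        for s, c in zip(status, cluster):
            if s not in _GENO_STATUSES:
                raise ValidationError(f"unknown genotype status {s!r}")
            if (s == GENO_SINGLET) != (c is not None):
                raise ValidationError("cluster must be present iff status is singlet")
        object.__setattr__(self, "barcodes", barcodes)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "cluster", cluster)

    def __len__(self) -> int:
        return len(self.barcodes)

    def labels(self) -> tuple[str, ...]:
        """Collapse status+cluster into one label per cell.

        Singlets yield their cluster id; doublets ``Doublet``; unassigned
        cells ``Unassigned``.
        """
        out = []
        for s, c in zip(self.status, self.cluster):
            if s == GENO_SINGLET:
                out.append(c)
            elif s == GENO_DOUBLET:
                out.append(DOUBLET)
            else:
                out.append(UNASSIGNED)
        return tuple(out)

    def to_label_table(self) -> LabelTable:
        return LabelTable(self.barcodes, self.labels())


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of hashing labels (rows) against genotype labels (columns).

    Rows span hashtag names plus ``Doublet``/``Negative``; columns span
    genotype cluster ids plus ``Doublet``/``Unassigned``. Entries count
    jointly observed cells.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.table)
        if df.size == 0:
            raise ValidationError("contingency table must be non-empty")
        arr = df.to_numpy()
        farr = arr.astype(float)
        if np.isnan(farr).any():
            raise ValidationError("contingency table contains NaN")
        if not np.allclose(farr, np.round(farr)):
            raise ValidationError("contingency counts must be integers")
        if farr.min() < 0:
            raise ValidationError("contingency counts must be non-negative")
        df = df.astype(np.int64)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        _check_unique(list(df.index), "row labels")
        _check_unique(list(df.columns), "column labels")
        object.__setattr__(self, "table", df)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def row_marginals(self) -> pd.Series:
        return self.table.sum(axis=1)

    def col_marginals(self) -> pd.Series:
        return self.table.sum(axis=0)

    def singlet_rows(self) -> list[str]:
        return [r for r in self.table.index if r not in (DOUBLET, NEGATIVE)]

    def singlet_cols(self) -> list[str]:
        return [c for c in self.table.columns if c not in (DOUBLET, UNASSIGNED)]

    def singlet_block(self) -> pd.DataFrame:
        """The hashing-singlet x genotype-singlet sub-table used for pairing."""
        return self.table.loc[self.singlet_rows(), self.singlet_cols()]
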