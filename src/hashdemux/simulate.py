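"""Synthetic cell-hashing experiments with a matched genotype channel.

The generator emulates the structure of a pooled hashing experiment: each
sample's cells draw their own hashtag's UMI count from a "positive"
lognormal and every other hashtag from a "background" lognormal, giving
each hashtag the bimodal count distribution that cutoff calling relies on.
Doublets are formed by summing the full count vectors of two cells from
distinct samples (physical co-encapsulation). The genotype channel reports
each cell's true sample cluster, corrupted by configurable doublet and
unassigned error rates. Optionally a fraction of cells is "unhashed"
(background-only hashtags, valid genotype) to emulate pooling unstained
cells alongside a stained aliquot, and one hashtag's positive signal can be
suppressed to emulate a staining failure.

Defaults describe a well-stained eight-sample pool of 5000 cells: balanced
sample sizes, ~12-UMI background vs ~400-UMI positive signal, 5% doublets,
5% genotype-doublet and 0.5% genotype-unassigned error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    GENO_DOUBLET,
    GENO_SINGLET,
    GENO_UNASSIGNED,
    ContingencyTable,
    CountMatrix,
    GenotypeAssignment,
    HashingAssignment,
    LabelTable,
    DOUBLET,
    NEGATIVE,
    UNASSIGNED,
)
from .errors import ValidationError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic hashing experiment.

    Lognormal parameters are on the natural-log scale of UMI counts.
    ``cells_per_sample`` allows imbalanced pools; ``staining_failure``
    optionally names a hashtag index and the multiplicative suppression of
    its positive-signal draws (e.g. ``(2, 0.05)``).
    """

    n_samples: int = 8
    cells_per_sample: tuple[int, ...] | None = None
    background_meanlog: float = 2.5
    background_sdlog: float = 0.6
    positive_meanlog: float = 6.0
    positive_sdlog: float = 0.5
    doublet_rate: float = 0.05
    staining_failure: tuple[int, float] | None = None
    geno_doublet_rate: float = 0.05
    geno_unassigned_rate: float = 0.005
    unhashed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be positive")
        cps = self.cells_per_sample
        if cps is None:
            cps = (625,) * self.n_samples
        cps = tuple(int(c) for c in cps)
        if len(cps) != self.n_samples:
            raise ValidationError("cells_per_sample length must equal n_samples")
        if any(c < 1 for c in cps):
            raise ValidationError("cells_per_sample entries must be positive")
        for r in (
            self.doublet_rate,
            self.geno_doublet_rate,
            self.geno_unassigned_rate,
            self.unhashed_fraction,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.doublet_rate + self.unhashed_fraction > 1.0:
            raise ValidationError("doublet_rate + unhashed_fraction must not exceed 1")
        if self.staining_failure is not None:
            idx, factor = self.staining_failure
            if not 0 <= int(idx) < self.n_samples:
                raise ValidationError("staining_failure hashtag index out of range")
            if factor < 0:
                raise ValidationError("staining_failure factor must be non-negative")
            object.__setattr__(self, "staining_failure", (int(idx), float(factor)))
        object.__setattr__(self, "cells_per_sample", cps)

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_samples))

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_sample))


def _draw_cell(rng: np.random.Generator, cfg: SimulationConfig, sample: int) -> np.ndarray:
    """One cell's hashtag count vector; ``sample < 0`` draws pure background."""
    n = cfg.n_samples
    counts = rng.lognormal(cfg.background_meanlog, cfg.background_sdlog, size=n)
    if sample >= 0:
        pos = rng.lognormal(cfg.positive_meanlog, cfg.positive_sdlog)
        if cfg.staining_failure is not None and sample == cfg.staining_failure[0]:
            pos *= cfg.staining_failure[1]
        counts[sample] = pos
    return np.round(counts)


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, LabelTable, GenotypeAssignment]:
    """Generate counts, ground-truth labels, and the genotype channel.

    Truth labels are the sample name for singlets (including unhashed
    cells, whose identity is real even though their hashtags are pure
    background) and ``Doublet`` for doublets. The genotype channel reports
    the true cluster (the sample index as a string) corrupted by the
    configured error rates. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_cells
    n_doublet = int(round(cfg.doublet_rate * n_total))
    n_unhashed = int(round(cfg.unhashed_fraction * n_total))
    n_singlet = n_total - n_doublet - n_unhashed

    p_sample = np.asarray(cfg.cells_per_sample, dtype=float)
    p_sample = p_sample / p_sample.sum()
    samples = rng.choice(cfg.n_samples, size=n_singlet, p=p_sample)
    unhashed_samples = rng.choice(cfg.n_samples, size=n_unhashed, p=p_sample)

    counts_rows: list[np.ndarray] = []
    truth: list[str] = []
    geno_truth: list[tuple[str, str | None]] = []  # (status, cluster)

    for s in samples:
        counts_rows.append(_draw_cell(rng, cfg, int(s)))
        truth.append(cfg.sample_names[int(s)])
        geno_truth.append((GENO_SINGLET, str(int(s))))
    for _ in range(n_doublet):
        a, b = rng.choice(cfg.n_samples, size=2, replace=False, p=p_sample)
        counts_rows.append(_draw_cell(rng, cfg, int(a)) + _draw_cell(rng, cfg, int(b)))
        truth.append(DOUBLET)
        geno_truth.append((GENO_DOUBLET, None))
    for s in unhashed_samples:
        counts_rows.append(_draw_cell(rng, cfg, -1))
        truth.append(cfg.sample_names[int(s)])
        geno_truth.append((GENO_SINGLET, str(int(s))))

    order = rng.permutation(n_total)
    counts = np.stack(counts_rows)[order]
    truth = [truth[i] for i in order]
    geno_truth = [geno_truth[i] for i in order]

    # genotype channel corruption
    u = rng.random(n_total)
    status: list[str] = []
    cluster: list[str | None] = []
    for i, (st, cl) in enumerate(geno_truth):
        if u[i] < cfg.geno_doublet_rate:
            status.append(GENO_DOUBLET)
            cluster.append(None)
        elif u[i] < cfg.geno_doublet_rate + cfg.geno_unassigned_rate:
            status.append(GENO_UNASSIGNED)
            cluster.append(None)
        else:
            status.append(st)
            cluster.append(cl)

    barcodes = tuple(f"cell-{i:06d}" for i in range(n_total))
    cm = CountMatrix(counts, barcodes, cfg.sample_names)
    truth_table = LabelTable(barcodes, tuple(truth))
    geno = GenotypeAssignment(barcodes, tuple(status), tuple(cluster))
    return cm, truth_table, geno


def expand_contingency_to_cells(
    tab: ContingencyTable,
) -> tuple[HashingAssignment, GenotypeAssignment]:
    """Materialize one synthetic barcode per counted cell of a contingency table.

    Each entry ``(row, col)`` with count ``k`` produces ``k`` cells whose
    hashing label is the row and whose genotype label is the column;
    re-tabulating the result reproduces the table exactly.
    """
    barcodes: list[str] = []
    h_labels: list[str] = []
    n_pos: list[int] = []
    status: list[str] = []
    cluster: list[str | None] = []
    i = 0
    for row in tab.table.index:
        for col in tab.table.columns:
            k = int(tab.table.at[row, col])
            for _ in range(k):
                barcodes.append(f"cell-{i:06d}")
                i += 1
                h_labels.append(str(row))
                if row == DOUBLET:
                    n_pos.append(2)
                elif row == NEGATIVE:
                    n_pos.append(0)
                else:
                    n_pos.append(1)
                if col == DOUBLET:
                    status.append(GENO_DOUBLET)
                    cluster.append(None)
                elif col == UNASSIGNED:
                    status.append(GENO_UNASSIGNED)
                    cluster.append(None)
                else:
                    status.append(GENO_SINGLET)
                    cluster.append(str(col))
    hashing = HashingAssignment(tuple(barcodes), tuple(h_labels), tuple(n_pos))
    geno = GenotypeAssignment(tuple(barcodes), tuple(status), tuple(cluster))
    return hashing, geno
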