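"""Reconcile hashing calls with SNP-cluster assignments.

SNP-based demultiplexing groups cells by genotype but cannot name the donor
behind each cluster; hashing names donors but suffers staining failures and
false doublets. The hybrid strategy joins the two per-cell tables, pairs
each genotype singlet cluster with the hashing singlet group it shares the
most cells with, scores the agreement, and resolves every cell's final
label:

* **convergence score** ``C = N1 / (N1 + N2)`` over cells called singlet by
  both methods, where ``N1`` counts cells whose hashing label matches the
  paired label of their genotype cluster and ``N2`` the rest. A score below
  the quality threshold (default 0.7) signals a problem (e.g. a high true
  doublet rate corrupting the SNP clustering) and the pipeline falls back
  to the hashing labels with a warning.
* **case 1**: hashing ``Doublet``/``Negative`` but genotype singlet — the
  cell is rescued with its genotype cluster's paired sample label (false
  doublets from tag spill-over, false negatives from staining failure).
* **case 2**: hashing singlet but genotype doublet/unassigned — final label
  ``Unassigned``.
* **case 3**: singlet by both but the identities disagree — ``Unassigned``.

Cells present in only one input are labeled from that side alone (a
genotype singlet still receives its cluster's paired sample label, which is
what makes hashing a small aliquot of each sample sufficient); they carry
the ``genotype_only``/``hashing_only`` case tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DOUBLET,
    GENO_SINGLET,
    NEGATIVE,
    UNASSIGNED,
    ContingencyTable,
    GenotypeAssignment,
    HashingAssignment,
)
from .errors import JoinError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7

CASE_CONSISTENT = "consistent"
CASE_1 = "case1"
CASE_2 = "case2"
CASE_3 = "case3"
CASE_FALLBACK = "fallback"
CASE_GENOTYPE_ONLY = "genotype_only"
CASE_HASHING_ONLY = "hashing_only"


@dataclass(frozen=True)
class PairingMap:
    """Genotype cluster id -> hashing sample label, with match diagnostics.

    ``conflicts`` lists clusters whose highest-overlap hashing group had
    already been claimed by a larger overlap; ``unmatched`` lists clusters
    left without a hashing group (more clusters than groups, e.g. one
    deliberately unlabeled sample).
    """

    mapping: dict[str, str] = field(default_factory=dict)
    conflicts: tuple[str, ...] = ()
    unmatched: tuple[str, ...] = ()

    def __getitem__(self, cluster: str) -> str:
        return self.mapping[cluster]

    def __contains__(self, cluster: str) -> bool:
        return cluster in self.mapping

    def get(self, cluster: str, default=None):
        return self.mapping.get(cluster, default)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_cluster": list(self.mapping),
                "sample_label": [self.mapping[g] for g in self.mapping],
                "conflict": [g in self.conflicts for g in self.mapping],
            }
        )


@dataclass(frozen=True)
class HybridResult:
    """Per-cell final labels with the agreement diagnostics that produced them."""

    barcodes: tuple[str, ...]
    final_labels: tuple[str, ...]
    hashing_labels: tuple[str | None, ...]
    genotype_labels: tuple[str | None, ...]
    cases: tuple[str, ...]
    convergence: float
    n1: int
    n2: int
    threshold: float
    pairing: PairingMap

    @property
    def quality_ok(self) -> bool:
        return self.convergence >= self.threshold

    def __len__(self) -> int:
        return len(self.barcodes)

    def case_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cases:
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": list(self.barcodes),
                "label": list(self.final_labels),
                "hashing_label": ["" if x is None else x for x in self.hashing_labels],
                "genotype_label": ["" if x is None else x for x in self.genotype_labels],
                "case": list(self.cases),
            }
        )


def build_contingency(
    hashing: HashingAssignment, geno: GenotypeAssignment
) -> ContingencyTable:
    """Cross-tabulate hashing labels against genotype labels on the barcode join.

    Cells present in only one of the two inputs are dropped (their count is
    logged); an empty intersection is an error.
    """
    h = pd.Series(list(hashing.labels), index=list(hashing.barcodes))
    g = pd.Series(list(geno.labels()), index=list(geno.barcodes))
    common = h.index.intersection(g.index)
    if len(common) == 0:
        raise JoinError("hashing and genotype tables share no barcodes")
    dropped = (len(h) - len(common)) + (len(g) - len(common))
    if dropped:
        logger.info("dropping %d cells present in only one input", dropped)
    tab = pd.crosstab(h.loc[common], g.loc[common])
    tab.index.name = None
    tab.columns.name = None
    return ContingencyTable(tab)


def pair_clusters(tab: ContingencyTable) -> PairingMap:
    """Pair each genotype singlet cluster with its highest-overlap hashing group.

    Greedy one-to-one matching over the singlet x singlet block in
    descending shared-cell order (ties broken lexicographically by cluster
    then hashing label), each hashing group claimed at most once. A cluster
    that ends up matched to a group other than its global best is
    conflict-flagged; clusters left over when hashing groups run out are
    reported unmatched.
    """
    block = tab.singlet_block()
    if block.shape[0] == 0 or block.shape[1] == 0:
        raise ValidationError(
            "pairing requires at least one hashing singlet group and one "
            "genotype singlet cluster"
        )
    pairs = [
        (int(block.at[row, col]), str(col), str(row))
        for row in block.index
        for col in block.columns
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[str, str] = {}
    used_groups: set[str] = set()
    for count, cluster, group in pairs:
        if cluster in mapping or group in used_groups:
            continue
        mapping[cluster] = group
        used_groups.add(group)
    best = block.idxmax(axis=0)  # global argmax hashing group per cluster
    conflicts = tuple(
        g for g in sorted(mapping) if mapping[g] != str(best[g])
    )
    unmatched = tuple(str(c) for c in block.columns if str(c) not in mapping)
    if unmatched:
        logger.warning("genotype clusters left unmatched: %s", list(unmatched))
    return PairingMap(mapping=mapping, conflicts=conflicts, unmatched=unmatched)


def convergence_score(
    tab: ContingencyTable, pairing: PairingMap
) -> tuple[float, int, int]:
    """Agreement over cells called singlet by both methods.

    ``N1`` counts both-singlet cells whose hashing label equals the paired
    label of their genotype cluster, ``N2`` the remaining both-singlet
    cells; ``C = N1/(N1+N2)``. With no both-singlet cells ``C`` is defined
    as 1 and a warning is logged.
    """
    block = tab.singlet_block()
    total = int(block.to_numpy().sum())
    n1 = 0
    for cluster in block.columns:
        group = pairing.get(str(cluster))
        if group is not None and group in block.index:
            n1 += int(block.at[group, cluster])
    n2 = total - n1
    if total == 0:
        logger.warning("no cells are singlet by both methods; convergence set to 1")
        return 1.0, 0, 0
    return n1 / total, n1, n2


def assign_hybrid_labels(
    hashing: HashingAssignment,
    geno: GenotypeAssignment,
    pairing: PairingMap,
    convergence: float,
    n1: int = 0,
    n2: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> HybridResult:
    """Resolve every cell's final sample label.

    When ``convergence < threshold`` every cell keeps its hashing label
    (``fallback``) and a quality warning is logged. Otherwise cells are
    resolved per the module rules (consistent / case 1-3); cells present in
    only one input are labeled from that side. A genotype cluster missing
    from the pairing yields ``Unassigned`` with a warning.
    """
    h_labels = dict(zip(hashing.barcodes, hashing.labels))
    g_status = dict(zip(geno.barcodes, geno.status))
    g_cluster = dict(zip(geno.barcodes, geno.cluster))
    g_label = dict(zip(geno.barcodes, geno.labels()))

    barcodes = list(hashing.barcodes) + [
        b for b in geno.barcodes if b not in h_labels
    ]
    quality_ok = convergence >= threshold
    if not quality_ok:
        logger.warning(
            "convergence score %.3f below threshold %.2f: demultiplexing results "
            "may not be accurate; falling back to cell hashing labels",
            convergence,
            threshold,
        )

    missing_clusters: set[str] = set()
    finals: list[str] = []
    cases: list[str] = []
    for b in barcodes:
        h = h_labels.get(b)
        in_geno = b in g_status
        if not quality_ok:
            finals.append(h if h is not None else UNASSIGNED)
            cases.append(CASE_FALLBACK)
            continue
        if h is None:
            # genotype-only cell: label via the pairing when singlet
            if g_status[b] == GENO_SINGLET:
                group = pairing.get(g_cluster[b])
                if group is None:
                    missing_clusters.add(g_cluster[b])
                    finals.append(UNASSIGNED)
                else:
                    finals.append(group)
            elif g_label[b] == DOUBLET:
                finals.append(DOUBLET)
            else:
                finals.append(UNASSIGNED)
            cases.append(CASE_GENOTYPE_ONLY)
            continue
        if not in_geno:
            finals.append(h)
            cases.append(CASE_HASHING_ONLY)
            continue
        h_singlet = h not in (DOUBLET, NEGATIVE)
        g_singlet = g_status[b] == GENO_SINGLET
        if g_singlet:
            group = pairing.get(g_cluster[b])
            if group is None:
                missing_clusters.add(g_cluster[b])
            if h_singlet:
                if group is not None and group == h:
                    finals.append(h)
                    cases.append(CASE_CONSISTENT)
                else:
                    finals.append(UNASSIGNED)
                    cases.append(CASE_3)
            else:
                finals.append(group if group is not None else UNASSIGNED)
                cases.append(CASE_1)
        else:
            if h_singlet:
                finals.append(UNASSIGNED)
                cases.append(CASE_2)
            else:
                finals.append(h)
                cases.append(CASE_CONSISTENT)
    if missing_clusters:
        logger.warning(
            "genotype clusters absent from the pairing, cells set to %s: %s",
            UNASSIGNED,
            sorted(missing_clusters),
        )
    return HybridResult(
        barcodes=tuple(barcodes),
        final_labels=tuple(finals),
        hashing_labels=tuple(h_labels.get(b) for b in barcodes),
        genotype_labels=tuple(g_label.get(b) for b in barcodes),
        cases=tuple(cases),
        convergence=float(convergence),
        n1=int(n1),
        n2=int(n2),
        threshold=float(threshold),
        pairing=pairing,
    )


def integrate(
    hashing: HashingAssignment,
    geno: GenotypeAssignment,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[HybridResult, ContingencyTable]:
    """End-to-end hybrid resolution: tabulate, pair, score, assign."""
    tab = build_contingency(hashing, geno)
    pairing = pair_clusters(tab)
    c, n1, n2 = convergence_score(tab, pairing)
    result = assign_hybrid_labels(
        hashing, geno, pairing, c, n1=n1, n2=n2, threshold=threshold
    )
    return result, tab
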