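"""Bundled reference tables.

The package ships the published hashing-vs-SNP contingency table from an
eight-donor pooled PBMC experiment: a hashtagged carrier-cell fraction
("CA": sorted B and T cells, per-cell hashing labels crossed with
souporcell genotype clusters) and the genotype-side counts of the matching
unhashed antigen-specific fraction ("AS", demultiplexed by genotype alone).
These tables exercise the hybrid integrator end to end without any raw
sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import ContingencyTable


def _data_path(name: str):
    return resources.files("hashdemux.data").joinpath(name)


def load_eightpool_ca_contingency() -> ContingencyTable:
    """Hashing x genotype contingency for the hashtagged carrier fraction.

    Rows are hashing labels (eight donor samples plus ``Doublet`` and
    ``Negative``); columns are genotype labels (eight singlet clusters plus
    ``Doublet`` and ``Unassigned``); 12 884 cells in total.
    """
    with resources.as_file(_data_path("eightpool_ca_contingency.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    return ContingencyTable(df)


def load_eightpool_as_genotype_counts() -> pd.Series:
    """Genotype-label cell counts for the unhashed antigen-specific fraction."""
    with resources.as_file(_data_path("eightpool_as_genotype_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return pd.Series(df["cells"].to_numpy(), index=df["genotype_label"].tolist())
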