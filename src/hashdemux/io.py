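"""Readers and writers for every external table the tool touches.

Formats:

* hashtag counts: a 10x-style feature-barcode directory (MatrixMarket
  ``matrix.mtx`` plus ``barcodes.tsv`` and ``features.tsv``, each optionally
  gzipped, matrix stored features x cells) or a dense table (cells x
  hashtags; first column barcodes; comma or tab separation auto-detected
  from the header line);
* genotype assignments: souporcell ``clusters.tsv`` dialect (tab-separated,
  columns ``barcode``/``status``/``assignment`` at minimum; both
  ``unassigned`` and ``negative`` accepted as the unassigned status token);
* label tables, contingency tables and hybrid results: plain TSV.

Barcodes are opaque strings: nothing is stripped or reordered unless
``strip_suffix`` explicitly requests removing a trailing ``-1``-style
chemistry suffix. Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    GENO_SINGLET,
    ContingencyTable,
    CountMatrix,
    GenotypeAssignment,
    HashingAssignment,
    LabelTable,
)
from .errors import SchemaError, ValidationError
from .hybrid import HybridResult

_SUFFIX_RE = re.compile(r"-\d+$")


def _strip(barcodes, strip_suffix: bool):
    if not strip_suffix:
        return list(barcodes)
    return [_SUFFIX_RE.sub("", b) for b in barcodes]


def _find_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_hto_counts(
    path: str | Path, format: str = "auto", strip_suffix: bool = False
) -> CountMatrix:
    """Read a hashtag count matrix from an mtx directory or a dense table.

    ``format`` is ``"mtx_dir"``, ``"dense_table"`` or ``"auto"`` (a
    directory is treated as mtx, a file as a dense table).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format == "auto":
        format = "mtx_dir" if path.is_dir() else "dense_table"
    if format == "mtx_dir":
        return _read_mtx_dir(path, strip_suffix)
    if format == "dense_table":
        return _read_dense_table(path, strip_suffix)
    raise ValidationError(f"unknown counts format {format!r}")


def _read_mtx_dir(directory: Path, strip_suffix: bool) -> CountMatrix:
    mtx = _find_file(directory, "matrix.mtx")
    bc = _find_file(directory, "barcodes.tsv")
    feat = _find_file(directory, "features.tsv")
    with _open_text(mtx) as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat).toarray()
    with _open_text(bc) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(feat) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # 10x features.tsv carries (id, name[, type]); prefer the display name
    names = [r[1] if len(r) > 1 else r[0] for r in rows]
    # 10x matrices are stored features x cells
    return CountMatrix(mat.T, _strip(barcodes, strip_suffix), names)


def _read_dense_table(path: Path, strip_suffix: bool) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValidationError(f"empty counts table: {path}")
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        df.to_numpy(), _strip(df.index.astype(str), strip_suffix), df.columns.astype(str)
    )


def write_counts_dense(cm: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    cm.to_frame().to_csv(path, sep=sep, index_label="barcode")


def write_counts_mtx_dir(cm: CountMatrix, directory: str | Path) -> None:
    """Write a 10x-style directory (matrix features x cells, uncompressed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(cm.counts.T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in cm.barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{h}\t{h}\tAntibody Capture\n" for h in cm.hashtag_names)
    )


_STATUS_MAP = {
    "singlet": "singlet",
    "doublet": "doublet",
    "unassigned": "unassigned",
    "negative": "unassigned",  # older souporcell versions use this token
}


def read_genotype_assignments(
    path: str | Path, strip_suffix: bool = False
) -> GenotypeAssignment:
    """Read a souporcell ``clusters.tsv``-dialect table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "status", "assignment"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"clusters table missing columns: {sorted(missing)}")
    status: list[str] = []
    cluster: list[str | None] = []
    for s, a in zip(df["status"], df["assignment"]):
        tok = str(s).strip().lower()
        if tok not in _STATUS_MAP:
            raise ValidationError(f"unknown genotype status token {s!r}")
        st = _STATUS_MAP[tok]
        status.append(st)
        cluster.append(str(a).strip() if st == GENO_SINGLET else None)
    return GenotypeAssignment(
        _strip(df["barcode"].astype(str), strip_suffix), status, cluster
    )


def write_genotype_assignments(geno: GenotypeAssignment, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "barcode": list(geno.barcodes),
            "status": list(geno.status),
            "assignment": ["" if c is None else c for c in geno.cluster],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_label_table(path: str | Path) -> LabelTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"barcode", "label"} - set(df.columns)
    if missing:
        raise SchemaError(f"label table missing columns: {sorted(missing)}")
    return LabelTable(df["barcode"].tolist(), df["label"].tolist())


def write_assignments(labels: LabelTable, path: str | Path) -> None:
    """Write a ``barcode<TAB>label`` table (header + one row per cell)."""
    if len(labels) == 0:
        raise ValidationError("refusing to write an empty label table")
    pd.DataFrame(
        {"barcode": list(labels.barcodes), "label": list(labels.labels)}
    ).to_csv(path, sep="\t", index=False)


def write_hashing_assignment(assign: HashingAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "barcode": list(assign.barcodes),
            "label": list(assign.labels),
            "n_positive": list(assign.n_positive),
        }
    ).to_csv(path, sep="\t", index=False)


def read_hashing_assignment(path: str | Path) -> HashingAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "label": str})
    missing = {"barcode", "label", "n_positive"} - set(df.columns)
    if missing:
        raise SchemaError(f"hashing table missing columns: {sorted(missing)}")
    return HashingAssignment(
        df["barcode"].tolist(), df["label"].tolist(), df["n_positive"].astype(int).tolist()
    )


def read_contingency_table(path: str | Path) -> ContingencyTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty contingency table: {path}") from exc
    return ContingencyTable(df)


def write_contingency_table(tab: ContingencyTable, path: str | Path) -> None:
    tab.table.to_csv(path, sep="\t", index_label="hashing_label")


def write_hybrid_result(result: HybridResult, path: str | Path) -> None:
    """Write per-cell final labels plus hashing/genotype labels and case tags."""
    if len(result) == 0:
        raise ValidationError("refusing to write an empty hybrid result")
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_hybrid_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"barcode", "label", "case"} - set(df.columns)
    if missing:
        raise SchemaError(f"hybrid table missing columns: {sorted(missing)}")
    return df
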