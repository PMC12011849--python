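"""Readers and writers for the on-disk formats used by the pipeline.

Count matrices travel as a 10x-style triplet (Matrix Market ``matrix.mtx``
with 1-based coordinate indices plus ``features.tsv`` / ``barcodes.tsv``);
gene sets as GMT; gene positions as BED-like TSV.  Gzipped MTX variants are
accepted transparently.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "write_10x_triplet",
    "load_counts_mtx",
    "read_gmt",
    "write_gmt",
    "read_gene_positions",
    "write_gene_positions",
    "write_json",
]


def write_10x_triplet(counts: CountMatrix, outdir: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(np.asarray(counts.values))
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    with open(outdir / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for c in counts.cell_ids:
            fh.write(f"{c}\n")
    return outdir


def _find(outdir: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = outdir / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {outdir}")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[column])
    return out


def load_counts_mtx(directory: str | Path) -> CountMatrix:
    """Parse a 10x-style triplet directory into a dense CountMatrix.

    Duplicate coordinate entries are summed with a warning; non-integer
    values are rejected for count input.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    mat = scipy.io.mmread(str(mtx_path))
    genes = _read_tsv_column(_find(directory, "features.tsv"))
    cells = _read_tsv_column(_find(directory, "barcodes.tsv"))
    if sp.issparse(mat):
        coo = mat.tocoo()
        n_listed = coo.data.size
        csr = coo.tocsr()
        csr.sum_duplicates()
        if csr.data.size < n_listed:
            warnings.warn("duplicate MTX entries summed")
        dense = np.asarray(csr.todense())
    else:
        dense = np.asarray(mat)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match features x barcodes "
            f"({len(genes)}, {len(cells)})"
        )
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("count matrix contains non-integer values")
    if dense.min() < 0:
        raise ValueError("count matrix contains negative values")
    return CountMatrix(dense.astype(np.int64), genes, cells)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV (chrom, start, end, gene_id) into a frame
    indexed by gene_id."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str, "start": int, "end": int, "gene_id": str},
    )
    return df.set_index("gene_id")


def write_gene_positions(gene_meta: pd.DataFrame, path: str | Path) -> None:
    out = gene_meta.reset_index()[["chromosome", "start", "end", "gene_id"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
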