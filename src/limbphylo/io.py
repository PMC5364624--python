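"""Readers and writers for the plain-text interchange formats.

All tabular files are TSV with a header row and gene IDs in the first
column.  Homology tables use an outfmt-6-like subset with explicit species
columns: ``qseqid  qspecies  sseqid  sspecies  evalue``.  Trees are Newick,
manifests and truth records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

HOMOLOGY_COLUMNS = ["qseqid", "qspecies", "sseqid", "sspecies", "evalue"]

#: number formatting used for every float written to disk, so that a fixed
#: seed yields byte-identical files.
FLOAT_FORMAT = "%.6g"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (gene IDs in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def read_lengths(path: str | Path) -> pd.Series:
    """Read a two-column TSV of gene ID -> transcript length (bp)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(int)
    s.index = s.index.astype(str)
    s.index.name = None
    s.name = "length"
    return s


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample, species, limb, stage, replicate."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_homology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HOMOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"homology table {path} missing columns: {sorted(missing)}")
    return df[HOMOLOGY_COLUMNS]


def write_homology(hits: pd.DataFrame, path: str | Path) -> None:
    hits[HOMOLOGY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.3g")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
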