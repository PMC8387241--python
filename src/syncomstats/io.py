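"""Plain-text readers and writers for the package's table formats.

Count tables travel as TSV with features as rows and samples as columns,
first column ``feature_id``; a leading ``# feature_kind: ...`` comment
records whether features are strains or OTUs.  Well tables are OTUs (rows)
by ``plate:well`` columns.  Config files are flat ``key: value`` text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import METADATA_COLUMNS, CountTable

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_metadata_tsv", "write_metadata_tsv",
    "read_wells_tsv", "write_wells_tsv",
    "read_profile_tsv", "write_profile_tsv",
    "read_qpcr_tsv", "read_fastq", "read_fastq_dir",
    "read_config",
]


def write_counts_tsv(table: CountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# feature_kind: {table.feature_kind}\n")
        table.counts.T.rename_axis("feature_id").to_csv(fh, sep="\t")


def read_counts_tsv(path, feature_kind: str | None = None) -> CountTable:
    kind = feature_kind
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if kind is None and "feature_kind:" in first:
                kind = first.split("feature_kind:")[1].strip()
            df = pd.read_csv(fh, sep="\t", index_col="feature_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="feature_id")
    counts = df.T
    counts.index.name = "sample_id"
    return CountTable(counts, kind or "strain")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id",
                       dtype={"replicate": "Int64"})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns
               and c not in ("first_syncom", "second_syncom")]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta


def write_wells_tsv(wells: pd.DataFrame, path) -> None:
    wells.T.rename_axis("otu_id").to_csv(path, sep="\t")


def read_wells_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    wells = df.T.astype(int)
    wells.index.name = "well"
    return wells


def write_profile_tsv(profile: pd.Series, path) -> None:
    profile.rename("ra").rename_axis("otu_id").to_csv(path, sep="\t")


def read_profile_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    return df["ra"]


def read_qpcr_tsv(path) -> pd.DataFrame:
    """qPCR table: columns sample_id, Ct_16S, Ct_plant."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "Ct_16S", "Ct_plant"):
        if col not in df.columns:
            raise ValueError(f"qPCR table missing column {col!r}")
    return df.set_index("sample_id")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a 4-line-record FASTQ into [(read_id, sequence), ...]."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def read_fastq_dir(directory) -> dict[str, list[tuple[str, str]]]:
    """One sample per ``*.fastq`` file; sample id is the file stem."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.fastq")):
        out[path.stem] = read_fastq(path)
    if not out:
        raise FileNotFoundError(f"no .fastq files under {directory}")
    return out


def read_config(path) -> dict:
    """Flat ``key: value`` config; values coerced to int/float when possible."""
    cfg: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            val = val.strip()
            for cast in (int, float):
                try:
                    val = cast(val)
                    break
                except ValueError:
                    continue
            cfg[key.strip()] = val
    return cfg
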