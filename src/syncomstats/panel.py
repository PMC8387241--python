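"""Strain panels: paired synthetic communities of root-derived bacteria.

A panel holds one record per strain: its identifier, the host species it was
isolated from (``Lj`` = *Lotus japonicus*, ``At`` = *Arabidopsis thaliana*),
its bacterial family, a species token and the 16S rRNA v5–v7 reference
fragment used for read mapping.  Panels built by :func:`make_strain_panel`
are *taxonomically paired*: every family contributes exactly one Lj-derived
and one At-derived strain, so the two half-communities are symmetric by
construction.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HOSTS = ("Lj", "At")
_BASES = np.frombuffer(b"ACGT", dtype="S1")

__all__ = ["HOSTS", "StrainPanel", "make_strain_panel"]


class StrainPanel:
    """Immutable table of SynCom member strains.

    Parameters
    ----------
    strains : pandas.DataFrame
        One row per strain with columns ``strain_id``, ``host_of_origin``,
        ``family``, ``species`` and ``ref_seq``.  ``strain_id`` values must
        be unique; reference sequences must be non-empty strings over ACGT.
    """

    REQUIRED = ("strain_id", "host_of_origin", "family", "species", "ref_seq")

    def __init__(self, strains: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in strains.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        df = strains.loc[:, list(self.REQUIRED)].copy()
        if df["strain_id"].duplicated().any():
            dupes = df.loc[df["strain_id"].duplicated(), "strain_id"].tolist()
            raise ValueError(f"duplicate strain ids: {dupes}")
        bad_host = set(df["host_of_origin"]) - set(HOSTS)
        if bad_host:
            raise ValueError(f"unknown host_of_origin values: {sorted(bad_host)}")
        for sid, seq in zip(df["strain_id"], df["ref_seq"]):
            if len(df) and (not seq or set(seq) - set("ACGT")):
                raise ValueError(f"strain {sid}: ref_seq must be non-empty over ACGT")
        self._df = df.set_index("strain_id", drop=False)

    # -- accessors ---------------------------------------------------------
    @property
    def strains(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def host_of_origin(self) -> pd.Series:
        return self._df["host_of_origin"]

    @property
    def families(self) -> pd.Series:
        return self._df["family"]

    @property
    def ref_seqs(self) -> pd.Series:
        return self._df["ref_seq"]

    def native_ids(self, host: str) -> list[str]:
        """Strain ids isolated from *host* (their cognate host)."""
        return list(self._df.index[self._df["host_of_origin"] == host])

    def subset(self, ids: Iterable[str]) -> "StrainPanel":
        ids = list(ids)
        unknown = set(ids) - set(self._df.index)
        if unknown:
            raise KeyError(f"unknown strain ids: {sorted(unknown)}")
        return StrainPanel(self._df.loc[ids].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, StrainPanel) and self._df.equals(other._df)

    def __repr__(self) -> str:
        fams = self._df["family"].nunique()
        return f"StrainPanel(n_strains={len(self)}, n_families={fams})"

    # -- IO ----------------------------------------------------------------
    def to_fasta(self, path) -> None:
        """Write one record per strain; header ``strain_id|host|family``."""
        records = [
            SeqRecord(
                Seq(row.ref_seq),
                id=f"{row.strain_id}|{row.host_of_origin}|{row.family}",
                description="",
            )
            for row in self._df.itertuples()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "StrainPanel":
        rows = []
        for rec in SeqIO.parse(path, "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise ValueError(f"malformed panel header {rec.id!r}; "
                                 "expected strain_id|host|family")
            sid, host, family = parts
            rows.append(
                dict(strain_id=sid, host_of_origin=host, family=family,
                     species=f"{family}_sp", ref_seq=str(rec.seq).upper())
            )
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def make_strain_panel(
    n_per_host: int,
    n_families: int,
    seq_len: int = 360,
    family_divergence: float = 0.10,
    seed: int = 0,
) -> StrainPanel:
    """Build a taxonomically paired panel of ``2 * n_per_host`` strains.

    Each family gets a random centroid sequence; its Lj member carries the
    centroid and its At member differs at 1..ceil(0.03*seq_len) positions —
    distinguishable at strain level yet within the same 97%-identity OTU.
    Centroids of different families differ at >= family_divergence*seq_len
    positions, so families are well separated.  Deterministic given *seed*.
    """
    if n_per_host < 0 or n_families < 0:
        raise ValueError("n_per_host and n_families must be >= 0")
    if n_per_host != n_families:
        raise ValueError("paired panel requires n_families == n_per_host")
    if n_per_host == 0:
        return StrainPanel(pd.DataFrame(columns=list(StrainPanel.REQUIRED)))
    if not (0 < family_divergence < 0.5):
        raise ValueError("family_divergence must be in (0, 0.5)")
    if seq_len < 50:
        raise ValueError("seq_len must be >= 50")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    min_between = math.ceil(family_divergence * seq_len)
    max_within = math.ceil(0.03 * seq_len)

    # Families must stay separated even after within-family mutations, so
    # centroids are kept 2*max_within further apart than the floor.
    for _attempt in range(100):
        centroids = [_random_seq(rng, seq_len) for _ in range(n_families)]
        ok = all(
            _hamming(centroids[i], centroids[j]) >= min_between + 2 * max_within
            for i in range(n_families)
            for j in range(i + 1, n_families)
        )
        if ok:
            break
    else:  # pragma: no cover - iid ACGT sequences diverge at ~75% of sites
        raise RuntimeError("could not draw sufficiently divergent family centroids")

    rows = []
    for f in range(n_families):
        family = f"f{f + 1:02d}"
        k = int(rng.integers(1, max_within + 1))
        positions = rng.choice(seq_len, size=k, replace=False)
        lj_seq = centroids[f]
        at_seq = _mutate(lj_seq, positions, rng)
        for host, seq in (("Lj", lj_seq), ("At", at_seq)):
            rows.append(
                dict(
                    strain_id=f"{host}_{family}",
                    host_of_origin=host,
                    family=family,
                    species=f"{family}_sp{1 if host == 'Lj' else 2}",
                    ref_seq=seq.tobytes().decode("ascii"),
                )
            )
    return StrainPanel(pd.DataFrame(rows))
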