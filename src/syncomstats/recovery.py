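"""Culture-collection (IRL) recovery statistics.

A sequence-indexed rhizobacterial library (IRL) is a set of limiting-dilution
microtitre wells whose contents are identified by 16S amplicon sequencing.
Cross-referencing the well x OTU count table against a culture-independent
community profile answers two questions: which community members are
*recoverable* in culture (they dominate at least one sufficiently pure
well), and how much of the natural community those recoverable members
represent (percentage of abundant OTUs recovered; accumulated relative
abundance of all recovered OTUs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "RecoveryReport",
    "greedy_cluster_otus",
    "filter_well_table",
    "recoverable_otus",
    "recoverable_set",
    "recovery_report",
    "pairwise_identity",
]


def _aligner(match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -2.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matched columns / alignment length."""
    if aligner is None:
        aligner = _aligner()
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()  # identities, mismatches, gaps
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def greedy_cluster_otus(
    sequences: pd.Series,
    abundances: pd.Series | None = None,
    identity: float = 0.97,
) -> pd.Series:
    """Abundance-sorted greedy centroid clustering at an identity threshold.

    Sequences are visited in decreasing abundance (ties broken by id,
    lexicographically); each joins the first existing centroid whose global
    pairwise identity is >= ``identity``, otherwise it founds a new OTU.
    Returns a Series mapping sequence id -> OTU id (``otu_0001``...).
    """
    if sequences.empty:
        raise ValueError("no sequences to cluster")
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if abundances is None:
        abundances = pd.Series(1.0, index=sequences.index)
    # stable sort over lexicographically ordered ids: ties break by id
    order = (
        pd.DataFrame({"ab": abundances.loc[sequences.index]})
        .loc[sorted(sequences.index)]
        .sort_values("ab", ascending=False, kind="mergesort")
    )
    aligner = _aligner()
    centroids: list[tuple[str, str]] = []  # (otu_id, centroid sequence)
    assignment: dict[str, str] = {}
    for sid in order.index:
        seq = sequences[sid]
        for otu_id, cseq in centroids:
            if seq == cseq or pairwise_identity(seq, cseq, aligner) >= identity:
                assignment[sid] = otu_id
                break
        else:
            otu_id = f"otu_{len(centroids) + 1:04d}"
            centroids.append((otu_id, seq))
            assignment[sid] = otu_id
    return pd.Series(assignment, name="otu_id").loc[sequences.index]


def filter_well_table(
    wells: pd.DataFrame,
    min_well_reads: int = 100,
    min_otu_well_reads: int = 10,
) -> pd.DataFrame:
    """Quality-filter a wells x OTUs count table.

    Wells totalling fewer than ``min_well_reads`` reads are removed; then
    OTUs never reaching ``min_otu_well_reads`` reads in any remaining well
    are removed.  Both boundaries are inclusive (a 100-read well and an
    OTU peaking at exactly 10 reads are kept).
    """
    if min_well_reads < 0 or min_otu_well_reads < 0:
        raise ValueError("thresholds must be >= 0")
    kept = wells.loc[wells.sum(axis=1) >= min_well_reads]
    if kept.empty:
        return kept.iloc[:, :0].copy() if kept.shape[1] else kept.copy()
    otu_max = kept.max(axis=0)
    return kept.loc[:, otu_max >= min_otu_well_reads].copy()


def recoverable_otus(
    wells: pd.DataFrame,
    purity_threshold: float = 0.90,
) -> pd.Series:
    """Best well purity per OTU; recoverable OTUs dominate a pure well.

    Well purity is the fraction of a well's reads belonging to its most
    abundant OTU.  An OTU is recoverable iff it is the top member of at
    least one well with purity >= ``purity_threshold`` (inclusive).
    Returns the per-OTU best purity *as a top member* (NaN if the OTU never
    tops a well); the recoverable set is ``best_purity >= threshold``.
    """
    if not 0 < purity_threshold <= 1:
        raise ValueError("purity_threshold must be in (0, 1]")
    best = pd.Series(np.nan, index=wells.columns, name="best_purity")
    totals = wells.sum(axis=1)
    for well in wells.index[totals > 0]:
        row = wells.loc[well]
        top = row.idxmax()
        purity = row[top] / totals[well]
        if pd.isna(best[top]) or purity > best[top]:
            best[top] = purity
    return best


def recoverable_set(best_purity: pd.Series, purity_threshold: float = 0.90) -> set:
    return set(best_purity.index[best_purity >= purity_threshold])


@dataclass
class RecoveryReport:
    """Cross-reference of a natural community profile with a culture set."""

    table: pd.DataFrame  # per OTU: ra, abundant, recovered, rank
    pct_abundant_recovered: float  # NaN when no abundant OTU exists
    accumulated_ra_recovered: float
    n_abundant: int
    n_recovered_abundant: int

    def rank_abundance(self) -> pd.DataFrame:
        """OTUs sorted by decreasing natural RA with recovered flags."""
        return self.table.sort_values("ra", ascending=False)


def recovery_report(
    natural_profile: pd.Series,
    recovered: set,
    abundance_threshold: float = 0.001,
    abundant_only_accumulation: bool = False,
) -> RecoveryReport:
    """Recovery statistics of a culture collection against a natural profile.

    ``pct_abundant_recovered`` is the percentage of abundant OTUs (natural
    RA >= ``abundance_threshold``, inclusive) present in ``recovered``;
    ``accumulated_ra_recovered`` sums the natural RA of every recovered OTU
    (restricted to abundant ones when ``abundant_only_accumulation``).
    The recovered set may come from the same host's collection or from the
    other host's (cross-collection mode) — it is just a set of OTU ids.
    """
    total = float(natural_profile.sum())
    if total > 1 + 1e-9:
        raise ValueError("natural profile must sum to <= 1")
    if (natural_profile < 0).any():
        raise ValueError("relative abundances must be >= 0")
    table = pd.DataFrame({"ra": natural_profile.astype(float)})
    table["abundant"] = table["ra"] >= abundance_threshold
    table["recovered"] = table.index.isin(recovered)
    table = table.sort_values("ra", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)

    n_abundant = int(table["abundant"].sum())
    n_rec_ab = int((table["abundant"] & table["recovered"]).sum())
    pct = 100.0 * n_rec_ab / n_abundant if n_abundant else float("nan")
    mask = table["recovered"] & (table["abundant"] if abundant_only_accumulation
                                 else True)
    accumulated = float(table.loc[mask, "ra"].sum())
    return RecoveryReport(
        table=table,
        pct_abundant_recovered=pct,
        accumulated_ra_recovered=accumulated,
        n_abundant=n_abundant,
        n_recovered_abundant=n_rec_ab,
    )
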