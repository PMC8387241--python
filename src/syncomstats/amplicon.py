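"""In-silico amplification and perfect-match strain quantification.

Strain reference sequences are the v5-v7 16S rRNA fragments delimited by the
degenerate primers 799F (AACMGGATTAGATACCCKG) and 1192R (ACGTCATCCCCACCTTCC).
:func:`extract_amplicon` locates exact degenerate-primer binding sites on a
template (genome contig) and returns the enclosed amplicon, primer sites
included.  :func:`map_reads_exact` assigns merged, oriented amplicon reads to
strains by full-length byte identity with a reference; reads matching no
reference are *unmapped*, reads matching two or more are *ambiguous* and are
reported but never counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountTable, check_metadata
from .panel import StrainPanel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

PRIMER_799F = "AACMGGATTAGATACCCKG"
PRIMER_1192R = "ACGTCATCCCCACCTTCC"

__all__ = [
    "PrimerPair",
    "MappingResult",
    "NoAmpliconError",
    "DEFAULT_PRIMERS",
    "extract_amplicon",
    "map_reads_exact",
    "unmapped_summary",
    "revcomp",
]


class NoAmpliconError(ValueError):
    """Raised when primer matching fails; ``primer`` names the culprit."""

    def __init__(self, message: str, primer: str):
        super().__init__(message)
        self.primer = primer


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate primer pair; both given 5'->3' on their own strand."""

    forward: str = PRIMER_799F
    reverse: str = PRIMER_1192R

    def __post_init__(self):
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC characters: {sorted(bad)}")


DEFAULT_PRIMERS = PrimerPair()


def revcomp(seq: str) -> str:
    """Reverse complement honouring IUPAC degeneracy codes."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))


def _iupac_regex(primer: str) -> re.Pattern:
    parts = []
    for c in primer.upper():
        opts = IUPAC[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def extract_amplicon(
    template: str,
    primers: PrimerPair = DEFAULT_PRIMERS,
    max_len: int = 2000,
) -> str:
    """Extract the amplicon delimited by exact degenerate-primer matches.

    The leftmost forward-primer match is paired with the leftmost
    reverse-complemented reverse-primer match downstream of it; the returned
    fragment includes both primer binding sites.  Matching allows zero
    mismatches; IUPAC codes match their degenerate base sets.
    """
    template = template.upper()
    bad = set(template) - set("ACGTN")
    if bad:
        raise ValueError(f"template has non-nucleotide characters: {sorted(bad)}")
    fwd = _iupac_regex(primers.forward).search(template)
    if fwd is None:
        raise NoAmpliconError("no forward-primer binding site", primer="forward")
    rev = _iupac_regex(revcomp(primers.reverse)).search(template, fwd.end())
    if rev is None:
        raise NoAmpliconError(
            "no reverse-primer binding site downstream of the forward site",
            primer="reverse",
        )
    amplicon = template[fwd.start():rev.end()]
    if len(amplicon) > max_len:
        raise NoAmpliconError(
            f"amplicon length {len(amplicon)} exceeds the {max_len} nt cap",
            primer="reverse",
        )
    return amplicon


@dataclass
class MappingResult:
    """Per-sample strain counts plus unmapped/ambiguous read tallies."""

    counts: CountTable
    unmapped: pd.Series
    ambiguous: pd.Series
    duplicated_refs: list = field(default_factory=list)

    def total_reads(self) -> pd.Series:
        return self.counts.sample_sums() + self.unmapped + self.ambiguous


def _normalize_reads(reads) -> Iterable[str]:
    for item in reads:
        yield item[1] if isinstance(item, tuple) else item


def map_reads_exact(
    reads_by_sample: Mapping[str, Iterable],
    references: StrainPanel,
    allow_revcomp: bool = False,
    trim: tuple[int, int] = (0, 0),
) -> MappingResult:
    """Assign reads to strains by exact full-length sequence identity.

    A read is counted for a strain iff (after optional constant-length
    prefix/suffix trimming) it equals that strain's reference byte for byte;
    reads equal to two or more references are ambiguous.  Reads are assumed
    merged and oriented; set ``allow_revcomp`` for unoriented input.
    """
    if len(references) == 0:
        raise ValueError("reference panel is empty")
    ref_of: dict[str, str | None] = {}
    duplicated: set[str] = set()
    for sid, seq in references.ref_seqs.items():
        if seq in ref_of:
            duplicated.add(seq)
            ref_of[seq] = None  # inherently ambiguous
        else:
            ref_of[seq] = sid
    if duplicated:
        warnings.warn(
            f"{len(duplicated)} duplicated reference sequences; their reads "
            "are inherently ambiguous",
            stacklevel=2,
        )

    strain_ids = references.ids
    samples = list(reads_by_sample)
    mat = np.zeros((len(samples), len(strain_ids)), dtype=np.int64)
    col = {s: j for j, s in enumerate(strain_ids)}
    unmapped = np.zeros(len(samples), dtype=np.int64)
    ambiguous = np.zeros(len(samples), dtype=np.int64)
    lo, hi = trim
    for i, sample in enumerate(samples):
        for seq in _normalize_reads(reads_by_sample[sample]):
            seq = seq.upper()
            if lo or hi:
                seq = seq[lo: len(seq) - hi if hi else None]
            hits = []
            if seq in ref_of:
                hits.append(ref_of[seq])
            if allow_revcomp:
                rc = revcomp(seq)
                if rc != seq and rc in ref_of:
                    hits.append(ref_of[rc])
            if not hits:
                unmapped[i] += 1
            elif len(hits) == 1 and hits[0] is not None:
                mat[i, col[hits[0]]] += 1
            else:  # duplicate reference or fwd+rc double hit
                ambiguous[i] += 1
    counts = pd.DataFrame(mat, index=samples, columns=strain_ids)
    counts.index.name = "sample_id"
    return MappingResult(
        counts=CountTable(counts, "strain"),
        unmapped=pd.Series(unmapped, index=samples, name="unmapped"),
        ambiguous=pd.Series(ambiguous, index=samples, name="ambiguous"),
        duplicated_refs=sorted(duplicated),
    )


def unmapped_summary(
    result: MappingResult,
    metadata: pd.DataFrame,
    factors: tuple = ("compartment", "host_species", "experiment"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Unmapped/ambiguous read fractions per grouping-factor level.

    Returns a tidy table (factor, level, n_samples, mean fractions) and a
    Kruskal-Wallis p-value per factor testing whether the per-sample
    unmapped fraction differs between its levels.  Zero-read samples have
    undefined fractions and are excluded (reported as missing).
    """
    meta = check_metadata(metadata, result.counts.sample_ids)
    total = result.total_reads().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_unmapped = (result.unmapped / total).where(total > 0)
        frac_ambiguous = (result.ambiguous / total).where(total > 0)
    rows = []
    pvalues: dict[str, float] = {}
    for factor in factors:
        if factor not in meta.columns:
            raise KeyError(f"metadata lacks column {factor!r}")
        groups = []
        for level, idx in meta.groupby(factor, observed=True).groups.items():
            fu = frac_unmapped.loc[idx]
            fa = frac_ambiguous.loc[idx]
            rows.append(
                dict(factor=factor, level=level, n_samples=int(fu.notna().sum()),
                     mean_unmapped=fu.mean(), mean_ambiguous=fa.mean())
            )
            vals = fu.dropna().to_numpy()
            if len(vals):
                groups.append(vals)
        if len(groups) >= 2:
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                pvalues[factor] = 1.0  # identical fractions everywhere
            else:
                pvalues[factor] = float(stats.kruskal(*groups).pvalue)
        else:
            pvalues[factor] = float("nan")
    return pd.DataFrame(rows), pvalues
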