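"""Community ecology statistics on count and abundance tables.

Normalization, Shannon diversity (natural log), Bray–Curtis dissimilarity,
principal coordinates analysis (classical scaling), PERMANOVA with optional
strata-restricted permutations, host-of-origin aggregation, Kruskal–Wallis
with Dunn's post hoc and Benjamini–Hochberg adjustment, and qPCR bacterial
load.  No rarefaction is applied before diversity; a minimum-depth sample
filter is available instead via ``min_sample_reads``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, spatial, stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, CountTable, check_metadata
from .panel import HOSTS, StrainPanel

__all__ = [
    "relative_abundance",
    "shannon",
    "bray_curtis",
    "bray_curtis_matrix",
    "OrdinationResult",
    "pcoa",
    "permanova",
    "aggregate_by_origin",
    "kruskal_dunn",
    "qpcr_load",
]


def relative_abundance(table: CountTable, min_sample_reads: int = 0) -> AbundanceTable:
    """Row-normalize counts to relative abundances.

    Samples with total reads below ``min_sample_reads`` (or zero) are kept
    as all-zero rows and flagged in ``empty_samples``.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    ok = totals >= max(min_sample_reads, 1)
    values = counts.where(ok, 0.0).div(totals.where(ok, 1.0), axis=0)
    empty = list(counts.index[~ok])
    return AbundanceTable(values, table.feature_kind, empty)


def shannon(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive entries."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a single abundance vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("abundances must sum to 1")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity: 1 - 2*sum(min)/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(ab: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray–Curtis distances between samples (empty ones dropped)."""
    df = ab.drop_empty().values if isinstance(ab, AbundanceTable) else ab
    condensed = spatial.distance.pdist(df.to_numpy(), metric="braycurtis")
    return pd.DataFrame(spatial.distance.squareform(condensed),
                        index=df.index, columns=df.index)


@dataclass
class OrdinationResult:
    """Classical-scaling ordination: coordinates and explained variance."""

    coordinates: pd.DataFrame  # samples x axes (PCo1, PCo2, ...)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray  # relative to the positive spectrum
    negative_eigenvalues: np.ndarray  # reported separately, not in variance


def pcoa(D: pd.DataFrame, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix -0.5 * J D^2 J.  Axes are
    ordered by decreasing eigenvalue; negative eigenvalues (non-Euclidean
    input) are excluded from the variance denominator and returned
    separately.
    """
    M = np.asarray(D, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(M), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (M ** 2) @ J
    eigvals, eigvecs = linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > eps
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    index = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(n)
    coordinates = pd.DataFrame(
        coords, index=index, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(
        coordinates=coordinates,
        eigenvalues=lam,
        proportion_explained=lam / lam.sum() if lam.size else lam,
        negative_eigenvalues=eigvals[eigvals < -eps],
    )


def _ss_within_batch(D2: np.ndarray, labels: np.ndarray, codes: int) -> np.ndarray:
    """Within-group sum of squared distances for a batch of label rows."""
    B, n = labels.shape
    onehot = np.zeros((B, n, codes))
    b_idx = np.repeat(np.arange(B), n)
    n_idx = np.tile(np.arange(n), B)
    onehot[b_idx, n_idx, labels.ravel()] = 1.0
    group_ss = np.einsum("bng,nm,bmg->bg", onehot, D2, onehot) / 2.0
    sizes = onehot.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_group = np.where(sizes > 0, group_ss / np.maximum(sizes, 1), 0.0)
    return per_group.sum(axis=1)


def permanova(
    D: pd.DataFrame,
    labels,
    n_perm: int = 5000,
    seed: int = 0,
    strata=None,
) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from among/within sums of squared distances;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  When ``strata`` is given,
    labels are permuted only within strata blocks.
    Returns ``{"F": ..., "R2": ..., "p": ..., "n_perm": ...}``.
    """
    M = np.asarray(D, dtype=float)
    labels = pd.Series(np.asarray(labels), index=range(len(labels)))
    if M.shape[0] != len(labels):
        raise ValueError("labels length must match the distance matrix")
    codes, uniques = pd.factorize(labels)
    g = len(uniques)
    if g < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if pd.Series(codes).value_counts().min() < 2:
        raise ValueError("every group needs at least two members")
    n = M.shape[0]
    D2 = M ** 2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    codes = np.asarray(codes)
    ss_within = _ss_within_batch(D2, codes[None, :], g)[0]
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    f_obs = (ss_among / df_among) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    base = np.arange(n)
    if strata is None:
        for b in range(n_perm):
            perms[b] = rng.permutation(base)
    else:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata length must match the distance matrix")
        blocks = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        for b in range(n_perm):
            row = base.copy()
            for blk in blocks:
                row[blk] = blk[rng.permutation(len(blk))]
            perms[b] = row
    # permuted labels: label of sample i under permutation row is codes[row[i]]
    perm_codes = codes[perms]
    batch = 500
    exceed = 0
    for start in range(0, n_perm, batch):
        sw = _ss_within_batch(D2, perm_codes[start:start + batch], g)
        f_perm = ((ss_total - sw) / df_among) / (sw / df_within)
        exceed += int((f_perm >= f_obs).sum())
    p = (1 + exceed) / (1 + n_perm)
    return {"F": float(f_obs), "R2": float(ss_among / ss_total), "p": float(p),
            "n_perm": n_perm}


def aggregate_by_origin(ab: AbundanceTable, panel: StrainPanel) -> pd.DataFrame:
    """Per-sample summed relative abundance of Lj- and At-derived strains."""
    missing = [f for f in ab.values.columns if f not in panel.ids]
    if missing:
        raise KeyError(f"features missing from panel: {missing}")
    origin = panel.host_of_origin.loc[ab.values.columns]
    out = pd.DataFrame(index=ab.values.index)
    for host in HOSTS:
        cols = origin.index[origin == host]
        out[f"{host}_derived_RA"] = ab.values[cols].sum(axis=1)
    return out


def _compact_letters(groups: list, nonsig: set[frozenset]) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Letters are the maximal cliques of the non-significance
    graph, ordered deterministically."""
    G = nx.Graph()
    G.add_nodes_from(groups)
    G.add_edges_from((a, b) for a, b in
                     (tuple(sorted(pair, key=str)) for pair in nonsig))
    cliques = sorted((sorted(c, key=groups.index) for c in nx.find_cliques(G)),
                     key=lambda c: (groups.index(c[0]), -len(c)))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        ch = string.ascii_lowercase[i % 26] * (i // 26 + 1)
        for g in clique:
            letters[g] += ch
    return letters


def kruskal_dunn(values, groups, alpha: float = 0.05) -> dict:
    """Kruskal–Wallis H test with Dunn's post hoc and BH adjustment.

    Returns the tie-corrected H statistic, its p-value, a pairwise table of
    Dunn z statistics with raw and BH-adjusted p-values, and a compact
    letter display (groups sharing a letter are not significantly different
    at ``alpha`` after adjustment).
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(groups))
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    sizes = groups.value_counts()
    if (sizes < 1).any() or len(sizes) != len(levels):
        raise ValueError("every group needs at least one observation")
    samples = [values[groups.to_numpy() == lv] for lv in levels]
    if np.ptp(values) == 0:
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = stats.kruskal(*samples)

    # Dunn's z statistics on mean ranks with tie correction
    N = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {lv: ranks[groups.to_numpy() == lv].mean() for lv in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            na, nb = len(samples[levels.index(a)]), len(samples[levels.index(b)])
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(dict(group_a=a, group_b=b, z=z, p=p))
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    nonsig = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.q > alpha
    }
    letters = _compact_letters(levels, nonsig)
    return {
        "H": float(H),
        "p": float(p_kw),
        "pairwise": pairwise,
        "letters": letters,
    }


def qpcr_load(ct_16s: float, ct_plant: float) -> float:
    """Bacterial load from qPCR cycle thresholds: 2^-Ct(16S) / 2^-Ct(plant).

    Equivalently 2^(Ct_plant - Ct_16S): each cycle earlier for the 16S
    amplicon doubles the inferred bacteria-to-plant DNA ratio.
    """
    if not (np.isfinite(ct_16s) and np.isfinite(ct_plant)):
        raise ValueError("Ct values must be finite")
    if ct_16s <= 0 or ct_plant <= 0:
        raise ValueError("Ct values must be positive")
    return float(2.0 ** (ct_plant - ct_16s))
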