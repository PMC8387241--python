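"""Host-preference and invasiveness statistics of individual SynCom strains.

The host preference index (HPI) of a strain is the ratio of its mean
relative abundance in root samples of its cognate host (the species it was
isolated from) over its mean relative abundance in root samples of the
other host, computed independently per experiment.  Strains whose mean RA
falls below 0.1% in either host are excluded to avoid inflated ratios from
tiny denominators.  Significance per strain is a two-sided Mann–Whitney
rank-sum test of per-sample RA between hosts, Benjamini–Hochberg adjusted
across strains.

The invasiveness index is the same ratio computed only from
sequential-inoculation samples in which the strain's SynCom arrived second,
onto an established resident community.  The two indices are compared by
Pearson correlation on log2 scale (ratios are multiplicative), with a
partial correlation given log2 mean RA operationalizing independence from
abundance.

Both statistics follow the statsmodels convention: a model object built
from data, whose ``fit()`` returns a results object with the estimates,
test statistics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, check_metadata
from .panel import HOSTS, StrainPanel
from .stats import aggregate_by_origin

__all__ = [
    "HostPreference",
    "Invasiveness",
    "IndexResults",
    "mann_whitney",
    "correlate_indices",
    "family_knockout",
]

EXACT_MW_MAX_N = 8  # exact enumeration at or below; normal approximation above


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U and p.

    Exact enumeration when both groups have <= 8 observations, otherwise the
    normal approximation with tie correction and continuity correction.
    All-tied inputs return p = 1 by convention (the test is uninformative).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class IndexResults:
    """Per-strain index table with significance; returned by ``fit()``.

    ``table`` columns: experiment, strain_id, host_of_origin, family,
    mean_ra_cognate, mean_ra_other, index (NaN when filtered), filtered,
    n_cognate, n_other, U, p, q, significant.
    """

    table: pd.DataFrame
    index_name: str
    alpha: float
    compartment: str
    min_mean_ra: float
    params: dict = field(default_factory=dict)

    def passing(self) -> pd.DataFrame:
        """Rows passing the minimum-abundance filter."""
        return self.table.loc[~self.table["filtered"]].copy()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].fillna(False).sum())

    def summary(self) -> str:
        t = self.table
        kept = (~t["filtered"]).sum()
        lines = [
            f"{self.index_name} results",
            "=" * 52,
            f"compartment: {self.compartment}   min mean RA: {self.min_mean_ra:g}",
            f"strains x experiments: {len(t)}   passing filter: {kept}",
            f"significant at BH q <= {self.alpha:g}: {self.n_significant}",
            "-" * 52,
        ]
        cols = ["experiment", "strain_id", "mean_ra_cognate", "mean_ra_other",
                "index", "q", "significant"]
        with pd.option_context("display.width", 120, "display.max_rows", 400):
            lines.append(t.loc[~t["filtered"], cols]
                         .sort_values("index", ascending=False)
                         .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _index_for_groups(
    ab: pd.DataFrame,
    meta: pd.DataFrame,
    panel: StrainPanel,
    sample_picker,
    min_mean_ra: float,
    experiment: str,
    index_col: str,
) -> pd.DataFrame:
    """Shared engine: ratio of mean RA on cognate vs other host.

    ``sample_picker(strain_host, sample_host)`` returns the boolean sample
    mask over *meta* for the strain-host/sample-host combination.
    """
    rows = []
    for strain in ab.columns:
        origin = panel.host_of_origin[strain]
        other = HOSTS[1] if origin == HOSTS[0] else HOSTS[0]
        mask_c = sample_picker(origin, origin)
        mask_o = sample_picker(origin, other)
        if not mask_c.any() or not mask_o.any():
            raise ValueError(
                f"no samples for host {'cognate' if not mask_c.any() else 'other'} "
                f"of strain {strain} in experiment {experiment}"
            )
        ra_c = ab.loc[mask_c.index[mask_c], strain]
        ra_o = ab.loc[mask_o.index[mask_o], strain]
        mean_c, mean_o = float(ra_c.mean()), float(ra_o.mean())
        filtered = (mean_c < min_mean_ra) or (mean_o < min_mean_ra)
        if filtered:
            idx_val, U, p = float("nan"), float("nan"), float("nan")
        else:
            idx_val = mean_c / mean_o
            U, p = mann_whitney(ra_c.to_numpy(), ra_o.to_numpy())
        rows.append(
            dict(
                experiment=experiment,
                strain_id=strain,
                host_of_origin=origin,
                family=panel.families[strain],
                mean_ra_cognate=mean_c,
                mean_ra_other=mean_o,
                **{index_col: idx_val},
                filtered=filtered,
                n_cognate=int(mask_c.sum()),
                n_other=int(mask_o.sum()),
                U=U,
                p=p,
            )
        )
    return pd.DataFrame(rows)


def _finalize(tables: list[pd.DataFrame], index_col: str, alpha: float) -> pd.DataFrame:
    out = pd.concat(tables, ignore_index=True)
    out = out.rename(columns={index_col: "index"})
    out["q"] = np.nan
    out["significant"] = pd.array([pd.NA] * len(out), dtype="boolean")
    for exp, idx in out.groupby("experiment").groups.items():
        sub = out.loc[idx]
        tested = sub.index[sub["p"].notna()]
        if len(tested):
            q = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
            out.loc[tested, "q"] = q
            out.loc[tested, "significant"] = q <= alpha
    return out


class HostPreference:
    """Model of per-strain host preference in mixed-community competition.

    Parameters
    ----------
    abundance : AbundanceTable
        Strain-level relative abundances (empty samples are dropped).
    metadata : pandas.DataFrame
        Sample metadata (indexed by sample id).  Only samples in the chosen
        compartment where the full mixed community was inoculated first
        enter the index.
    panel : StrainPanel
    compartment : str
        Compartment whose samples are compared (default root; the
        preference signal is a root phenomenon).
    min_mean_ra : float
        Strains below this mean RA in either host are filtered (inclusive
        boundary: exactly ``min_mean_ra`` is kept).
    """

    index_name = "Host preference index"
    index_col = "hpi"

    def __init__(
        self,
        abundance: AbundanceTable,
        metadata: pd.DataFrame,
        panel: StrainPanel,
        compartment: str = "root",
        min_mean_ra: float = 0.001,
    ):
        ab = abundance.drop_empty().values
        self.metadata = check_metadata(metadata, ab.index)
        self.abundance = ab
        self.panel = panel
        self.compartment = compartment
        self.min_mean_ra = min_mean_ra
        missing = [f for f in ab.columns if f not in panel.ids]
        if missing:
            raise KeyError(f"features missing from panel: {missing[:5]}")

    def _select(self, meta: pd.DataFrame) -> pd.DataFrame:
        mask = meta["compartment"] == self.compartment
        if "first_syncom" in meta.columns:
            mask &= meta["first_syncom"].isin(["mixed"]) | (
                meta["treatment"] == "competition"
            )
        return meta.loc[mask]

    def _picker(self, meta: pd.DataFrame):
        def pick(strain_host: str, sample_host: str) -> pd.Series:
            return meta["host_species"] == sample_host

        return pick

    def fit(self, alpha: float = 0.05) -> IndexResults:
        tables = []
        for exp, meta_exp in self.metadata.groupby("experiment"):
            meta_sel = self._select(meta_exp)
            meta_sel = meta_sel.loc[meta_sel.index.isin(self.abundance.index)]
            ab = self.abundance.loc[meta_sel.index]
            tables.append(
                _index_for_groups(
                    ab, meta_sel, self.panel, self._picker(meta_sel),
                    self.min_mean_ra, str(exp), self.index_col,
                )
            )
        table = _finalize(tables, self.index_col, alpha)
        return IndexResults(
            table=table,
            index_name=self.index_name,
            alpha=alpha,
            compartment=self.compartment,
            min_mean_ra=self.min_mean_ra,
            params=dict(model=type(self).__name__),
        )


class Invasiveness(HostPreference):
    """Model of per-strain invasiveness in sequential-inoculation designs.

    Only samples in which the strain's SynCom was the *second* (invading)
    inoculum enter the means: the index contrasts invasion success on the
    cognate host against the other host.
    """

    index_name = "Invasiveness index"
    index_col = "inv_index"

    def _select(self, meta: pd.DataFrame) -> pd.DataFrame:
        mask = (meta["compartment"] == self.compartment) & (
            meta["treatment"] == "sequential"
        )
        sub = meta.loc[mask]
        if sub.empty:
            raise ValueError("no sequential-inoculation samples in metadata")
        return sub

    def _picker(self, meta: pd.DataFrame):
        def pick(strain_host: str, sample_host: str) -> pd.Series:
            return (meta["host_species"] == sample_host) & (
                meta["second_syncom"] == strain_host
            )

        return pick


def correlate_indices(
    pref: IndexResults | pd.DataFrame,
    inv: IndexResults | pd.DataFrame,
    method: str = "pearson",
) -> dict:
    """Correlation between log2 host-preference and log2 invasiveness.

    Strains present (and passing the abundance filter) in both tables are
    matched by strain id and experiment.  Returns Pearson (or Spearman) r
    with its two-sided p from the t transform, the partial correlation
    controlling for log2 mean RA, and n.
    """
    pt = pref.passing() if isinstance(pref, IndexResults) else pref
    it = inv.passing() if isinstance(inv, IndexResults) else inv
    keys = ["strain_id", "experiment"]
    merged = pt.merge(it, on=keys, suffixes=("_pref", "_inv"))
    merged = merged.dropna(subset=["index_pref", "index_inv"])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 strains passing both filters, got {n}")
    x = np.log2(merged["index_pref"].to_numpy())
    y = np.log2(merged["index_inv"].to_numpy())
    mean_ra = merged[["mean_ra_cognate_pref", "mean_ra_other_pref",
                      "mean_ra_cognate_inv", "mean_ra_other_inv"]].mean(axis=1)
    z = np.log2(mean_ra.to_numpy())
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        rxz = stats.pearsonr(x, z)[0]
        ryz = stats.pearsonr(y, z)[0]
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        rxz = stats.spearmanr(x, z)[0]
        ryz = stats.spearmanr(y, z)[0]
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    denom = np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    partial = (r - rxz * ryz) / denom if denom > 0 else float("nan")
    return {
        "r": float(r),
        "p": float(p),
        "partial_r_given_meanRA": float(partial),
        "n": n,
        "method": method,
    }


def family_knockout(
    abundance: AbundanceTable,
    metadata: pd.DataFrame,
    panel: StrainPanel,
    compartment: str = "root",
) -> pd.DataFrame:
    """Robustness of community-level host preference to family removal.

    For each family in turn, its strains are removed, each sample is
    renormalized to sum 1, and per host the aggregated RA of native strains
    is compared against that of non-native strains (Mann–Whitney).  A
    baseline row (family "none") is included.  Families whose removal would
    leave no features are skipped.
    """
    ab = abundance.drop_empty()
    meta = check_metadata(metadata, ab.values.index)
    sel = meta.index[meta["compartment"] == compartment]
    values = ab.values.loc[ab.values.index.isin(sel)]
    if values.empty:
        raise ValueError(f"no samples in compartment {compartment!r}")
    families = ["none"] + sorted(pd.unique(panel.families))
    rows = []
    for family in families:
        if family == "none":
            keep = list(values.columns)
        else:
            keep = [c for c in values.columns if panel.families[c] != family]
        if not keep:
            continue  # removal would leave zero features
        sub = values[keep]
        totals = sub.sum(axis=1)
        nonzero = totals > 0
        renorm = sub.loc[nonzero].div(totals[nonzero], axis=0)
        agg = aggregate_by_origin(
            AbundanceTable(renorm, abundance.feature_kind), panel.subset(keep)
        )
        for host in HOSTS:
            hs = meta.loc[renorm.index, "host_species"] == host
            if not hs.any():
                continue
            native = agg.loc[hs.to_numpy(), f"{host}_derived_RA"].to_numpy()
            other = HOSTS[1] if host == HOSTS[0] else HOSTS[0]
            nonnative = agg.loc[hs.to_numpy(), f"{other}_derived_RA"].to_numpy()
            U, p = mann_whitney(native, nonnative)
            rows.append(
                dict(
                    family_removed=family,
                    host=host,
                    mean_native_ra=float(native.mean()),
                    mean_nonnative_ra=float(nonnative.mean()),
                    preference_direction=(
                        "native>nonnative" if native.mean() > nonnative.mean()
                        else "nonnative>=native"
                    ),
                    U=U,
                    p=p,
                )
            )
    return pd.DataFrame(rows)
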