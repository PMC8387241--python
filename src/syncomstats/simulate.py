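"""Generative models of gnotobiotic SynCom experiments.

The simulator emulates competition (mixed-community) and sequential
(invasion) inoculation experiments on two plant hosts.  Per sample, strain
weights are

    w_s = base_s * phi_s(host, compartment) * pi_s(inoculation order)

where ``base_s`` is a log-normal base abundance drawn once per experiment
and shared between the two members of a taxonomic family pair, ``phi_s`` is
a host-preference fold-factor applied to strains native to the sample's
host (in root samples; optionally rhizosphere; never in unplanted soil) and
``pi_s`` is a resident-advantage factor applied to first-arriving strains
in sequential designs.  Expected relative abundances are w / sum(w); counts
are Dirichlet–multinomial around that expectation, collapsing to plain
multinomial as the overdispersion concentration grows.

Amplicon reads and limiting-dilution culture plates (well x OTU tables) are
simulated from such count tables with the same seeding discipline: one
top-level seed, fixed sub-stream indices per module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import METADATA_COLUMNS, CountTable
from .panel import HOSTS, StrainPanel

__all__ = [
    "Host",
    "DesignSpec",
    "EffectSpec",
    "TruthRecord",
    "simulate_competition",
    "simulate_invasion",
    "simulate_reads",
    "simulate_irl_plates",
    "write_fastq_dir",
]


@dataclass(frozen=True)
class Host:
    species: str  # "Lj" or "At"
    genotype: str = "wt"

    def __post_init__(self):
        if self.species not in HOSTS:
            raise ValueError(f"unknown host species {self.species!r}")

    @property
    def label(self) -> str:
        return f"{self.species}.{self.genotype}"


@dataclass
class DesignSpec:
    """Experimental layout: hosts x compartments x replicates."""

    hosts: Sequence[Host] = (Host("Lj"), Host("At"))
    compartments: Sequence[str] = ("root", "rhizosphere", "soil")
    replicates_per_cell: int = 12
    treatment: str = "competition"  # or "sequential"
    resident_set: frozenset | None = None
    invader_set: frozenset | None = None
    experiment: str = "exp1"

    def __post_init__(self):
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.treatment not in ("competition", "sequential"):
            raise ValueError("treatment must be 'competition' or 'sequential'")
        bad = set(self.compartments) - {"root", "rhizosphere", "soil"}
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")
        if self.treatment == "sequential":
            if not self.resident_set or not self.invader_set:
                raise ValueError("sequential design needs resident and invader sets")
            self.resident_set = frozenset(self.resident_set)
            self.invader_set = frozenset(self.invader_set)
            if self.resident_set & self.invader_set:
                raise ValueError("resident and invader sets must be disjoint")


@dataclass
class EffectSpec:
    """Effect sizes and noise parameters of the generative model.

    phi_root / phi_rhizo : float or mapping strain_id -> float
        Host-preference fold-factor applied to a native strain's weight in
        root / rhizosphere samples of its cognate host (soil is neutral).
    nfr5_attenuation : float in [0, 1]
        For hosts whose genotype is in ``mutant_genotypes`` the effective
        preference factor becomes 1 + a*(phi - 1): a=1 keeps the wild-type
        preference, a=0 removes it.
    pi_priority : float
        Resident-advantage fold-factor on first-inoculated strains
        (sequential designs only).
    depth : int
        Sequencing reads per sample.
    overdispersion : float
        Dirichlet concentration; counts ~ Multinomial(depth, Dirichlet(
        overdispersion * expected_RA)).  Larger = closer to multinomial.
    base_sdlog : float
        sdlog of the log-normal base abundances (meanlog 0), drawn once per
        experiment and shared within each family pair.
    """

    phi_root: float | Mapping[str, float] = 4.0
    phi_rhizo: float | Mapping[str, float] = 1.0
    nfr5_attenuation: float = 0.5
    pi_priority: float = 3.0
    depth: int = 10_000
    overdispersion: float = 200.0
    base_sdlog: float = 1.0
    mutant_genotypes: tuple = ("nfr5",)

    def __post_init__(self):
        for name in ("phi_root", "phi_rhizo"):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, Mapping) else [val]
            if any((not math.isfinite(v)) or v < 0 for v in vals):
                raise ValueError(f"{name} factors must be finite and >= 0")
        if not 0 <= self.nfr5_attenuation <= 1:
            raise ValueError("nfr5_attenuation must be in [0, 1]")
        if not math.isfinite(self.pi_priority) or self.pi_priority < 0:
            raise ValueError("pi_priority must be finite and >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.overdispersion > 0:
            raise ValueError("overdispersion must be > 0")


@dataclass
class TruthRecord:
    """Realized ground truth of one simulated experiment."""

    expected_ra: pd.DataFrame  # samples x strains
    base_abundance: pd.Series  # per strain
    params: dict = field(default_factory=dict)

    def to_files(self, prefix: str) -> None:
        """Write ``<prefix>.params.txt`` (flat key: value) and
        ``<prefix>.expected_ra.tsv``."""
        with open(f"{prefix}.params.txt", "w") as fh:
            for k, v in self.params.items():
                fh.write(f"{k}: {v}\n")
            for sid, b in self.base_abundance.items():
                fh.write(f"base.{sid}: {b!r}\n")
        self.expected_ra.rename_axis("sample_id").to_csv(
            f"{prefix}.expected_ra.tsv", sep="\t"
        )

    @classmethod
    def from_files(cls, prefix: str) -> "TruthRecord":
        params: dict = {}
        base: dict = {}
        with open(f"{prefix}.params.txt") as fh:
            for line in fh:
                key, _, val = line.rstrip("\n").partition(": ")
                if key.startswith("base."):
                    base[key[5:]] = float(val)
                else:
                    params[key] = _coerce(val)
        expected = pd.read_csv(f"{prefix}.expected_ra.tsv", sep="\t",
                               index_col="sample_id")
        return cls(expected, pd.Series(base, name="base_abundance"), params)


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _draw_bases(panel: StrainPanel, rng: np.random.Generator, sdlog: float) -> pd.Series:
    """Log-normal base abundances, one draw per family shared by the pair."""
    families = pd.unique(panel.families)
    fam_base = dict(zip(families, np.exp(rng.normal(0.0, sdlog, size=len(families)))))
    return pd.Series([fam_base[f] for f in panel.families], index=panel.ids,
                     name="base_abundance")


def _phi_vector(phi, panel: StrainPanel) -> np.ndarray:
    if isinstance(phi, Mapping):
        missing = set(panel.ids) - set(phi)
        if missing:
            raise ValueError(f"phi mapping missing strains: {sorted(missing)[:5]}")
        return np.array([float(phi[s]) for s in panel.ids])
    return np.full(len(panel), float(phi))


def _preference_weights(
    panel: StrainPanel,
    host: Host,
    compartment: str,
    effects: EffectSpec,
) -> np.ndarray:
    """Per-strain host-preference factor for one sample cell."""
    if compartment == "root":
        phi = _phi_vector(effects.phi_root, panel)
    elif compartment == "rhizosphere":
        phi = _phi_vector(effects.phi_rhizo, panel)
    else:  # unplanted soil is neutral
        return np.ones(len(panel))
    if host.genotype in effects.mutant_genotypes:
        phi = 1.0 + effects.nfr5_attenuation * (phi - 1.0)
    native = (panel.host_of_origin == host.species).to_numpy()
    return np.where(native, phi, 1.0)


def _sample_counts(
    expected: np.ndarray,
    depth: int,
    concentration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    alpha = concentration * expected
    # Dirichlet draws need strictly positive alphas; zero-expectation strains
    # stay at zero counts.
    pos = alpha > 0
    p = np.zeros_like(expected)
    if pos.any():
        p[pos] = rng.dirichlet(alpha[pos])
    return rng.multinomial(depth, p)


def _emit_samples(
    panel: StrainPanel,
    design: DesignSpec,
    effects: EffectSpec,
    bases: pd.Series,
    arms: Sequence[tuple[str, str, str, frozenset | None]],
    rng: np.random.Generator,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame]:
    """Generate counts/metadata/expected-RA for every host x compartment x
    replicate cell of each arm.  An arm is (treatment, first, second,
    priority_set)."""
    base = bases.to_numpy()
    rows, meta_rows, expected_rows, sample_ids = [], [], [], []
    for treatment, first, second, priority_set in arms:
        prio = np.array(
            [effects.pi_priority if (priority_set and s in priority_set) else 1.0
             for s in panel.ids]
        )
        for host in design.hosts:
            for compartment in design.compartments:
                w = base * prio * _preference_weights(panel, host, compartment, effects)
                total = w.sum()
                if total <= 0:
                    raise ValueError("all strain weights are zero")
                expected = w / total
                for rep in range(1, design.replicates_per_cell + 1):
                    sid = (f"{design.experiment}.{host.label}.{compartment}."
                           f"{first}first.r{rep:02d}")
                    counts = _sample_counts(expected, effects.depth,
                                            effects.overdispersion, rng)
                    rows.append(counts)
                    expected_rows.append(expected)
                    sample_ids.append(sid)
                    meta_rows.append(
                        dict(
                            sample_id=sid,
                            compartment=compartment,
                            host_species=host.species,
                            host_genotype=host.genotype,
                            treatment=treatment,
                            first_syncom=first,
                            second_syncom=second,
                            experiment=design.experiment,
                            replicate=rep,
                        )
                    )
    counts_df = pd.DataFrame(np.array(rows, dtype=np.int64), index=sample_ids,
                             columns=panel.ids)
    counts_df.index.name = "sample_id"
    metadata = (pd.DataFrame(meta_rows).set_index("sample_id")
                .loc[:, list(METADATA_COLUMNS)])
    expected_df = pd.DataFrame(np.array(expected_rows), index=sample_ids,
                               columns=panel.ids)
    return CountTable(counts_df, "strain"), metadata, expected_df


def _truth_params(design: DesignSpec, effects: EffectSpec, seed: int) -> dict:
    phi_root = effects.phi_root
    params = dict(
        treatment=design.treatment,
        experiment=design.experiment,
        replicates_per_cell=design.replicates_per_cell,
        depth=effects.depth,
        overdispersion=effects.overdispersion,
        phi_root=(phi_root if not isinstance(phi_root, Mapping) else "per-strain"),
        phi_rhizo=(effects.phi_rhizo
                   if not isinstance(effects.phi_rhizo, Mapping) else "per-strain"),
        nfr5_attenuation=effects.nfr5_attenuation,
        pi_priority=effects.pi_priority,
        base_sdlog=effects.base_sdlog,
        seed=seed,
    )
    return params


def simulate_competition(
    panel: StrainPanel,
    design: DesignSpec,
    effects: EffectSpec,
    seed: int = 0,
) -> tuple[CountTable, pd.DataFrame, TruthRecord]:
    """Simulate a mixed-community competition experiment.

    All strains are co-inoculated; native strains receive the preference
    factor on their cognate host's root (and optionally rhizosphere).
    Returns counts, per-sample metadata and the realized ground truth.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    if design.treatment != "competition":
        raise ValueError("design.treatment must be 'competition'")
    rng = _rng(seed, 1)
    bases = _draw_bases(panel, rng, effects.base_sdlog)
    arms = [("competition", "mixed", "mock", None)]
    counts, metadata, expected = _emit_samples(panel, design, effects, bases,
                                               arms, rng)
    truth = TruthRecord(expected, bases, _truth_params(design, effects, seed))
    return counts, metadata, truth


def simulate_invasion(
    panel: StrainPanel,
    design: DesignSpec,
    effects: EffectSpec,
    seed: int = 0,
) -> tuple[CountTable, pd.DataFrame, TruthRecord]:
    """Simulate a sequential-inoculation (invasion) experiment.

    Emits, for every host x compartment x replicate cell, three arms:
    resident-set first (invader set arrives second), invader-set first
    (roles swapped) and a mixed-community control where both sets arrive
    together.  First-arriving strains' weights are multiplied by
    ``pi_priority``; host-preference factors apply as in competition.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    if design.treatment != "sequential":
        raise ValueError("design.treatment must be 'sequential'")
    covered = design.resident_set | design.invader_set
    if covered != set(panel.ids):
        raise ValueError("resident and invader sets must partition the panel")

    def syncom_label(ids: frozenset) -> str:
        hosts = set(panel.host_of_origin.loc[list(ids)])
        return hosts.pop() if len(hosts) == 1 else "custom"

    res_label = syncom_label(design.resident_set)
    inv_label = syncom_label(design.invader_set)
    rng = _rng(seed, 2)
    bases = _draw_bases(panel, rng, effects.base_sdlog)
    arms = [
        ("sequential", res_label, inv_label, design.resident_set),
        ("sequential", inv_label, res_label, design.invader_set),
        ("competition", "mixed", "mock", None),
    ]
    counts, metadata, expected = _emit_samples(panel, design, effects, bases,
                                               arms, rng)
    params = _truth_params(design, effects, seed)
    params["resident_set"] = ",".join(sorted(design.resident_set))
    params["invader_set"] = ",".join(sorted(design.invader_set))
    truth = TruthRecord(expected, bases, params)
    return counts, metadata, truth


def simulate_reads(
    table: CountTable,
    panel: StrainPanel,
    sub_error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Emit per-sample amplicon reads from a strain count table.

    Exactly ``counts[sample, strain]`` copies of each strain's reference are
    emitted per sample; each position is substituted independently at
    ``sub_error_rate``.  Returns {sample_id: [(read_id, sequence), ...]}.
    """
    if table.feature_kind != "strain":
        raise ValueError("read simulation requires a strain-level count table")
    unknown = set(table.feature_ids) - set(panel.ids)
    if unknown:
        raise KeyError(f"features without a reference sequence: {sorted(unknown)[:5]}")
    if not 0 <= sub_error_rate < 1:
        raise ValueError("sub_error_rate must be in [0, 1)")
    rng = _rng(seed, 3)
    refs = {s: np.frombuffer(panel.ref_seqs[s].encode(), dtype="S1")
            for s in table.feature_ids}
    out: dict[str, list[tuple[str, str]]] = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for sid in table.sample_ids:
        reads: list[tuple[str, str]] = []
        idx = 0
        for strain in table.feature_ids:
            n = int(table.counts.at[sid, strain])
            if n == 0:
                continue
            ref = refs[strain]
            block = np.tile(ref, (n, 1))
            if sub_error_rate > 0:
                mask = rng.random(block.shape) < sub_error_rate
                n_err = int(mask.sum())
                if n_err:
                    # substitute with one of the three other bases
                    offsets = rng.integers(1, 4, size=n_err)
                    cur = np.searchsorted(bases, block[mask])
                    block[mask] = bases[(cur + offsets) % 4]
            for r in range(n):
                idx += 1
                reads.append((f"{sid}.read{idx:06d}",
                              block[r].tobytes().decode("ascii")))
        out[sid] = reads
    return out


def write_fastq_dir(reads: Mapping[str, list[tuple[str, str]]], outdir,
                    quality_char: str = "I") -> None:
    """Write one 4-line-record FASTQ per sample into *outdir*."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for sid, recs in reads.items():
        with open(os.path.join(outdir, f"{sid}.fastq"), "w") as fh:
            for rid, seq in recs:
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def simulate_irl_plates(
    community_ra: pd.Series,
    n_wells: int,
    cells_per_well_mean: float,
    reads_per_well: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate limiting-dilution culture plates (wells x OTUs counts).

    Each well receives Poisson(cells_per_well_mean) founder cells drawn from
    the community profile; well reads are multinomial over the founders'
    OTUs.  Empty wells yield all-zero rows.
    """
    total = float(community_ra.sum())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("community_ra must sum to 1")
    if n_wells < 0:
        raise ValueError("n_wells must be >= 0")
    if not cells_per_well_mean > 0:
        raise ValueError("cells_per_well_mean must be > 0")
    rng = _rng(seed, 4)
    otus = list(community_ra.index)
    p = community_ra.to_numpy()
    rows = np.zeros((n_wells, len(otus)), dtype=np.int64)
    for w in range(n_wells):
        n_cells = rng.poisson(cells_per_well_mean)
        if n_cells == 0:
            continue
        founders = rng.multinomial(n_cells, p)
        founder_p = founders / n_cells
        rows[w] = rng.multinomial(reads_per_well, founder_p)
    # 96-well plate coordinates: plateN:RowCol with rows A-H, columns 1-12
    names = [
        f"plate{w // 96 + 1}:{chr(65 + (w % 96) // 12)}{(w % 96) % 12 + 1}"
        for w in range(n_wells)
    ]
    wells = pd.DataFrame(rows, index=names, columns=otus)
    wells.index.name = "well"
    return wells
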