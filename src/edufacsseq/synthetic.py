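"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of an EdU-click FACS-Seq
experiment so that every analysis stage is testable without any download:

* flow cytometry: per-population bivariate log-normal fluorescence (debris,
  unlabeled and labeled/high-APC cells on log-decade axes), paired +EdU /
  no-EdU acquisitions, and rare Poisson background events in the controls;
* community fraction tables: multinomial counts at a fixed depth for the six
  sorted/unsorted fractions, with a replicating taxon subset enriched in the
  EdU-positive fraction, rare-taxon dropout on incubation, and
  sorter-sheath contaminant taxa present only in sheath and sorted samples;
* growth curves: logistic/Gompertz/linear/constant OD600 series at 15-minute
  sampling with i.i.d. Gaussian noise;
* genome KO sets that complete exactly a requested subset of the packaged
  pyrimidine pathway rules, plus decoy KOs that never complete another one.

Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

from .filtering import FeatureTable
from .gating import EVENT_COLUMNS, FlowEventTable
from .growth import GrowthCurve
from .pathways import GenomeAnnotation, PathwayRule, builtin_rules

__all__ = [
    "PopulationParams",
    "FlowSimConfig",
    "MockMember",
    "CommunitySimConfig",
    "GrowthSimConfig",
    "simulate_flow_pair",
    "simulate_mock_community",
    "perturb_events",
    "simulate_fraction_tables",
    "simulate_tree",
    "simulate_growth",
    "simulate_genome_kos",
]

CHANNELS = EVENT_COLUMNS  # fitc, apc, fsc, ssc


@dataclass(frozen=True)
class PopulationParams:
    """Location/scale of log10 intensity per channel for one population."""

    loc: dict
    scale: dict

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if ch not in self.loc or ch not in self.scale:
                raise ValueError(f"population params missing channel {ch!r}")
            if self.scale[ch] <= 0:
                raise ValueError("population scales must be > 0")


def _pop(fitc, apc, fsc=2.8, ssc=2.7, scale=0.25) -> PopulationParams:
    return PopulationParams(
        loc={"fitc": fitc, "apc": apc, "fsc": fsc, "ssc": ssc},
        scale={ch: scale for ch in CHANNELS},
    )


def default_populations() -> dict:
    """Debris at low FITC; unlabeled cells stained (high FITC, low APC);
    labeled cells additionally >= 2 log-decades up in APC."""
    return {
        "debris": _pop(fitc=1.0, apc=0.8, fsc=2.0, ssc=2.0, scale=0.3),
        "unlabeled": _pop(fitc=3.5, apc=1.0),
        "labeled": _pop(fitc=3.5, apc=3.5),
    }


@dataclass
class FlowSimConfig:
    """Parameters of a paired +EdU / no-EdU acquisition simulation."""

    n_events: int = 50_000
    labeled_fraction: float = 0.3
    pop_params: dict = field(default_factory=default_populations)
    background_q2_rate: float = 5.0
    debris_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must be in [0, 1)")
        if self.background_q2_rate < 0:
            raise ValueError("background_q2_rate must be >= 0")
        for name in ("debris", "unlabeled", "labeled"):
            if name not in self.pop_params:
                raise ValueError(f"pop_params missing population {name!r}")


def _draw_population(rng, params: PopulationParams, n: int) -> pd.DataFrame:
    cols = {
        ch: 10.0 ** rng.normal(params.loc[ch], params.scale[ch], size=n)
        for ch in CHANNELS
    }
    return pd.DataFrame(cols)


def _assemble(rng, frames) -> pd.DataFrame:
    df = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(df))  # acquisition order carries no structure
    return df.iloc[order].reset_index(drop=True)


def simulate_flow_pair(cfg: FlowSimConfig) -> tuple[FlowEventTable, FlowEventTable]:
    """A (+EdU, no-EdU) pair of event tables from one configuration.

    The +EdU table draws ``labeled_fraction`` of its stained (non-debris)
    events from the labeled population. The no-EdU table has no labeled
    population but carries Poisson(``background_q2_rate``) spurious high-APC
    events — the background the gating pipeline must subtract.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_plus, rng_minus = (np.random.default_rng(s) for s in root.spawn(2))
    pops = cfg.pop_params

    n_debris = int(rng_plus.binomial(cfg.n_events, cfg.debris_fraction))
    n_cells = cfg.n_events - n_debris
    n_labeled = int(rng_plus.binomial(n_cells, cfg.labeled_fraction))
    plus = _assemble(
        rng_plus,
        [
            _draw_population(rng_plus, pops["debris"], n_debris),
            _draw_population(rng_plus, pops["unlabeled"], n_cells - n_labeled),
            _draw_population(rng_plus, pops["labeled"], n_labeled),
        ],
    )

    n_debris_m = int(rng_minus.binomial(cfg.n_events, cfg.debris_fraction))
    n_bg = int(rng_minus.poisson(cfg.background_q2_rate))
    minus = _assemble(
        rng_minus,
        [
            _draw_population(rng_minus, pops["debris"], n_debris_m),
            _draw_population(rng_minus, pops["unlabeled"], cfg.n_events - n_debris_m),
            _draw_population(rng_minus, pops["labeled"], n_bg),
        ],
    )
    plus_tbl = FlowEventTable(plus, sample_id="sim+EdU", edu_present=True)
    minus_tbl = FlowEventTable(minus, sample_id="sim-EdU", edu_present=False)
    return plus_tbl, minus_tbl


@dataclass(frozen=True)
class MockMember:
    """One isolate of a simulated mock community."""

    name: str
    fraction: float
    labeled: bool
    fitc_loc: float = 3.5
    apc_loc_labeled: float = 3.5
    apc_loc_unlabeled: float = 1.0
    scale: float = 0.25


def default_mock_members() -> list[MockMember]:
    """Five equal-abundance members, three of which label with EdU."""
    return [
        MockMember("member_ecoli", 0.2, True, fitc_loc=3.6),
        MockMember("member_efaecalis", 0.2, True, fitc_loc=3.4),
        MockMember("member_pintermedia", 0.2, True, fitc_loc=3.5),
        MockMember("member_bfragilis", 0.2, False, fitc_loc=3.5),
        MockMember("member_binfantis", 0.2, False, fitc_loc=3.4),
    ]


def simulate_mock_community(
    n_events: int = 50_000,
    members: list[MockMember] | None = None,
    debris_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[FlowEventTable, FlowEventTable]:
    """A (+EdU, no-EdU control) pair for a multi-member mock community.

    In the +EdU table, members flagged ``labeled`` sit in the high-APC
    population; in the control nobody does.
    """
    members = default_mock_members() if members is None else members
    fr = np.array([m.fraction for m in members], float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("member fractions must sum to 1")
    root = np.random.SeedSequence(seed)
    tables = []
    for edu, sub in zip((True, False), root.spawn(2)):
        rng = np.random.default_rng(sub)
        n_debris = int(rng.binomial(n_events, debris_fraction))
        counts = rng.multinomial(n_events - n_debris, fr)
        frames = [
            _draw_population(
                rng, _pop(fitc=1.0, apc=0.8, fsc=2.0, ssc=2.0, scale=0.3), n_debris
            )
        ]
        for m, n in zip(members, counts):
            apc_loc = m.apc_loc_labeled if (edu and m.labeled) else m.apc_loc_unlabeled
            frames.append(
                _draw_population(
                    rng,
                    _pop(fitc=m.fitc_loc, apc=apc_loc, scale=m.scale),
                    int(n),
                )
            )
        tables.append(
            FlowEventTable(
                _assemble(rng, frames),
                sample_id=f"mock{'+' if edu else '-'}EdU",
                edu_present=edu,
            )
        )
    return tables[0], tables[1]


def perturb_events(tbl: FlowEventTable, noise_sd: float, seed: int) -> FlowEventTable:
    """Re-measurement noise: jitter each intensity by N(0, noise_sd) in
    log10 space, emulating re-acquisition of sorted cells."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    vals = tbl.events[list(CHANNELS)].to_numpy(float)
    jittered = 10.0 ** (np.log10(np.maximum(vals, np.finfo(float).tiny))
                        + rng.normal(0.0, noise_sd, size=vals.shape))
    out = pd.DataFrame(jittered, columns=list(CHANNELS))
    return FlowEventTable(
        out,
        sample_id=tbl.sample_id + "_reacquired",
        edu_present=tbl.edu_present,
        replicate=tbl.replicate,
        dilution=tbl.dilution,
    )


# ---------------------------------------------------------------------------
# community fraction tables

def _default_base_abundance(n_taxa: int) -> np.ndarray:
    # geometric-series rank abundance: a few dominant genera, a rare tail,
    # the shape typical of fecal 16S profiles
    ranks = np.arange(n_taxa)
    p = 0.75 ** ranks
    return p / p.sum()


def _default_weights(n_taxa: int) -> np.ndarray:
    # most taxa replicate at baseline; one abundant and one rare taxon
    # replicate much faster (the Ileibacterium / Prevotella UCG-001 pattern)
    w = np.ones(n_taxa)
    if n_taxa >= 2:
        w[1] = 8.0
    if n_taxa >= 12:
        w[11] = 8.0
    return w


@dataclass
class CommunitySimConfig:
    """Parameters of the fraction-structured community simulation."""

    n_taxa: int = 40
    base_abundance: np.ndarray | None = None
    replication_weights: np.ndarray | None = None
    incubation_loss_rate: float = 0.5
    rare_threshold: float = 0.005
    contaminant_taxa: dict | None = None        # name -> sheath rel. abundance
    contaminant_in_sorted: float = 0.02         # reads routed to contaminants
    sheath_carryover: float = 0.1               # community reads in sheath
    depth_per_sample: int = 20_000
    n_replicates: int = 3
    n_experiments: int = 1
    experiment_jitter_sd: float = 0.3           # log-normal cohort variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be > 0")
        if self.base_abundance is None:
            self.base_abundance = _default_base_abundance(self.n_taxa)
        self.base_abundance = np.asarray(self.base_abundance, float)
        if len(self.base_abundance) != self.n_taxa:
            raise ValueError("base_abundance length must equal n_taxa")
        if not np.isclose(self.base_abundance.sum(), 1.0, atol=1e-9):
            raise ValueError("base_abundance must sum to 1")
        if self.replication_weights is None:
            self.replication_weights = _default_weights(self.n_taxa)
        self.replication_weights = np.asarray(self.replication_weights, float)
        if len(self.replication_weights) != self.n_taxa:
            raise ValueError("replication_weights length must equal n_taxa")
        if np.any(self.replication_weights < 0):
            raise ValueError("replication weights must be >= 0")
        if not np.any(self.replication_weights > 0):
            raise ValueError("at least one taxon must have replication weight > 0")
        if not 0.0 <= self.incubation_loss_rate <= 1.0:
            raise ValueError("incubation_loss_rate must be in [0, 1]")
        if self.contaminant_taxa is None:
            self.contaminant_taxa = {"contam_01": 0.5, "contam_02": 0.3, "contam_03": 0.2}
        self.taxa = [f"taxon_{i + 1:02d}" for i in range(self.n_taxa)]
        overlap = set(self.contaminant_taxa) & set(self.taxa)
        if overlap:
            raise ValueError(f"contaminant ids collide with taxa: {sorted(overlap)}")


def simulate_fraction_tables(cfg: CommunitySimConfig) -> FeatureTable:
    """Multinomial count tables for all six fractions of each experiment.

    Composition model per experiment: the initial (unsorted) community is the
    base abundance (jittered between experiments); incubation drops each taxon
    rarer than ``rare_threshold`` with probability ``incubation_loss_rate``;
    the whole incubated community and the EdU-negative fraction share the
    incubated composition; the EdU-positive composition is the incubated
    composition re-weighted by the replication weights. Sorted samples carry a
    small contaminant admixture; the sheath sample is contaminant-dominated
    with a small community carryover; the unsorted initial sample has no
    contaminants at all.
    """
    rng = np.random.default_rng(cfg.seed)
    contam_names = list(cfg.contaminant_taxa)
    contam_p = np.asarray([cfg.contaminant_taxa[c] for c in contam_names], float)
    contam_p = contam_p / contam_p.sum()
    features = cfg.taxa + contam_names
    n_c = len(contam_names)

    def pad(community_p: np.ndarray, contaminated: bool) -> np.ndarray:
        full = np.zeros(len(features))
        if contaminated and n_c:
            full[: cfg.n_taxa] = (1 - cfg.contaminant_in_sorted) * community_p
            full[cfg.n_taxa:] = cfg.contaminant_in_sorted * contam_p
        else:
            full[: cfg.n_taxa] = community_p
        return full

    rows, meta_rows = [], []

    def add(sample_id, fraction, experiment, p):
        rows.append(rng.multinomial(cfg.depth_per_sample, p / p.sum()))
        meta_rows.append(
            {
                "sample_id": sample_id,
                "fraction": fraction,
                "experiment": experiment,
                "treatment": "none",
                "replicate": sample_id.rsplit("_", 1)[-1],
            }
        )

    for e in range(cfg.n_experiments):
        exp = f"exp{e + 1}"
        base = cfg.base_abundance * np.exp(
            rng.normal(0.0, cfg.experiment_jitter_sd, cfg.n_taxa)
            if cfg.n_experiments > 1
            else np.zeros(cfg.n_taxa)
        )
        base = base / base.sum()
        # incubation: rare-taxon dropout
        rare = base < cfg.rare_threshold
        lost = rare & (rng.random(cfg.n_taxa) < cfg.incubation_loss_rate)
        incubated = np.where(lost, 0.0, base)
        incubated = incubated / incubated.sum()
        edu_pos = incubated * cfg.replication_weights
        if edu_pos.sum() == 0:
            edu_pos = incubated.copy()  # nothing replicating survived incubation
        edu_pos = edu_pos / edu_pos.sum()

        for r in range(cfg.n_replicates):
            rep = f"r{r + 1}"
            add(f"{exp}_initial_unsorted_{rep}", "initial_unsorted", exp, pad(base, False))
            add(f"{exp}_initial_sorted_{rep}", "initial_sorted", exp, pad(base, True))
            add(f"{exp}_whole_{rep}", "whole", exp, pad(incubated, True))
            add(f"{exp}_edu_neg_{rep}", "edu_neg", exp, pad(incubated, True))
            add(f"{exp}_edu_pos_{rep}", "edu_pos", exp, pad(edu_pos, True))
        sheath_p = np.zeros(len(features))
        sheath_p[: cfg.n_taxa] = cfg.sheath_carryover * incubated
        sheath_p[cfg.n_taxa:] = (1 - cfg.sheath_carryover) * contam_p
        add(f"{exp}_sheath_r1", "sheath", exp, sheath_p)

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = pd.DataFrame(rows, index=meta.index, columns=features)
    return FeatureTable(counts, meta)


def simulate_tree(feature_ids, seed: int = 0, mean_branch_length: float = 0.5) -> TreeNode:
    """A random bifurcating tree over the given features, with exponential
    branch lengths — a stand-in phylogeny for weighted UniFrac."""
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    nodes = [f"{name}:{rng.exponential(mean_branch_length):.6f}" for name in feature_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(mean_branch_length):.6f}")
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return TreeNode.read(StringIO(newick), convert_underscores=False)


# ---------------------------------------------------------------------------
# growth curves

GROWTH_MODELS = ("logistic", "gompertz", "linear", "constant")


@dataclass
class GrowthSimConfig:
    """OD600 curve simulation at plate-reader cadence (default 15 min)."""

    model: str = "logistic"
    carrying_capacity: float = 1.0   # K, OD units
    rate: float = 0.8                # r, 1/h (OD/h for the linear model)
    inflection_time: float = 5.0     # t0, h
    baseline: float = 0.05           # y0, OD
    noise_sd: float = 0.0            # OD
    timestep: float = 0.25           # h
    duration: float = 24.0           # h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in GROWTH_MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {GROWTH_MODELS}")
        if not self.carrying_capacity > self.baseline >= 0:
            raise ValueError("need K > y0 >= 0")
        if self.rate < 0 or self.timestep <= 0 or self.duration <= 0:
            raise ValueError("rate >= 0 and timestep, duration > 0 required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_growth(cfg: GrowthSimConfig) -> GrowthCurve:
    """A seeded OD600 time series for the configured growth model."""
    t = np.arange(0.0, cfg.duration + cfg.timestep / 2, cfg.timestep)
    k, r, t0, y0 = cfg.carrying_capacity, cfg.rate, cfg.inflection_time, cfg.baseline
    if cfg.model == "logistic":
        y = y0 + (k - y0) / (1.0 + np.exp(-r * (t - t0)))
    elif cfg.model == "gompertz":
        y = y0 + (k - y0) * np.exp(-np.exp(-r * (t - t0)))
    elif cfg.model == "linear":
        y = y0 + r * t
    else:
        y = np.full_like(t, y0)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    return GrowthCurve(times=t, od=y)


# ---------------------------------------------------------------------------
# genome KO sets

def simulate_genome_kos(
    include_modules,
    extra_kos: int = 0,
    seed: int = 0,
    rules: list[PathwayRule] | None = None,
    genome_id: str = "sim_genome",
) -> GenomeAnnotation:
    """A KO set completing exactly the requested pathway rules.

    One KO is chosen at random from each OR-group of each requested rule;
    ``extra_kos`` decoy ids are added from outside every rule's KO universe,
    so an unrequested rule can only complete through KOs shared with a
    requested one (K00940/K00943 overlap salvage and the deoxyribonucleoside
    rule, but neither completes the other alone).
    """
    rules = builtin_rules() if rules is None else rules
    by_name = {r.name: r for r in rules}
    unknown = set(include_modules) - set(by_name)
    if unknown:
        raise ValueError(f"unknown module name(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    kos: set[str] = set()
    for name in sorted(include_modules):
        for group in by_name[name].groups:
            kos.add(rng.choice(sorted(group)))
    forbidden = frozenset().union(*(r.all_kos for r in rules))
    n_added = 0
    while n_added < extra_kos:
        candidate = f"K{rng.integers(20000, 100000):05d}"
        if candidate not in forbidden and candidate not in kos:
            kos.add(candidate)
            n_added += 1
    return GenomeAnnotation(genome_id, kos)
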