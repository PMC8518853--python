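"""Synthetic diet-metabarcoding datasets with recorded ground truth.

The generator emulates the sampling design the analysis assumes: three
predator species occupying nine maternity colonies (5/2/2), sampled on 11
dates spanning mid-April to early October; every colony/date yields one
"community" sample pooling 15-20 faecal pellets, and one colony per species
additionally yields six replicate "smaller" samples of 1-3 pellets each.

Each pellet from a colony of species s at date t contains prey i with
probability

    logistic( alpha_i + phi_i(t) + sum_m B[s, m] * Q[i, m] ),

where alpha_i is a per-prey baseline detectability, phi_i(t) a Gaussian
seasonal phenology bump in date index, Q the prey trait matrix and B a
species x trait preference matrix in log-odds units (the planted effects
parameter-recovery tests must detect).  A sample detects the union of its
pellets' prey; read counts per detection are negative binomial, and
low-read noise detections plus flagged contaminant/coprophage/secondary-
prey/predator-DNA MOTUs are mixed in to exercise the curation stage.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    HABITAT_CLASSES,
    SPECIES,
    DetectionTable,
    MotuAssignment,
    assign_season,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate",
    "worked_example",
    "TRAIT_NAMES",
]

#: 17 binary habitat traits (two correlated blocks: closed- vs open-habitat),
#: plus ordinal size and the night-flying flag.
CLOSED_TRAITS = (
    "closed_habitats",
    "woodlands_forests",
    "hedgerows",
    "shrublands",
    "urban_areas",
    "semi_open_habitats",
    "lowlands",
    "cultivated_lands",
)
OPEN_TRAITS = (
    "ubiquitous",
    "mesophilous_areas",
    "dry_areas",
    "screes",
    "mountainous_areas",
    "slopes",
    "lawns",
    "meadows",
    "open_habitats",
)
TRAIT_NAMES = CLOSED_TRAITS + OPEN_TRAITS + ("size", "night_flying")

#: Arthropod orders and sampling weights for synthetic taxonomy assignment,
#: lepidopteran- and dipteran-dominated like a long-eared bat prey spectrum.
_ORDERS = (
    ("Lepidoptera", 0.55),
    ("Diptera", 0.27),
    ("Coleoptera", 0.06),
    ("Hemiptera", 0.04),
    ("Hymenoptera", 0.03),
    ("Neuroptera", 0.02),
    ("Araneae", 0.02),
    ("Orthoptera", 0.01),
)

#: Baseline detectability offsets (log-odds) by prey order: moths dominate
#: the diet of long-eared bats, dipterans come second, everything else is
#: occasional.
_ORDER_BASELINE_OFFSET = {"Lepidoptera": 0.0, "Diptera": -1.0}
_OTHER_ORDER_OFFSET = -1.7


@dataclass
class GeneratorConfig:
    """Study-design and effect parameters of the synthetic generator.

    Defaults mirror the emulated field design: 400 candidate prey, colonies
    split 5/2/2 across the three predator species, 11 sampling dates, and
    the community/smaller pellet-pooling scheme.  ``planted_effects`` lists
    (species, trait, log_odds) preference effects forming the B matrix; the
    default plants a +1.5 log-odds closed-habitat preference for auritus
    and an open-habitat preference for macrobullaris, the effect size at
    which the recovery tests are run.
    """

    n_prey: int = 400
    colonies_per_species: tuple = (5, 2, 2)
    n_dates: int = 11
    start_date: _dt.date = _dt.date(2015, 4, 20)
    date_step_days: int = 17
    community_pellets: tuple = (15, 20)
    smaller_pellets: tuple = (1, 3)
    smaller_replicates: int = 6
    planted_effects: tuple = (
        ("auritus", "closed_habitats", 1.5),
        ("macrobullaris", "open_habitats", 1.5),
    )
    baseline_mean: float = -4.0
    baseline_sd: float = 1.3
    phenology_amplitude: float = 2.0
    phenology_width: tuple = (1.5, 3.0)
    reads_mean: float = 300.0
    reads_dispersion: float = 1.0
    noise_motus: int = 30
    noise_rate: float = 3.0
    rare_motus: int = 8
    n_contaminant: int = 12
    n_coprophage: int = 4
    n_secondary_prey: int = 3
    n_predator_dna: int = 2
    n_no_match: int = 10
    flagged_prevalence: float = 0.08
    trait_block_scale: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prey < 2 or self.n_dates < 1:
            raise ValueError("n_prey and n_dates must be positive")
        if len(self.colonies_per_species) != len(SPECIES):
            raise ValueError("colonies_per_species must have one entry "
                             "per predator species")
        for sp, trait, _ in self.planted_effects:
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r} in planted_effects")
            if trait not in TRAIT_NAMES:
                raise ValueError(f"unknown trait {trait!r} in planted_effects")

    @property
    def dates(self) -> list[_dt.date]:
        return [
            self.start_date + _dt.timedelta(days=self.date_step_days * i)
            for i in range(self.n_dates)
        ]

    def effect_matrix(self) -> pd.DataFrame:
        B = pd.DataFrame(
            0.0, index=list(SPECIES), columns=list(TRAIT_NAMES)
        )
        for sp, trait, eff in self.planted_effects:
            B.loc[sp, trait] += eff
        return B


@dataclass
class GroundTruth:
    """Everything needed to recompute the generator's expected values."""

    B: pd.DataFrame
    phenology_mu: pd.Series
    phenology_sigma: pd.Series
    baseline: pd.Series
    habitat: pd.DataFrame
    pellet_prey_sets: dict = field(repr=False, default_factory=dict)


@dataclass
class SimulatedDataset:
    """A full synthetic pipeline input bundle."""

    table: DetectionTable
    traits: pd.DataFrame
    habitat: pd.DataFrame
    assignments: dict
    truth: GroundTruth
    config: GeneratorConfig


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _nb_reads(rng: np.random.Generator, n: int, mean: float,
              dispersion: float) -> np.ndarray:
    """Negative binomial reads per detection, shifted to be >= 1."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n) + 1


def _trait_matrix(rng: np.random.Generator, prey_ids: list[str],
                  scale: float) -> pd.DataFrame:
    """Correlated Bernoulli trait blocks: closed-habitat traits positively
    correlated with each other, open-habitat traits likewise, and the two
    blocks negatively correlated through a shared latent axis."""
    n = len(prey_ids)
    latent = rng.normal(size=n)
    cols = {}
    for t in CLOSED_TRAITS:
        a = rng.normal(-0.3, 0.4)
        cols[t] = (rng.random(n) < _logistic(a + scale * latent)).astype(int)
    for t in OPEN_TRAITS:
        a = rng.normal(-0.3, 0.4)
        cols[t] = (rng.random(n) < _logistic(a - scale * latent)).astype(int)
    cols["size"] = rng.integers(1, 4, size=n)
    cols["night_flying"] = (rng.random(n) < 0.8).astype(int)
    return pd.DataFrame(cols, index=prey_ids)


def _habitat_table(rng: np.random.Generator,
                   colonies: Mapping[str, str]) -> pd.DataFrame:
    """Colony habitat compositions: Dirichlet rows whose concentration
    depends on the resident species (auritus near forest, macrobullaris
    near grasslands, austriacus intermediate/farmland)."""
    base = {
        "auritus": np.array([2.0, 1.0, 1.5, 1.0, 4.0, 1.5]),
        "austriacus": np.array([2.5, 1.0, 1.5, 1.5, 1.5, 3.0]),
        "macrobullaris": np.array([1.0, 1.0, 1.5, 4.0, 2.0, 1.5]),
    }
    rows = {
        cid: rng.dirichlet(base[sp] * 4.0) for cid, sp in colonies.items()
    }
    h = pd.DataFrame.from_dict(rows, orient="index",
                               columns=list(HABITAT_CLASSES))
    # ALR needs strictly positive parts; nudge exact zeros (Dirichlet draws
    # are almost surely positive, this guards degenerate float underflow)
    h = h.clip(lower=1e-6)
    return h.div(h.sum(axis=1), axis=0)


def _draw_orders(rng: np.random.Generator, n: int) -> list[str]:
    names = [o for o, _ in _ORDERS]
    weights = np.array([w for _, w in _ORDERS])
    picks = rng.choice(len(names), size=n, p=weights / weights.sum())
    return [names[k] for k in picks]


def _synthetic_taxonomy(
    rng: np.random.Generator, prey_ids: list[str], orders: list[str]
) -> dict[str, MotuAssignment]:
    out = {}
    for i, motu in enumerate(prey_ids):
        order = orders[i]
        family = f"{order}_fam{rng.integers(1, 7)}"
        u = rng.random()
        if u < 0.88:
            rank, ident, cov = "species", float(rng.uniform(99.0, 100.0)), 99.0
        elif u < 0.92:
            rank, ident, cov = "genus", float(rng.uniform(96.1, 98.9)), 99.0
        else:
            rank, ident, cov = "family", float(rng.uniform(90.1, 96.0)), 99.0
        out[motu] = MotuAssignment(
            motu_id=motu,
            best_identity=ident,
            best_coverage=cov,
            order=order,
            family=family,
            genus=f"{family}_gen{rng.integers(1, 4)}" if rank != "family" else "",
            species=f"{motu}_sp" if rank == "species" else "",
            assigned_rank=rank,
        )
    return out


def generate(config: GeneratorConfig | None = None,
             seed: int | None = None) -> SimulatedDataset:
    """Draw one synthetic dataset (deterministic given config and seed).

    ``seed`` overrides ``config.seed``.  Returns raw (uncurated) counts:
    the prey signal plus sub-threshold noise detections and flagged
    non-prey MOTUs, so the curation stage has real work to do.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    prey_ids = [f"motu{i + 1:04d}" for i in range(cfg.n_prey)]
    prey_orders = _draw_orders(rng, cfg.n_prey)
    traits = _trait_matrix(rng, prey_ids, cfg.trait_block_scale)
    B = cfg.effect_matrix()

    colonies: dict[str, str] = {}
    for sp, n_col in zip(SPECIES, cfg.colonies_per_species):
        for k in range(n_col):
            colonies[f"{sp[:3]}_c{k + 1}"] = sp
    habitat = _habitat_table(rng, colonies)
    smaller_colonies = [
        cid for cid, sp in colonies.items() if cid.endswith("_c1")
    ]

    mu = pd.Series(
        rng.uniform(0, cfg.n_dates - 1, size=cfg.n_prey), index=prey_ids
    )
    sigma = pd.Series(
        rng.uniform(*cfg.phenology_width, size=cfg.n_prey), index=prey_ids
    )
    offsets = np.array(
        [
            _ORDER_BASELINE_OFFSET.get(o, _OTHER_ORDER_OFFSET)
            for o in prey_orders
        ]
    )
    alpha = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_prey)
        + offsets,
        index=prey_ids,
    )
    trait_arr = traits.to_numpy(dtype=float)

    def pellet_prob(species: str, t_idx: int) -> np.ndarray:
        phi = cfg.phenology_amplitude * np.exp(
            -((t_idx - mu.to_numpy()) ** 2) / (2.0 * sigma.to_numpy() ** 2)
        )
        eta = alpha.to_numpy() + phi + trait_arr @ B.loc[species].to_numpy()
        return _logistic(eta)

    noise_ids = [f"noise{i + 1:03d}" for i in range(cfg.noise_motus)]
    flagged: list[tuple[str, str]] = []
    for flag, n in (
        ("contaminant", cfg.n_contaminant),
        ("coprophage", cfg.n_coprophage),
        ("secondary_prey", cfg.n_secondary_prey),
        ("predator_dna", cfg.n_predator_dna),
        ("no_match", cfg.n_no_match),
    ):
        flagged.extend((f"{flag}{i + 1:02d}", flag) for i in range(n))

    rows: list[dict] = []
    meta_rows: list[dict] = []
    pellet_sets: dict[str, list] = {}

    def add_sample(sample_id: str, colony: str, species: str,
                   date: _dt.date, t_idx: int, n_pellets: int,
                   sample_type: str) -> None:
        p = pellet_prob(species, t_idx)
        hits = rng.random((n_pellets, cfg.n_prey)) < p
        pellet_sets[sample_id] = [
            [prey_ids[j] for j in np.flatnonzero(hits[k])]
            for k in range(n_pellets)
        ]
        detected = np.flatnonzero(hits.any(axis=0))
        cell: dict[str, int] = {}
        reads = _nb_reads(rng, detected.size, cfg.reads_mean,
                          cfg.reads_dispersion)
        for j, nr in zip(detected, reads):
            cell[prey_ids[j]] = int(nr)
        # sub-threshold noise detections (1-2 reads)
        for _ in range(rng.poisson(cfg.noise_rate)):
            nm = noise_ids[rng.integers(len(noise_ids))]
            cell[nm] = cell.get(nm, 0) + int(rng.integers(1, 3))
        # flagged non-prey MOTUs at normal read depth
        for fm, _flag in flagged:
            if rng.random() < cfg.flagged_prevalence:
                cell[fm] = int(
                    _nb_reads(rng, 1, cfg.reads_mean, cfg.reads_dispersion)[0]
                )
        rows.append({"sample_id": sample_id, **cell})
        meta_rows.append(
            {
                "sample_id": sample_id,
                "colony_id": colony,
                "species": species,
                "date": date,
                "season": assign_season(date),
                "sample_type": sample_type,
            }
        )

    for t_idx, date in enumerate(cfg.dates):
        for colony, species in colonies.items():
            n_pellets = int(rng.integers(cfg.community_pellets[0],
                                         cfg.community_pellets[1] + 1))
            add_sample(f"{colony}_d{t_idx + 1:02d}_comm", colony, species,
                       date, t_idx, n_pellets, "community")
            if colony in smaller_colonies:
                for rep in range(cfg.smaller_replicates):
                    n_pellets = int(rng.integers(cfg.smaller_pellets[0],
                                                 cfg.smaller_pellets[1] + 1))
                    add_sample(
                        f"{colony}_d{t_idx + 1:02d}_small{rep + 1}",
                        colony, species, date, t_idx, n_pellets, "smaller",
                    )

    counts = (
        pd.DataFrame(rows).set_index("sample_id").fillna(0).astype(np.int64)
    )
    # rare MOTUs: 1-2 detections of 1-2 reads each, so the data-set-wide
    # total stays below the 5-read minimum and the MOTU-level filter bites
    rare_ids = [f"rare{i + 1:02d}" for i in range(cfg.rare_motus)]
    for rm in rare_ids:
        counts[rm] = 0
        hit_rows = rng.choice(len(counts), size=rng.integers(1, 3),
                              replace=False)
        for hr in hit_rows:
            counts.iloc[hr, counts.columns.get_loc(rm)] = int(
                rng.integers(1, 3)
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = DetectionTable(counts, meta)

    assignments = _synthetic_taxonomy(rng, prey_ids, prey_orders)
    for rm in rare_ids:
        assignments[rm] = MotuAssignment(
            motu_id=rm, best_identity=float(rng.uniform(99.0, 100.0)),
            best_coverage=99.0, order="Diptera", family="Diptera_fam1",
            assigned_rank="species", species=f"{rm}_sp",
        )
    for nm in noise_ids:
        assignments[nm] = MotuAssignment(
            motu_id=nm, best_identity=float(rng.uniform(99.0, 100.0)),
            best_coverage=99.0, order="Lepidoptera",
            family="Lepidoptera_fam1", assigned_rank="species",
            species=f"{nm}_sp",
        )
    for fm, flag in flagged:
        if flag == "no_match":
            assignments[fm] = MotuAssignment(
                motu_id=fm, best_identity=0.0, best_coverage=0.0,
                assigned_rank="unassigned", flags=frozenset({"no_match"}),
            )
        else:
            assignments[fm] = MotuAssignment(
                motu_id=fm, best_identity=float(rng.uniform(97.0, 100.0)),
                best_coverage=99.0, order="NonPrey",
                family=f"NonPrey_{flag}", assigned_rank="species",
                species=f"{fm}_sp", flags=frozenset({flag}),
            )

    truth = GroundTruth(
        B=B,
        phenology_mu=mu,
        phenology_sigma=sigma,
        baseline=alpha,
        habitat=habitat,
        pellet_prey_sets=pellet_sets,
    )
    return SimulatedDataset(
        table=table, traits=traits, habitat=habitat,
        assignments=assignments, truth=truth, config=cfg,
    )


def null_config(**overrides) -> GeneratorConfig:
    """A no-association configuration: B = 0 and flat phenology, for null
    calibration of the permutation tests."""
    kwargs = dict(planted_effects=(), phenology_amplitude=0.0)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def small_config(**overrides) -> GeneratorConfig:
    """A desk-scale configuration (one colony per species, fewer prey and
    dates) for simulation studies that repeat generation many times."""
    kwargs = dict(
        n_prey=60,
        colonies_per_species=(1, 1, 1),
        n_dates=6,
        smaller_replicates=2,
        noise_motus=8,
        n_contaminant=3,
        n_coprophage=1,
        n_secondary_prey=1,
        n_predator_dna=1,
        n_no_match=2,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def worked_example():
    """A tiny hand-checkable fixture: 6 samples, 12 prey, two colonies.

    Returns ``(table, assignments, traits, habitat, manifest)`` where the
    manifest records hand-computed wPOO, Levins, Morisita-Horn and Chao2
    values for the two predator groups (exact fractions, evaluated by hand
    from the occurrence pattern below and frozen here).
    """
    prey = [f"m{i + 1:02d}" for i in range(12)]
    detections = {
        "A1": ["m01", "m02", "m03", "m04"],
        "A2": ["m01", "m02"],
        "A3": ["m01", "m06"],
        "B1": ["m06", "m07"],
        "B2": ["m06", "m08", "m09", "m10"],
        "B3": ["m05", "m11", "m12"],
    }
    reads = {}
    for k, (sid, motus) in enumerate(detections.items()):
        reads[sid] = {m: 100 + 10 * k + 7 * j for j, m in enumerate(motus)}
    counts = (
        pd.DataFrame.from_dict(reads, orient="index")
        .reindex(columns=prey)
        .fillna(0)
        .astype(np.int64)
    )
    meta = pd.DataFrame(
        {
            "colony_id": ["a1", "a1", "a1", "b1", "b1", "b1"],
            "species": ["auritus"] * 3 + ["austriacus"] * 3,
            "date": [
                _dt.date(2015, 5, 1), _dt.date(2015, 7, 15),
                _dt.date(2015, 9, 10), _dt.date(2015, 5, 1),
                _dt.date(2015, 7, 15), _dt.date(2015, 9, 10),
            ],
            "season": ["spring", "summer", "autumn"] * 2,
            "sample_type": ["smaller"] * 6,
        },
        index=counts.index,
    )
    table = DetectionTable(counts, meta)

    orders = ["Lepidoptera"] * 6 + ["Diptera"] * 3 + ["Coleoptera"] * 3
    assignments = {
        m: MotuAssignment(
            motu_id=m, best_identity=99.5, best_coverage=99.0,
            order=orders[i], family=f"{orders[i]}_fam{1 + i % 2}",
            genus=f"gen{i + 1}", species=f"{m}_sp",
            assigned_rank="species",
        )
        for i, m in enumerate(prey)
    }
    traits = pd.DataFrame(
        {
            "closed_habitats": [1, 1, 1, 0, 0, 0, 1, 0, 1, 0, 0, 1],
            "open_habitats": [0, 0, 0, 1, 1, 1, 0, 1, 0, 1, 1, 0],
            "size": [1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3],
            "night_flying": [1, 1, 0, 1, 0, 1, 1, 1, 0, 1, 1, 1],
        },
        index=prey,
    )
    habitat = pd.DataFrame(
        {
            "urbanized": [0.10, 0.20],
            "wetlands_water": [0.05, 0.05],
            "lawns_isolated_trees": [0.10, 0.15],
            "grasslands_prairies": [0.15, 0.20],
            "forest_shrub": [0.40, 0.15],
            "farmland": [0.20, 0.25],
        },
        index=["a1", "b1"],
    )
    manifest = {
        "wpoo_auritus": {
            "m01": 5 / 12, "m02": 1 / 4, "m03": 1 / 12, "m04": 1 / 12,
            "m06": 1 / 6,
        },
        "wpoo_austriacus": {
            "m06": 1 / 4, "m07": 1 / 6, "m08": 1 / 12, "m09": 1 / 12,
            "m10": 1 / 12, "m05": 1 / 9, "m11": 1 / 9, "m12": 1 / 9,
        },
        "levins_auritus": 18 / 5,
        "levins_austriacus": 27 / 4,
        "morisita_horn": 9 / 46,
        "chao2_auritus": 8.0,
        "chao2_austriacus": 8 + 49 / 3,
        "incidence_auritus": {"m": 3, "S_obs": 5, "Q1": 3, "Q2": 1},
        "incidence_austriacus": {"m": 3, "S_obs": 8, "Q1": 7, "Q2": 1},
    }
    return table, assignments, traits, habitat, manifest
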