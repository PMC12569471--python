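"""Synthetic trees, nest traits and covariates with known ground truth.

The generator emulates the statistical structure of the real inputs: a
birth-death phylogeny (depth normalized to 1), continuous covariates
evolving by Brownian motion on that tree, five correlated climate columns
driven by two latent Brownian factors (so a PCA concentrates their
variance on two axes), an island flag obtained by thresholding a latent
Brownian variable, and nominal nest traits generated under a
liability-threshold model: each trait's latent liability is a linear
combination of (standardized) covariates — the *coupling*, the known true
effect — plus Brownian noise, discretized at empirical quantile cut
points. Heights are drawn log-normally from the height liability so the
geometric-mean binning of the traits module is exercised, and a small
fraction of species is assigned the rare site states (ant nest, water
body) that recoding later folds back in.

Everything is a pure function of the SimConfig: the same seed reproduces
the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import NestarchError, ValidationError
from .phylo import Phylogeny, vcv
from .traits import GROUPS, NestRecord, records_to_frame

#: quantile cut points defining the latent->state maps (must be ordered)
TRAIT_CUTS = {
    "nest_type": (0.7,),                # below -> non_cavity, above -> cavity
    "structure": (0.15, 0.5, 0.85),     # scrape | platform | cup | enclosed
    "site": (0.35, 0.75, 0.9),          # ground | vegetation | cliff | underground
    "attachment": (0.7, 0.9),           # basal | lateral | pensile
    "height": (0.35,),                  # below -> ground level (0 m)
}

TRAIT_STATE_ORDER = {
    "nest_type": ("non_cavity", "cavity"),
    "structure": ("scrape", "platform", "cup", "enclosed"),
    "site": ("ground", "vegetation", "cliff", "underground"),
    "attachment": ("basal", "lateral", "pensile"),
}

#: fixed loadings of the five climate columns on the two latent factors
CLIMATE_LOADINGS = np.array(
    [
        [0.9, 0.1],    # temperature
        [0.8, -0.3],   # precipitation
        [-0.2, 0.9],   # wind_speed
        [0.7, 0.4],    # vapour_pressure
        [0.3, 0.8],    # solar_radiation
    ]
)

COVARIATE_COLUMNS = (
    "temperature",
    "precipitation",
    "wind_speed",
    "vapour_pressure",
    "solar_radiation",
    "ndvi",
    "predator_diversity",
)

#: covariate names that couplings may reference
COUPLABLE = COVARIATE_COLUMNS + ("island", "log_mass", "climate_f1", "climate_f2")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; the seed is mandatory."""

    seed: int
    n_tips: int = 128
    birth_rate: float = 1.0
    death_rate: float = 0.0
    climate_noise: float = 0.1
    island_frac: float = 0.15
    rare_site_frac: float = 0.03
    #: Brownian sd of each continuous covariate (and the latent log mass)
    sigma_covariates: dict = field(
        default_factory=lambda: {
            "ndvi": 1.0, "predator_diversity": 1.0, "log_mass": 1.0,
        }
    )
    #: Brownian residual sd of each trait liability
    trait_sigma: dict = field(
        default_factory=lambda: {
            "nest_type": 1.0, "structure": 1.0, "site": 1.0,
            "attachment": 1.0, "height": 1.0,
        }
    )
    #: true effects: {trait: {covariate: beta}} on the liability scale
    coupling: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValidationError("n_tips must be >= 3")
        if not (0 <= self.death_rate < self.birth_rate):
            raise ValidationError("need 0 <= death_rate < birth_rate")
        for trait, effects in self.coupling.items():
            if trait not in TRAIT_CUTS:
                raise ValidationError(f"unknown coupled trait {trait!r}")
            for cov in effects:
                if cov not in COUPLABLE:
                    raise ValidationError(f"unknown covariate {cov!r} in coupling")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    records: list[NestRecord]
    covariates: pd.DataFrame
    truth: SimConfig


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    names = ("tree", "climate", "covariates", "island", "mass", "traits", "misc")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def sim_tree(config: SimConfig, rng: np.random.Generator | None = None) -> Phylogeny:
    """Birth-death tree conditioned on n_tips, depth normalized to 1."""
    rng = rng or _streams(config)["tree"]
    last_err = None
    for _ in range(25):
        pyseed = int(rng.integers(0, 2**31 - 1))
        try:
            # GSA conditioning: sample a time at which exactly n_tips lineages
            # exist, avoiding the zero-length cherry of naive stopping
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_tips,
                gsa_ntax=config.n_tips + 2,
                rng=random.Random(pyseed),
            )
        except Exception as exc:  # lineage extinction; retry with a new seed
            last_err = exc
            continue
        # normalize depth to 1 so liability/covariate sigmas are comparable
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        scale = max(depths)
        if scale <= 0:
            continue
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / scale
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"sp{i + 1:04d}"
        return Phylogeny(tree=tree)
    raise NestarchError(f"tree simulation failed repeatedly: {last_err}")


def _bm(chol: np.ndarray, rng: np.random.Generator, k: int = 1) -> np.ndarray:
    z = rng.standard_normal((chol.shape[0], k))
    x = chol @ z
    return x[:, 0] if k == 1 else x


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def sim_covariates(
    tree: Phylogeny, config: SimConfig, streams: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the covariate table; returns (public table, latents).

    The public table has the five climate columns plus ndvi and predator
    diversity. The latent frame carries the climate factors, the island
    flag and log mass (merged into the nest records downstream) so that
    couplings can reference them.
    """
    streams = streams or _streams(config)
    C = vcv(tree)
    labels = C.labels
    chol = np.linalg.cholesky(C.values + 1e-12 * np.eye(len(labels)))

    f = _bm(chol, streams["climate"], 2)  # latent climate factors
    noise = streams["climate"].standard_normal((len(labels), 5)) * config.climate_noise
    climate = f @ CLIMATE_LOADINGS.T + noise

    sig = config.sigma_covariates
    ndvi = sig.get("ndvi", 1.0) * _bm(chol, streams["covariates"])
    predator = sig.get("predator_diversity", 1.0) * _bm(chol, streams["covariates"])
    island_latent = _bm(chol, streams["island"])
    cut = np.quantile(island_latent, 1 - config.island_frac)
    island = island_latent >= cut
    log_mass = sig.get("log_mass", 1.0) * _bm(chol, streams["mass"])

    public = pd.DataFrame(
        np.column_stack([climate, ndvi, predator]),
        index=labels,
        columns=list(COVARIATE_COLUMNS),
    )
    latents = pd.DataFrame(
        {
            "climate_f1": f[:, 0],
            "climate_f2": f[:, 1],
            "island": island.astype(float),
            "log_mass": log_mass,
        },
        index=labels,
    )
    return public, latents


def sim_traits(
    tree: Phylogeny,
    covariates: pd.DataFrame,
    latents: pd.DataFrame,
    config: SimConfig,
    streams: dict | None = None,
) -> list[NestRecord]:
    """Generate nest records under the liability-threshold model."""
    streams = streams or _streams(config)
    rng = streams["traits"]
    misc = streams["misc"]
    C = vcv(tree)
    labels = C.labels
    n = len(labels)
    chol = np.linalg.cholesky(C.values + 1e-12 * np.eye(n))

    pool = pd.concat([covariates, latents], axis=1).loc[labels]
    zpool = {
        c: _zscore(pool[c].to_numpy(dtype=float))
        if pool[c].std(ddof=1) > 0 else np.zeros(n)
        for c in pool.columns
    }

    liab = {}
    for trait, cuts in TRAIT_CUTS.items():
        if list(cuts) != sorted(cuts):
            raise ValidationError(f"misordered thresholds for {trait!r}")
        sigma = config.trait_sigma.get(trait, 1.0)
        ell = sigma * _bm(chol, rng)
        for cov, beta in config.coupling.get(trait, {}).items():
            ell = ell + beta * zpool[cov]
        liab[trait] = ell

    states = {}
    for trait, order in TRAIT_STATE_ORDER.items():
        cuts = np.quantile(liab[trait], TRAIT_CUTS[trait])
        idx = np.searchsorted(cuts, liab[trait], side="right")
        states[trait] = [order[i] for i in idx]

    # rare site states, folded back by recoding downstream
    site = list(states["site"])
    for raw, rare in (("vegetation", "ant_nest"), ("ground", "water_body")):
        members = [i for i, s in enumerate(site) if s == raw]
        n_rare = int(round(config.rare_site_frac * len(members)))
        for i in misc.choice(members, size=min(n_rare, len(members)), replace=False):
            site[i] = rare

    # heights: ground-level below the height cut, else log-normal in the
    # liability with a seeded min/max spread around the geometric mean
    ell_h = liab["height"]
    ground_cut = np.quantile(ell_h, TRAIT_CUTS["height"][0])
    gm_height = np.exp(0.9 + 0.9 * _zscore(ell_h))
    spread = np.exp(np.abs(misc.standard_normal(n)) * 0.25 + 0.1)

    log_mass = latents.loc[labels, "log_mass"].to_numpy(dtype=float)
    gm_mass = np.exp(3.0 + log_mass)
    mass_spread = np.exp(np.abs(misc.standard_normal(n)) * 0.1 + 0.05)
    island = latents.loc[labels, "island"].to_numpy(dtype=float) > 0.5
    groups = misc.choice(GROUPS, size=n, p=[0.6, 0.35, 0.05])

    records = []
    for i, sp in enumerate(labels):
        if ell_h[i] <= ground_cut:
            h_min = h_max = 0.0
        else:
            h_min = gm_height[i] / spread[i]
            h_max = gm_height[i] * spread[i]
        records.append(
            NestRecord(
                species_id=sp,
                nest_type=states["nest_type"][i],
                structure=states["structure"][i],
                site=site[i],
                attachment=states["attachment"][i],
                height_min_m=round(h_min, 6),
                height_max_m=round(h_max, 6),
                mass_min_g=round(gm_mass[i] / mass_spread[i], 6),
                mass_max_g=round(gm_mass[i] * mass_spread[i], 6),
                island_endemic=bool(island[i]),
                group=str(groups[i]),
            )
        )
    return records


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Tree + covariates + nest records, fully determined by the config."""
    streams = _streams(config)
    tree = sim_tree(config, streams["tree"])
    covariates, latents = sim_covariates(tree, config, streams)
    records = sim_traits(tree, covariates, latents, config, streams)
    return SyntheticDataset(
        tree=tree, records=records, covariates=covariates, truth=config
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write tree.nwk, traits.csv, covariates.csv and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "traits": out / "traits.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.json",
    }
    paths["tree"].write_text(ds.tree.write_newick() + "\n")
    records_to_frame(ds.records).to_csv(paths["traits"], index=False)
    ds.covariates.rename_axis("species_id").to_csv(paths["covariates"])
    paths["truth"].write_text(ds.truth.to_json() + "\n")
    return paths
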