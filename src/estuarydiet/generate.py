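"""Seeded generator of complete synthetic datasets with the monitoring
program's sampling design, plus ground truth for recovery tests.

The generator emulates the study design: five estuarine sites sampled
February-July over 2008-2021, with per-(site, month) fish counts, per-site
length-bin and hatchery-mark proportions, site-specific prey profiles
(amphipod-dominated at the downstream sites, dipteran/cladoceran-dominated
upstream), and seasonal water temperatures interpolated between February
and July endpoints.

Sampling model per fish: a fork length drawn uniformly within its length
bin, mass from the allometry W = a * L^b, a stomach whose total prey count
is negative binomial and is split across taxa by a multinomial with the
site's (Dirichlet-drawn) profile, and per-item wet weights that are
lognormal around a per-taxon median.  Chironomid counts are split across
larva/pupa/adult-emergent life stages; all other taxa carry stage
"unknown".  Empty stomachs are inserted on top of the design counts, so
the design cells are exactly the counts that survive the empty-stomach
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import Dataset, EnergyTable, validate

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_gamma_responses",
    "generate_temperatures",
    "TABLE1_DESIGN",
]

#: Per-(site, month) fish counts of the monitoring design (months 2-7).
#: These are the per-cell values, which are internally consistent with the
#: per-site totals (40 / 444 / 455 / 343 / 83; grand total 1365).
TABLE1_DESIGN: dict[str, dict[int, int]] = {
    "Ilwaco Slough": {2: 29, 3: 5, 4: 6},
    "Welch Island": {2: 25, 3: 62, 4: 79, 5: 154, 6: 98, 7: 26},
    "Whites Island": {2: 5, 3: 44, 4: 85, 5: 186, 6: 108, 7: 27},
    "Campbell Slough": {2: 4, 3: 8, 4: 27, 5: 216, 6: 75, 7: 13},
    "Franz Lake": {2: 5, 4: 36, 5: 42},
}

#: Per-site (30-65 mm, 66-99 mm) counts used as bin proportions.
LENGTH_BIN_COUNTS: dict[str, tuple[int, int]] = {
    "Ilwaco Slough": (40, 0),
    "Welch Island": (308, 136),
    "Whites Island": (285, 170),
    "Campbell Slough": (91, 252),
    "Franz Lake": (59, 24),
}

#: Per-site (unmarked, marked) counts used as mark-status proportions.
MARK_COUNTS: dict[str, tuple[int, int]] = {
    "Ilwaco Slough": (40, 0),
    "Welch Island": (383, 61),
    "Whites Island": (400, 55),
    "Campbell Slough": (180, 163),
    "Franz Lake": (62, 21),
}

DEFAULT_TAXA = (
    "Americorophium",
    "Amphipoda Other",
    "Chironomidae",
    "Diptera Other",
    "Daphnia",
    "Corixidae",
    "Trichoptera",
    "Hymenoptera",
    "Other",
)

#: Dirichlet concentrations per site over DEFAULT_TAXA.  Downstream sites
#: (Ilwaco, Welch, Whites) are corophiid-amphipod dominated; Campbell is
#: cladoceran/dipteran; Franz is dipteran with essentially no cladocerans.
DEFAULT_PREY_PROFILES: dict[str, tuple[float, ...]] = {
    "Ilwaco Slough": (40.0, 3.0, 14.0, 6.0, 0.4, 1.0, 0.8, 0.8, 2.0),
    "Welch Island": (40.0, 3.0, 12.0, 4.0, 5.0, 1.5, 1.0, 1.0, 2.0),
    "Whites Island": (40.0, 3.0, 12.0, 4.0, 6.0, 1.5, 1.0, 1.0, 2.0),
    "Campbell Slough": (3.0, 1.0, 12.0, 4.0, 42.0, 2.0, 1.0, 1.0, 2.0),
    "Franz Lake": (1.5, 0.8, 42.0, 12.0, 0.4, 3.0, 2.0, 2.0, 4.0),
}

#: Per-taxon median wet weight of one prey item, in grams.
DEFAULT_ITEM_WEIGHT_G: dict[str, float] = {
    "Americorophium": 0.0020,
    "Amphipoda Other": 0.0018,
    "Chironomidae": 0.0010,
    "Diptera Other": 0.0008,
    "Daphnia": 0.0004,
    "Corixidae": 0.0015,
    "Trichoptera": 0.0015,
    "Hymenoptera": 0.0010,
    "Other": 0.0010,
}

#: Round placeholder energy densities (kJ per g wet mass) per taxon;
#: cladocerans are the energy-poor prey, insects the energy-rich ones.
DEFAULT_ENERGY_DENSITIES: dict[str, float] = {
    "Americorophium": 4.0,
    "Amphipoda Other": 4.0,
    "Chironomidae": 3.0,
    "Diptera Other": 3.5,
    "Daphnia": 2.0,
    "Corixidae": 4.5,
    "Trichoptera": 4.5,
    "Hymenoptera": 4.5,
    "Other": 3.0,
}

#: Per-site water temperature endpoints (February mean, July mean) in
#: degC; the across-site February range spans 4.4-10.9 and the July range
#: 18.9-23.3.
DEFAULT_TEMPERATURES: dict[str, tuple[float, float]] = {
    "Ilwaco Slough": (4.4, 18.9),
    "Welch Island": (6.0, 21.0),
    "Whites Island": (7.0, 22.0),
    "Campbell Slough": (10.9, 23.3),
    "Franz Lake": (5.5, 20.0),
}

#: Chironomid life-stage mix (larva, pupa, adult/emergent) by count.
CHIRONOMID_STAGE_PROBS = (0.36, 0.20, 0.44)
CHIRONOMID_PUPA_WEIGHT_FACTOR = 2.5  # pupae are the heavy stage

SITE_CODES = {
    "Ilwaco Slough": "ILW",
    "Welch Island": "WEL",
    "Whites Island": "WHI",
    "Campbell Slough": "CAM",
    "Franz Lake": "FRA",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce the monitoring design: per-(site, month) counts,
    2008-2021 years (cells spread as evenly as possible, remainder to the
    earliest years), per-site length-bin and mark proportions, and the
    seasonal temperature envelope.
    """

    design: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: TABLE1_DESIGN
    )
    years: tuple[int, int] = (2008, 2021)
    taxa: tuple[str, ...] = DEFAULT_TAXA
    prey_profiles: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: DEFAULT_PREY_PROFILES
    )
    dirichlet_profiles: bool = True  # False: use normalized concentrations directly
    #: Dirichlet precision of per-(site, year) profiles around the site
    #: profile, emulating interannual variation in which taxon dominates;
    #: 0 disables (every year reuses the site profile exactly).
    interannual_concentration: float = 25.0
    item_weight_g: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_ITEM_WEIGHT_G
    )
    item_weight_log_sd: float = 0.6
    count_mean: float = 20.0  # negative-binomial stomach total
    count_dispersion: float = 5.0  # NB size parameter k; Var = m + m^2/k
    empty_stomach_rate: float = 18.0 / 1383.0  # share of all generated fish
    fullness_missing_rate: float = 0.2
    energy_densities: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_ENERGY_DENSITIES
    )
    default_energy_density: float = 3.0
    temperature_endpoints: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_TEMPERATURES
    )
    temperature_noise_sd: float = 1.0
    temperature_threshold_C: float = 17.5
    length_bin_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: LENGTH_BIN_COUNTS
    )
    mark_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: MARK_COUNTS
    )
    mass_a: float = 1e-5  # W = a * L^b, grams vs mm
    mass_b: float = 3.0
    mass_noise_log_sd: float = 0.08
    seed: int = 0

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def validate(self) -> "GeneratorConfig":
        for site, months in self.design.items():
            if site not in self.prey_profiles:
                raise ValueError(f"design site {site!r} has no prey profile")
            for m, n in months.items():
                if m not in (2, 3, 4, 5, 6, 7):
                    raise ValueError(f"design month {m} outside 2..7 ({site})")
                if n < 0:
                    raise ValueError("design counts must be >= 0")
            if site not in self.temperature_endpoints:
                raise ValueError(f"no temperature endpoints for {site!r}")
        for site, conc in self.prey_profiles.items():
            if len(conc) != len(self.taxa) or any(c <= 0 for c in conc):
                raise ValueError(f"bad Dirichlet concentrations for {site!r}")
        if not (0 <= self.empty_stomach_rate < 1):
            raise ValueError("empty_stomach_rate must be in [0, 1)")
        return self


@dataclass
class GroundTruth:
    """Everything needed to recompute what was simulated."""

    site_profiles: pd.DataFrame  # site x taxon realized proportions
    fish_truth: pd.DataFrame  # fish_id, expected_ir, expected_er, is_empty
    config: GeneratorConfig
    seed: int
    beta: np.ndarray | None = None
    alpha: float | None = None

    def dominant_taxon(self, site: str) -> str:
        return self.site_profiles.loc[site].idxmax()


def _spread_over_years(n: int, years: Sequence[int]) -> list[int]:
    """Split a cell count across years as evenly as possible, remainder
    going to the earliest years."""
    base, rem = divmod(n, len(years))
    return [base + (1 if i < rem else 0) for i in range(len(years))]


def generate_temperatures(
    site: str,
    month: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
    size: int = 1,
) -> np.ndarray:
    """Seasonal water temperature draws for a site and month.

    The monthly mean interpolates linearly between the site's February and
    July endpoints; seeded Gaussian noise is added on top.
    """
    if month not in (2, 3, 4, 5, 6, 7):
        raise ValueError(f"month {month} outside 2..7")
    feb, jul = cfg.temperature_endpoints[site]
    mean = feb + (jul - feb) * (month - 2) / 5.0
    if cfg.temperature_noise_sd == 0:
        return np.full(size, mean)
    rng = np.random.default_rng(rng)
    return mean + rng.normal(scale=cfg.temperature_noise_sd, size=size)


def exceeds_threshold(temp_C, cfg: GeneratorConfig) -> np.ndarray:
    """Flag temperatures above the rearing-suitability threshold
    (default 17.5 degC)."""
    return np.asarray(temp_C) > cfg.temperature_threshold_C


def _draw_profiles(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = {}
    for site in cfg.design:
        conc = np.asarray(cfg.prey_profiles[site], dtype=float)
        if cfg.dirichlet_profiles:
            rows[site] = rng.dirichlet(conc)
        else:
            rows[site] = conc / conc.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(cfg.taxa))


def generate_dataset(cfg: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one complete synthetic dataset plus its ground truth.

    Reproducible given ``cfg.seed``; per-(site, month) non-empty fish
    counts equal the design exactly, with empty stomachs inserted on top
    at ``empty_stomach_rate`` (they are what the exclusion filter later
    removes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    years = list(range(cfg.years[0], cfg.years[1] + 1))
    profiles = _draw_profiles(cfg, rng)
    # per-(site, year) profiles jittered around the site profile emulate
    # interannual shifts in which taxon dominates
    year_profiles: dict[tuple[str, int], np.ndarray] = {}
    for site in cfg.design:
        base_p = profiles.loc[site].to_numpy()
        for year in years:
            if cfg.interannual_concentration > 0:
                year_profiles[(site, year)] = rng.dirichlet(
                    cfg.interannual_concentration * base_p
                )
            else:
                year_profiles[(site, year)] = base_p
    taxa = list(cfg.taxa)
    chiron_idx = taxa.index("Chironomidae") if "Chironomidae" in taxa else None

    fish_rows = []
    prey_rows = []
    truth_rows = []
    fid = 0
    empty_odds = (
        cfg.empty_stomach_rate / (1.0 - cfg.empty_stomach_rate)
        if cfg.empty_stomach_rate > 0
        else 0.0
    )
    # expected per-item weight by taxon (lognormal mean; chironomid stage mix)
    exp_item_w = {}
    for t in taxa:
        w = cfg.item_weight_g.get(t, 0.001) * np.exp(cfg.item_weight_log_sd**2 / 2)
        if t == "Chironomidae":
            w *= (
                CHIRONOMID_STAGE_PROBS[1] * CHIRONOMID_PUPA_WEIGHT_FACTOR
                + (1 - CHIRONOMID_STAGE_PROBS[1])
            )
        exp_item_w[t] = w
    dens = {
        t: cfg.energy_densities.get(t, cfg.default_energy_density) for t in taxa
    }

    for site in cfg.design:
        p = profiles.loc[site].to_numpy()
        p_small = _site_proportion(cfg.length_bin_counts[site])
        p_unmarked = _site_proportion(cfg.mark_counts[site])
        exp_w_per_item = float(np.dot(p, [exp_item_w[t] for t in taxa]))
        exp_e_per_item = float(
            np.dot(p, [exp_item_w[t] * dens[t] for t in taxa])
        )
        for month in sorted(cfg.design[site]):
            n_design = cfg.design[site][month]
            n_empty = int(rng.binomial(n_design, empty_odds)) if n_design else 0
            per_year = _spread_over_years(n_design, years)
            for year, n_year in zip(years, per_year):
                for i in range(n_year):
                    fid += 1
                    fish_rows.append(
                        _draw_fish(
                            fid, site, year, month, cfg, rng, p_small, p_unmarked
                        )
                    )
            # empties appended after the cell's design fish, spread over years
            for j in range(n_empty):
                fid += 1
                year = years[j % len(years)]
                row = _draw_fish(
                    fid, site, year, month, cfg, rng, p_small, p_unmarked
                )
                row["_empty"] = True
                fish_rows.append(row)

    fish = pd.DataFrame(fish_rows)
    is_empty = fish.pop("_empty").fillna(False) if "_empty" in fish else pd.Series(
        False, index=fish.index
    )

    # stomach contents for non-empty fish
    for idx in fish.index[~is_empty]:
        row = fish.loc[idx]
        p = year_profiles[(row["site"], row["year"])]
        total = _nb_draw(cfg, rng)
        counts = rng.multinomial(total, p)
        for j in np.nonzero(counts)[0]:
            taxon = taxa[j]
            c = int(counts[j])
            if j == chiron_idx:
                stage_counts = rng.multinomial(c, CHIRONOMID_STAGE_PROBS)
                stages = ("larva", "pupa", "adult/emergent")
            else:
                stage_counts = (c,)
                stages = ("unknown",)
            for stage, sc in zip(stages, stage_counts):
                if sc == 0:
                    continue
                draws = cfg.item_weight_g.get(taxon, 0.001) * np.exp(
                    rng.normal(scale=cfg.item_weight_log_sd, size=sc)
                )
                if stage == "pupa":
                    draws = draws * CHIRONOMID_PUPA_WEIGHT_FACTOR
                prey_rows.append(
                    {
                        "fish_id": row["fish_id"],
                        "taxon": taxon,
                        "life_stage": stage,
                        "count": int(sc),
                        "weight_g": float(draws.sum()),
                    }
                )

    prey = pd.DataFrame(
        prey_rows, columns=["fish_id", "taxon", "life_stage", "count", "weight_g"]
    )

    # ordinal fullness from IR quintiles among non-empty fish
    totals = prey.groupby("fish_id")["weight_g"].sum()
    ir = (
        fish.set_index("fish_id")["mass_g"].rdiv(totals).reindex(
            fish["fish_id"]
        ).fillna(0.0)
    )
    fullness = np.full(len(fish), 2, dtype=float)
    nonempty_ir = ir.to_numpy()[~is_empty.to_numpy()]
    if len(nonempty_ir):
        quintiles = np.quantile(nonempty_ir, [0.2, 0.4, 0.6, 0.8])
        fullness[~is_empty.to_numpy()] = 2 + np.searchsorted(
            quintiles, nonempty_ir
        )
    miss = rng.random(len(fish)) < cfg.fullness_missing_rate
    fullness = pd.array(fullness, dtype="Int64")
    fullness[miss] = pd.NA
    fish["fullness_category"] = fullness

    energy = EnergyTable(dict(cfg.energy_densities), cfg.default_energy_density)

    for idx in fish.index:
        row = fish.loc[idx]
        p = year_profiles[(row["site"], row["year"])]
        exp_items = 0.0 if is_empty[idx] else cfg.count_mean
        exp_w = exp_items * float(np.dot(p, [exp_item_w[t] for t in taxa]))
        exp_e = exp_items * float(np.dot(p, [exp_item_w[t] * dens[t] for t in taxa]))
        truth_rows.append(
            {
                "fish_id": row["fish_id"],
                "expected_ir": exp_w / row["mass_g"],
                "expected_er": exp_e / row["mass_g"],
                "is_empty": bool(is_empty[idx]),
            }
        )

    fish = fish[
        [
            "fish_id",
            "site",
            "year",
            "month",
            "fork_length_mm",
            "mass_g",
            "mark_status",
            "water_temp_C",
            "fullness_category",
        ]
    ]
    ds = validate(Dataset(fish, prey, energy))
    truth = GroundTruth(
        site_profiles=profiles,
        fish_truth=pd.DataFrame(truth_rows),
        config=cfg,
        seed=cfg.seed,
    )
    return ds, truth


def _site_proportion(pair: tuple[int, int]) -> float:
    a, b = pair
    return a / (a + b) if (a + b) > 0 else 1.0


def _nb_draw(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    """Total stomach prey count: negative binomial with mean count_mean and
    size count_dispersion, truncated to >= 1."""
    k = cfg.count_dispersion
    p = k / (k + cfg.count_mean)
    total = int(rng.negative_binomial(k, p))
    return max(total, 1)


def _draw_fish(
    fid: int,
    site: str,
    year: int,
    month: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    p_small: float,
    p_unmarked: float,
) -> dict:
    small = rng.random() < p_small
    length = rng.uniform(30.0, 66.0) if small else rng.uniform(66.0, 100.0)
    length = np.floor(length * 10.0) / 10.0  # 0.1 mm precision, stays in-bin
    mass = (
        cfg.mass_a
        * length**cfg.mass_b
        * np.exp(rng.normal(scale=cfg.mass_noise_log_sd))
    )
    temp = float(generate_temperatures(site, month, cfg, rng)[0])
    return {
        "fish_id": f"{SITE_CODES.get(site, site[:3].upper())}-{fid:05d}",
        "site": site,
        "year": year,
        "month": month,
        "fork_length_mm": float(length),
        "mass_g": round(float(mass), 4),
        "mark_status": "unmarked" if rng.random() < p_unmarked else "marked",
        "water_temp_C": round(temp, 2),
        "fullness_category": pd.NA,
        "_empty": False,
    }


def generate_gamma_responses(
    design: pd.DataFrame | np.ndarray,
    beta: Sequence[float],
    alpha: float,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Draw gamma responses x_i ~ Gamma(shape 1/alpha, scale mu_i*alpha)
    with log mu_i = design_i . beta.

    ``design`` is a numeric design matrix (intercept included); sample
    mean and variance are consistent with mu and alpha*mu^2.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    x = np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float)
    mu = np.exp(x @ beta)
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
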