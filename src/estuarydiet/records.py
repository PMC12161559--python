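"""Data model, delimited-text I/O, validation, and exclusion filters.

The study design samples juvenile (subyearling) Chinook salmon at five
estuarine monitoring sites, February through July, 2008-2021.  Three flat
tables describe a dataset:

* ``fish.csv`` -- one row per sampled fish (site, date, fork length, mass,
  hatchery mark status, water temperature at capture, ordinal stomach
  fullness category 2-6 or blank);
* ``prey.csv`` -- one row per (fish, prey taxon, life stage) with a count
  and a blotted wet weight in grams;
* ``energy.csv`` -- taxon -> energy density in kJ per g wet mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SITES = (
    "Ilwaco Slough",
    "Welch Island",
    "Whites Island",
    "Campbell Slough",
    "Franz Lake",
)

MONTHS = (2, 3, 4, 5, 6, 7)

MARK_STATUSES = ("marked", "unmarked")

LIFE_STAGES = ("larva", "pupa", "adult/emergent", "unknown")

FULLNESS_CATEGORIES = (2, 3, 4, 5, 6)

FISH_COLUMNS = [
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

PREY_COLUMNS = ["fish_id", "taxon", "life_stage", "count", "weight_g"]

ENERGY_COLUMNS = ["taxon", "energy_density_kJ_per_g"]

#: Aggregation of fine taxon labels (genus/family level) to the coarse
#: groups used in ordinations and summary figures.  Labels not listed map
#: to themselves.  Keys are canonical (title-cased) labels.
TAXON_GROUPS: dict[str, str] = {
    "Americorophium": "Amphipoda",
    "Eogammarus": "Amphipoda",
    "Hyalella": "Amphipoda",
    "Amphipoda Other": "Amphipoda",
    "Chironomidae": "Diptera",
    "Psychodidae": "Diptera",
    "Diptera Other": "Diptera",
    "Daphnia": "Cladocera",
    "Cladocera Other": "Cladocera",
    "Corixidae": "Hemiptera",
    "Hemiptera Other": "Hemiptera",
}

#: Case-insensitive aliases folded onto canonical labels.  Deliberately
#: small: unidentified categories are kept distinct from identified ones.
TAXON_ALIASES: dict[str, str] = {
    "americorophium spp.": "Americorophium",
    "americorophium salmonis": "Americorophium",
    "americorophium spinicorne": "Americorophium",
    "eogammarus confervicolus": "Eogammarus",
    "hyalella azteca": "Hyalella",
    "hyallela azteca": "Hyalella",
    "daphnia spp.": "Daphnia",
    "chironomid": "Chironomidae",
    "chironomids": "Chironomidae",
}


class SchemaError(ValueError):
    """A required column is missing or a field fails validation."""


class ReferentialError(ValueError):
    """A prey row references a fish_id absent from the fish table."""


def canonical_taxon(label: str) -> str:
    """Canonicalize a taxon label: strip, collapse case via title-casing,
    and fold known aliases."""
    cleaned = " ".join(str(label).split())
    alias = TAXON_ALIASES.get(cleaned.lower())
    if alias is not None:
        return alias
    return cleaned.title()


def taxon_group(label: str) -> str:
    """Coarse group (Amphipoda, Diptera, Cladocera, ...) for a canonical
    taxon label; labels without a mapping are their own group."""
    return TAXON_GROUPS.get(canonical_taxon(label), canonical_taxon(label))


@dataclass(frozen=True)
class FishRecord:
    fish_id: str
    site: str
    year: int
    month: int
    fork_length_mm: float
    mass_g: float
    mark_status: str
    water_temp_C: float
    fullness_category: int | None = None

    def __post_init__(self) -> None:
        if self.fork_length_mm <= 0:
            raise SchemaError(f"fork_length_mm must be > 0 ({self.fish_id})")
        if self.mass_g <= 0:
            raise SchemaError(f"mass_g must be > 0 ({self.fish_id})")
        if self.month not in MONTHS:
            raise SchemaError(f"month must be in 2..7 ({self.fish_id})")
        if (
            self.fullness_category is not None
            and self.fullness_category not in FULLNESS_CATEGORIES
        ):
            raise SchemaError(f"fullness_category must be 2..6 ({self.fish_id})")


@dataclass(frozen=True)
class PreyItem:
    fish_id: str
    taxon: str
    life_stage: str
    count: int
    weight_g: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise SchemaError(f"count must be >= 1 ({self.fish_id}/{self.taxon})")
        if self.weight_g < 0:
            raise SchemaError(f"weight_g must be >= 0 ({self.fish_id}/{self.taxon})")


@dataclass(frozen=True)
class EnergyTable:
    """Taxon -> energy density (kJ per g wet mass), with a default for
    unlisted taxa."""

    densities: Mapping[str, float]
    default_density: float = 3.0

    def __post_init__(self) -> None:
        bad = [t for t, v in self.densities.items() if not v > 0]
        if bad or not self.default_density > 0:
            raise SchemaError(f"energy densities must be > 0: {bad}")

    def density(self, taxon: str) -> float:
        return self.densities.get(canonical_taxon(taxon), self.default_density)

    def __contains__(self, taxon: str) -> bool:
        return canonical_taxon(taxon) in self.densities


@dataclass
class Dataset:
    """Validated container: fish and prey tables plus the energy table.

    ``fish`` and ``prey`` are pandas DataFrames with the documented
    columns; every ``prey.fish_id`` resolves to a fish row.
    """

    fish: pd.DataFrame
    prey: pd.DataFrame
    energy: EnergyTable
    unknown_energy_taxa: tuple[str, ...] = ()

    @property
    def n_fish(self) -> int:
        return len(self.fish)

    def prey_of(self, fish_id: str) -> pd.DataFrame:
        return self.prey[self.prey["fish_id"] == fish_id]

    def copy(self) -> "Dataset":
        return Dataset(
            self.fish.copy(), self.prey.copy(), self.energy, self.unknown_energy_taxa
        )


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of fish removed by each exclusion rule."""

    empty_stomach: int
    oversize: int

    @property
    def total(self) -> int:
        return self.empty_stomach + self.oversize

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["empty_stomach", "oversize"],
                "removed": [self.empty_stomach, self.oversize],
            }
        )


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing column(s): {', '.join(missing)}")


def validate(ds: Dataset) -> Dataset:
    """Check invariants in place; raise on violation, return ``ds``."""
    fish, prey = ds.fish, ds.prey
    _require_columns(fish, FISH_COLUMNS, "fish table")
    _require_columns(prey, PREY_COLUMNS, "prey table")
    if fish["fish_id"].duplicated().any():
        dup = fish.loc[fish["fish_id"].duplicated(), "fish_id"].tolist()
        raise SchemaError(f"duplicate fish_id: {dup}")
    if not (fish["fork_length_mm"] > 0).all():
        raise SchemaError("fork_length_mm must be > 0")
    if not (fish["mass_g"] > 0).all():
        raise SchemaError("mass_g must be > 0")
    if not fish["month"].isin(MONTHS).all():
        raise SchemaError("month must be in 2..7")
    full = fish["fullness_category"].dropna()
    if not full.isin(FULLNESS_CATEGORIES).all():
        raise SchemaError("fullness_category must be 2..6 or missing")
    if len(prey):
        if (prey["count"] < 1).any():
            raise SchemaError("prey count must be >= 1")
        if (prey["weight_g"] < 0).any():
            raise SchemaError("prey weight_g must be >= 0")
        orphans = sorted(set(prey["fish_id"]) - set(fish["fish_id"]))
        if orphans:
            raise ReferentialError(
                f"prey rows reference unknown fish_id: {orphans[:10]}"
            )
        keys = prey[["fish_id", "taxon", "life_stage"]]
        if keys.duplicated().any():
            raise SchemaError("(fish_id, taxon, life_stage) must be unique")
    return ds


def read_dataset(
    fish_path: str | Path, prey_path: str | Path, energy_path: str | Path
) -> Dataset:
    """Read and validate the three input tables.

    Taxon labels in prey and energy tables are canonicalized.  Prey taxa
    absent from the energy table are retained and flagged in
    ``Dataset.unknown_energy_taxa``.
    """
    fish = pd.read_csv(fish_path, dtype={"fish_id": str})
    prey = pd.read_csv(prey_path, dtype={"fish_id": str})
    energy_df = pd.read_csv(energy_path)
    _require_columns(energy_df, ENERGY_COLUMNS, "energy table")
    if len(prey) == 0:
        prey = pd.DataFrame(columns=PREY_COLUMNS)
    _require_columns(fish, FISH_COLUMNS, "fish table")
    _require_columns(prey, PREY_COLUMNS, "prey table")
    fish = fish.copy()
    fish["fullness_category"] = pd.to_numeric(
        fish["fullness_category"], errors="coerce"
    )
    prey = prey.copy()
    if len(prey):
        prey["taxon"] = prey["taxon"].map(canonical_taxon)
        prey["life_stage"] = prey["life_stage"].fillna("unknown")
    energy = EnergyTable(
        {
            canonical_taxon(t): float(v)
            for t, v in zip(
                energy_df["taxon"], energy_df["energy_density_kJ_per_g"]
            )
        }
    )
    unknown = tuple(
        sorted(set(prey["taxon"]) - set(energy.densities)) if len(prey) else ()
    )
    return validate(Dataset(fish, prey, energy, unknown))


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a dataset back to fish.csv / prey.csv / energy.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fish": out / "fish.csv",
        "prey": out / "prey.csv",
        "energy": out / "energy.csv",
    }
    fish = ds.fish[FISH_COLUMNS].copy()
    fish["fullness_category"] = fish["fullness_category"].astype("Int64")
    fish.to_csv(paths["fish"], index=False)
    ds.prey[PREY_COLUMNS].to_csv(paths["prey"], index=False)
    pd.DataFrame(
        {
            "taxon": list(ds.energy.densities),
            "energy_density_kJ_per_g": list(ds.energy.densities.values()),
        }
    ).to_csv(paths["energy"], index=False)
    return paths


def apply_exclusions(
    ds: Dataset, max_fork_length_mm: float = 100.0
) -> tuple[Dataset, ExclusionReport]:
    """Remove fish with empty stomachs and fish at or above the fork-length
    cutoff (default 100 mm, so the 66-99 mm bin is the last retained).

    Idempotent: re-applying to the result removes nothing.
    """
    fish, prey = ds.fish, ds.prey
    with_prey = set(prey["fish_id"]) if len(prey) else set()
    empty_mask = ~fish["fish_id"].isin(with_prey)
    oversize_mask = (fish["fork_length_mm"] >= max_fork_length_mm) & ~empty_mask
    keep = ~(empty_mask | oversize_mask)
    kept_fish = fish[keep].reset_index(drop=True)
    kept_prey = (
        prey[prey["fish_id"].isin(set(kept_fish["fish_id"]))].reset_index(drop=True)
        if len(prey)
        else prey
    )
    report = ExclusionReport(
        empty_stomach=int(empty_mask.sum()), oversize=int(oversize_mask.sum())
    )
    out = Dataset(kept_fish, kept_prey, ds.energy, ds.unknown_energy_taxa)
    if out.n_fish == 0:
        import warnings

        warnings.warn("all fish excluded; dataset is empty", stacklevel=2)
    return out, report


#: (label, inclusive lower, inclusive upper integer endpoint) per scheme.
LENGTH_BINS = {
    "model": (("30-65", 30.0, 65.0), ("66-99", 66.0, 99.0)),
    "ordination": (
        ("30-59", 30.0, 59.0),
        ("60-79", 60.0, 79.0),
        ("80-99", 80.0, 99.0),
    ),
}


def assign_length_bin(fork_length_mm: float, scheme: str = "model") -> str:
    """Bin a fork length (mm) under the two-bin model scheme (30-65, 66-99)
    or the three-bin ordination scheme (30-59, 60-79, 80-99).

    Printed endpoints are inclusive; adjacent bins partition [30, 100):
    a real-valued length falls in the bin whose integer span contains it
    (e.g. 65.5 mm -> 30-65's successor starts at 66, so 65.5 stays in
    30-65's half-open interval [30, 66)).
    """
    if scheme not in LENGTH_BINS:
        raise ValueError(f"unknown length-bin scheme: {scheme!r}")
    if not (30.0 <= fork_length_mm < 100.0):
        raise ValueError(
            f"fork length {fork_length_mm} mm outside [30, 100); "
            "apply exclusions first"
        )
    bins = LENGTH_BINS[scheme]
    for (label, lo, _), nxt in zip(bins, bins[1:]):
        if fork_length_mm < nxt[1]:
            return label
    return bins[-1][0]


def assign_length_bins(lengths: pd.Series, scheme: str = "model") -> pd.Series:
    """Vectorized :func:`assign_length_bin`."""
    bins = LENGTH_BINS[scheme]
    edges = [b[1] for b in bins] + [100.0]
    labels = [b[0] for b in bins]
    if ((lengths < 30.0) | (lengths >= 100.0)).any():
        raise ValueError("fork length outside [30, 100); apply exclusions first")
    out = pd.cut(lengths, bins=edges, labels=labels, right=False)
    return out.astype(str)
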