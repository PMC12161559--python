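"""Diet-importance and bioenergetic scores per fish and per group.

Statistics
----------
Index of Relative Importance (per taxon, within a group of stomachs):

    IRI_i = F_i * (%N_i + %G_i)

where %N_i is the taxon's share of all prey counts (0-100), %G_i its share
of all prey wet weight (0-100), and F_i the proportion of stomachs in the
group containing the taxon (0-1), so IRI is bounded by 200.  %IRI
normalizes IRI to sum to 100 within the group and is what the ordination
machinery consumes.

Per-fish scores:

* instantaneous ration   IR = (total prey weight) / (fish mass), a
  dimensionless stomach-fullness proxy;
* energy ration          ER = sum_i (prey_i weight * taxon_i energy
  density) / (fish mass), in kJ per g fish;
* maintenance metabolism Jm = jm0 * exp(d * t) * W, the modeled baseline
  metabolic cost of a fish of mass W (g) at water temperature t (degC).
  jm0 is the mass-specific maintenance cost at 0 degC and d the
  temperature coefficient for biomass assimilation.  Units are carried
  abstractly ("model units"); only ratios and orderings of Jm are
  interpreted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import Dataset, EnergyTable, FULLNESS_CATEGORIES, assign_length_bins


@dataclass(frozen=True)
class MetabolismParams:
    """Maintenance-metabolism parameters.

    jm0
        Mass-specific maintenance cost at 0 degC; default 0.003.
    d
        Temperature coefficient per degC; default 0.68.  Note the default
        makes Jm grow by a factor e^0.68 ~ 2 per degree, far steeper than
        typical bioenergetics coefficients (~0.05-0.08 per degC); it is
        kept as the model's stated default and exposed here so users can
        substitute a literature value.
    """

    jm0: float = 0.003
    d: float = 0.68

    def __post_init__(self) -> None:
        if self.jm0 <= 0:
            raise ValueError("jm0 must be > 0")


def maintenance_metabolism(
    mass_g: float, temp_C: float, params: MetabolismParams = MetabolismParams()
) -> float:
    """Jm = jm0 * exp(d * t) * W for a fish of mass W grams at t degC."""
    if np.any(np.asarray(mass_g) <= 0):
        raise ValueError("mass_g must be > 0")
    return params.jm0 * np.exp(params.d * np.asarray(temp_C)) * np.asarray(mass_g)


def instantaneous_ration(mass_g: float, prey_weights_g: Sequence[float]) -> float:
    """IR: total prey wet weight divided by fish mass."""
    if mass_g <= 0:
        raise ValueError("mass_g must be > 0")
    return float(np.sum(prey_weights_g)) / mass_g


def energy_ration(
    mass_g: float,
    prey_taxa: Sequence[str],
    prey_weights_g: Sequence[float],
    energy: EnergyTable,
) -> float:
    """ER: prey weights scaled by taxon energy densities (kJ/g wet mass),
    summed, divided by fish mass."""
    if mass_g <= 0:
        raise ValueError("mass_g must be > 0")
    total = sum(w * energy.density(t) for t, w in zip(prey_taxa, prey_weights_g))
    return total / mass_g


def composition(
    ds: Dataset,
    grouping: Sequence[str] = ("site",),
    stage_resolved: bool = False,
) -> pd.DataFrame:
    """Per-group, per-taxon composition statistics.

    Returns a tidy frame keyed by the grouping columns plus ``taxon`` with
    columns ``numeric_pct`` (%N), ``gravimetric_pct`` (%G),
    ``freq_occurrence`` (F, proportion 0-1), ``iri`` and ``iri_pct``.
    Every taxon present anywhere in the dataset appears in every group
    (zeros when absent).  Life stages are summed within taxon unless
    ``stage_resolved``.

    ``grouping`` names fish-table columns; the derived column
    ``length_bin`` (model scheme) or ``length_bin_ordination`` may also be
    used.
    """
    fish = ds.fish.copy()
    if "length_bin" in grouping:
        fish["length_bin"] = assign_length_bins(fish["fork_length_mm"], "model")
    if "length_bin_ordination" in grouping:
        fish["length_bin_ordination"] = assign_length_bins(
            fish["fork_length_mm"], "ordination"
        )
    grouping = list(grouping)
    prey = ds.prey.copy()
    if len(prey) == 0:
        raise ValueError("composition undefined: dataset has no prey rows")
    taxon_cols = ["taxon", "life_stage"] if stage_resolved else ["taxon"]
    if stage_resolved:
        prey["taxon"] = prey["taxon"] + " (" + prey["life_stage"] + ")"
    merged = prey.merge(fish[["fish_id"] + grouping], on="fish_id", how="inner")

    all_taxa = sorted(merged["taxon"].unique())
    results = []
    for key, sub in merged.groupby(grouping, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        fish_ids_in_group = fish.loc[
            (fish[grouping] == pd.Series(dict(zip(grouping, key)))).all(axis=1),
            "fish_id",
        ]
        n_stomachs = len(fish_ids_in_group)
        agg = sub.groupby("taxon").agg(
            counts=("count", "sum"),
            weight=("weight_g", "sum"),
            stomachs=("fish_id", "nunique"),
        )
        agg = agg.reindex(all_taxa, fill_value=0)
        total_counts = agg["counts"].sum()
        total_weight = agg["weight"].sum()
        pct_n = 100.0 * agg["counts"] / total_counts
        pct_g = (
            100.0 * agg["weight"] / total_weight
            if total_weight > 0
            else agg["weight"] * 0.0
        )
        freq = agg["stomachs"] / n_stomachs
        iri = freq * (pct_n + pct_g)
        iri_pct = 100.0 * iri / iri.sum()
        block = pd.DataFrame(
            {
                "taxon": all_taxa,
                "numeric_pct": pct_n.to_numpy(),
                "gravimetric_pct": pct_g.to_numpy(),
                "freq_occurrence": freq.to_numpy(),
                "iri": iri.to_numpy(),
                "iri_pct": iri_pct.to_numpy(),
            }
        )
        for col, val in zip(grouping, key):
            block.insert(0, col, val)
        results.append(block)
    out = pd.concat(results, ignore_index=True)
    return out[grouping + ["taxon"] + ["numeric_pct", "gravimetric_pct",
                                       "freq_occurrence", "iri", "iri_pct"]]


def ration_table(
    ds: Dataset, params: MetabolismParams = MetabolismParams()
) -> pd.DataFrame:
    """Per-fish IR, ER and Jm joined to the model covariates.

    One row per fish (post-exclusion datasets have >= 1 prey row per fish,
    so IR, ER > 0).  Adds the model-scheme ``length_bin`` column.
    """
    fish = ds.fish.copy()
    prey = ds.prey
    totals = (
        prey.groupby("fish_id")
        .agg(prey_weight=("weight_g", "sum"))
        .reset_index()
    )
    dens = prey["taxon"].map(ds.energy.density)
    energy = (
        prey.assign(energy_kJ=prey["weight_g"] * dens)
        .groupby("fish_id")
        .agg(prey_energy=("energy_kJ", "sum"))
        .reset_index()
    )
    out = fish.merge(totals, on="fish_id", how="left").merge(
        energy, on="fish_id", how="left"
    )
    out["prey_weight"] = out["prey_weight"].fillna(0.0)
    out["prey_energy"] = out["prey_energy"].fillna(0.0)
    out["ir"] = out["prey_weight"] / out["mass_g"]
    out["er"] = out["prey_energy"] / out["mass_g"]
    out["jm"] = maintenance_metabolism(
        out["mass_g"].to_numpy(), out["water_temp_C"].to_numpy(), params
    )
    out["length_bin"] = assign_length_bins(out["fork_length_mm"], "model")
    return out.drop(columns=["prey_weight", "prey_energy"])


def fullness_histogram(
    fish: pd.DataFrame, by: str = "site"
) -> pd.DataFrame:
    """Counts of the ordinal fullness categories (2..6) per group, with
    uncategorized stomachs tallied in a separate ``missing`` column."""
    rows = []
    for key, sub in fish.groupby(by, sort=True):
        counts = {
            int(c): int((sub["fullness_category"] == c).sum())
            for c in FULLNESS_CATEGORIES
        }
        rows.append(
            {by: key, **counts, "missing": int(sub["fullness_category"].isna().sum())}
        )
    return pd.DataFrame(rows)
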