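"""Shared fixtures: deterministic datasets mirroring the monitoring
design table and small hand-checkable examples."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from estuarydiet.generate import LENGTH_BIN_COUNTS, MARK_COUNTS, TABLE1_DESIGN
from estuarydiet.records import Dataset, EnergyTable, validate


def build_design_dataset(n_empty_extra: int = 0) -> Dataset:
    """Deterministic dataset whose per-site month counts, length-bin
    counts and mark counts equal the design table cells exactly.

    ``n_empty_extra`` appends that many additional fish with no prey rows
    (they disappear under the empty-stomach exclusion).
    """
    fish_rows = []
    prey_rows = []
    fid = 0
    for site, months in TABLE1_DESIGN.items():
        n_site = sum(months.values())
        n_small, _ = LENGTH_BIN_COUNTS[site]
        n_unmarked, _ = MARK_COUNTS[site]
        k = 0  # per-site fish counter
        for month in sorted(months):
            for _ in range(months[month]):
                fid += 1
                length = 50.0 if k < n_small else 80.0
                mark = "unmarked" if k < n_unmarked else "marked"
                k += 1
                fish_rows.append(
                    {
                        "fish_id": f"F{fid:05d}",
                        "site": site,
                        "year": 2008 + (k % 14),
                        "month": month,
                        "fork_length_mm": length,
                        "mass_g": 1.5 if length < 66 else 5.0,
                        "mark_status": mark,
                        "water_temp_C": 10.0,
                        "fullness_category": 4,
                    }
                )
                prey_rows.append(
                    {
                        "fish_id": f"F{fid:05d}",
                        "taxon": "Chironomidae",
                        "life_stage": "larva",
                        "count": 2,
                        "weight_g": 0.002,
                    }
                )
    for _ in range(n_empty_extra):
        fid += 1
        fish_rows.append(
            {
                "fish_id": f"F{fid:05d}",
                "site": "Welch Island",
                "year": 2010,
                "month": 5,
                "fork_length_mm": 45.0,
                "mass_g": 1.0,
                "mark_status": "unmarked",
                "water_temp_C": 12.0,
                "fullness_category": 2,
            }
        )
    fish = pd.DataFrame(fish_rows)
    fish["fullness_category"] = fish["fullness_category"].astype("Int64")
    prey = pd.DataFrame(prey_rows)
    energy = EnergyTable({"Chironomidae": 3.0})
    return validate(Dataset(fish, prey, energy))


@pytest.fixture(scope="session")
def design_dataset() -> Dataset:
    return build_design_dataset()


@pytest.fixture()
def two_fish_dataset() -> Dataset:
    """Hand-worked example: fish1 has taxon A (count 3, 0.03 g) and
    taxon B (count 1, 0.01 g); fish2 has taxon B (count 2, 0.06 g)."""
    fish = pd.DataFrame(
        {
            "fish_id": ["f1", "f2"],
            "site": ["Welch Island"] * 2,
            "year": [2010, 2010],
            "month": [5, 5],
            "fork_length_mm": [50.0, 60.0],
            "mass_g": [2.0, 4.0],
            "mark_status": ["unmarked", "marked"],
            "water_temp_C": [12.0, 12.0],
            "fullness_category": pd.array([4, 5], dtype="Int64"),
        }
    )
    prey = pd.DataFrame(
        {
            "fish_id": ["f1", "f1", "f2"],
            "taxon": ["A", "B", "B"],
            "life_stage": ["unknown"] * 3,
            "count": [3, 1, 2],
            "weight_g": [0.03, 0.01, 0.06],
        }
    )
    return validate(Dataset(fish, prey, EnergyTable({"A": 4.0, "B": 3.0})))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
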