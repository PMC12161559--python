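"""End-to-end orchestration: generate or read a dataset, apply
exclusions, compute composition and ration scores, run the multivariate
comparisons and the gamma models, and write a delimited-text report.

All randomness flows from one root seed, split per stage
(generation, NMDS restarts, ANOSIM permutations, species-vector
permutations), so any stage can be re-run in isolation and a run is
deterministic given its seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    bray_curtis,
    diet_matrix,
    fit_species_vectors,
    nmds,
    pairwise_anosim,
    simper,
)
from .generate import GeneratorConfig, generate_dataset
from .metrics import composition, fullness_histogram, ration_table
from .models import (
    ModelSpec,
    estimated_marginal_means,
    fit_gamma_loglink,
    pairwise_comparisons,
)
from .records import Dataset, apply_exclusions, read_dataset

log = logging.getLogger("estuarydiet")

DEFAULT_MODEL_SPECS = (
    ModelSpec("ir", ("site", "month", "length_bin")),
    ModelSpec("er", ("site", "month", "length_bin")),
    ModelSpec("jm", ("site", "month", "mark_status")),
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (dict with fish/prey/energy CSV paths)
    or ``generator`` must be provided.
    """

    seed: int = 0
    input_paths: dict[str, str] | None = None
    generator: GeneratorConfig | None = None
    grouping: tuple[str, ...] = ("site", "year")
    length_scheme: str | None = "ordination"
    model_specs: tuple[ModelSpec, ...] = DEFAULT_MODEL_SPECS
    n_permutations: int = 999
    nmds_restarts: int = 8
    output_dir: str = "run_output"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_paths / generator must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        specs = raw.pop("model_specs", None)
        kwargs: dict[str, Any] = dict(raw)
        if gen is not None:
            kwargs["generator"] = GeneratorConfig(**gen)
        if specs is not None:
            kwargs["model_specs"] = tuple(
                ModelSpec(
                    s["response"],
                    tuple(s["factors"]),
                    s.get("blocking", "year"),
                    s.get("reference_levels", {}),
                )
                for s in specs
            )
        if "grouping" in kwargs:
            kwargs["grouping"] = tuple(kwargs["grouping"])
        return cls(**kwargs)


@dataclass
class RunReport:
    exclusions: pd.DataFrame
    table1: pd.DataFrame
    composition_by_site: pd.DataFrame
    rations: pd.DataFrame
    diet_matrix: pd.DataFrame
    nmds_coordinates: pd.DataFrame
    nmds_stress: float
    species_vectors: pd.DataFrame
    anosim_simper: pd.DataFrame
    model_comparisons: pd.DataFrame
    fullness: pd.DataFrame
    temperatures: pd.DataFrame
    manifest: dict


def summarize_table1(ds: Dataset) -> pd.DataFrame:
    """Design bookkeeping: per-site fish counts by month, length bin, and
    mark status, with per-site totals (post-exclusion datasets reproduce
    the study's design table)."""
    from .records import MONTHS, SITES, assign_length_bins

    fish = ds.fish
    sites = [s for s in SITES if s in set(fish["site"])] or sorted(
        fish["site"].unique()
    )
    month_names = {
        2: "February", 3: "March", 4: "April", 5: "May", 6: "June", 7: "July"
    }
    rows = {}
    for m in MONTHS:
        rows[month_names[m]] = [
            int(((fish["site"] == s) & (fish["month"] == m)).sum()) for s in sites
        ]
    if len(fish):
        bins = assign_length_bins(fish["fork_length_mm"], "model")
    else:
        bins = pd.Series(dtype=str)
    for label in ("30-65", "66-99"):
        rows[label] = [
            int(((fish["site"] == s) & (bins == label)).sum()) for s in sites
        ]
    for status in ("unmarked", "marked"):
        rows[status] = [
            int(((fish["site"] == s) & (fish["mark_status"] == status)).sum())
            for s in sites
        ]
    rows["Total"] = [int((fish["site"] == s).sum()) for s in sites]
    return pd.DataFrame.from_dict(rows, orient="index", columns=sites)


def _temperature_summary(ds: Dataset, threshold: float = 17.5) -> pd.DataFrame:
    agg = (
        ds.fish.groupby(["site", "month"])["water_temp_C"]
        .agg(["mean", "min", "max", "count"])
        .reset_index()
    )
    agg["exceeds_17_5"] = agg["mean"] > threshold
    return agg


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=True, float_format="%.10g").encode()
    ).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in order and write every artifact to
    ``cfg.output_dir``.  Optional-stage failures (e.g. too few ordination
    rows for NMDS) are reported in the manifest without aborting."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    gen_seed, nmds_seed, anosim_seed, vec_seed = (
        int(s.generate_state(1)[0]) % (2**31) for s in root.spawn(4)
    )
    failures: dict[str, str] = {}

    if cfg.generator is not None:
        ds, _truth = generate_dataset(cfg.generator.with_seed(gen_seed))
        log.info("generated %d fish, %d prey rows", ds.n_fish, len(ds.prey))
    else:
        ds = read_dataset(
            cfg.input_paths["fish"], cfg.input_paths["prey"], cfg.input_paths["energy"]
        )
        log.info("read %d fish, %d prey rows", ds.n_fish, len(ds.prey))

    ds, report = apply_exclusions(ds)
    log.info(
        "exclusions: %d empty stomach, %d oversize; %d fish retained",
        report.empty_stomach,
        report.oversize,
        ds.n_fish,
    )
    table1 = summarize_table1(ds)
    comp = composition(ds, ("site",))
    rations = ration_table(ds)
    mat = diet_matrix(ds, cfg.grouping, length_scheme=cfg.length_scheme)
    dmat = bray_curtis(mat)
    site_labels = mat.index.get_level_values("site")

    try:
        ord_res = nmds(dmat, n_restarts=cfg.nmds_restarts, seed=nmds_seed)
        coords = ord_res.coordinates.reset_index()
        stress = ord_res.stress
        vectors = fit_species_vectors(
            mat, ord_res, n_permutations=cfg.n_permutations, seed=vec_seed
        )
    except Exception as exc:  # pragma: no cover - defensive
        failures["nmds"] = str(exc)
        coords, stress, vectors = pd.DataFrame(), float("nan"), pd.DataFrame()

    pw = pairwise_anosim(
        dmat, site_labels, n_permutations=cfg.n_permutations, seed=anosim_seed
    )
    simper_heads = []
    for _, row in pw.iterrows():
        res = simper(mat, site_labels, (row["group_a"], row["group_b"]))
        simper_heads.append(", ".join(map(str, res.head_taxa)))
    pw["simper_head_taxa"] = simper_heads

    model_rows = []
    for spec in cfg.model_specs:
        try:
            fit = fit_gamma_loglink(rations, spec)
            for factor in spec.factors:
                emm = estimated_marginal_means(fit, factor)
                cmp_table = pairwise_comparisons(emm, fit)
                cmp_table.insert(0, "factor", factor)
                cmp_table.insert(0, "response", spec.response)
                cmp_table["aicc"] = fit.aicc
                model_rows.append(cmp_table)
        except Exception as exc:
            failures[f"model:{spec.response}"] = str(exc)
    model_table = (
        pd.concat(model_rows, ignore_index=True) if model_rows else pd.DataFrame()
    )

    fullness = fullness_histogram(ds.fish)
    temps = _temperature_summary(ds)

    artifacts = {
        "exclusions.csv": report.to_frame(),
        "table1.csv": table1,
        "composition_by_site.csv": comp,
        "rations.csv": rations,
        "diet_matrix.csv": mat.reset_index(),
        "nmds_coordinates.csv": coords,
        "species_vectors.csv": vectors,
        "anosim_simper.csv": pw,
        "model_comparisons.csv": model_table,
        "fullness.csv": fullness,
        "temperatures.csv": temps,
    }
    hashes = {}
    for name, frame in artifacts.items():
        frame.to_csv(out / name, index=isinstance(frame.index, pd.MultiIndex))
        hashes[name] = _hash_frame(frame)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {
            "generator": gen_seed,
            "nmds": nmds_seed,
            "anosim": anosim_seed,
            "vectors": vec_seed,
        },
        "n_fish": int(ds.n_fish),
        "n_prey_rows": int(len(ds.prey)),
        "exclusions": {
            "empty_stomach": report.empty_stomach,
            "oversize": report.oversize,
        },
        "nmds_stress": None if np.isnan(stress) else round(float(stress), 6),
        "artifact_hashes": hashes,
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(
        exclusions=report.to_frame(),
        table1=table1,
        composition_by_site=comp,
        rations=rations,
        diet_matrix=mat,
        nmds_coordinates=coords,
        nmds_stress=stress,
        species_vectors=vectors,
        anosim_simper=pw,
        model_comparisons=model_table,
        fullness=fullness,
        temperatures=temps,
        manifest=manifest,
    )
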