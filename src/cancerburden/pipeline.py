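"""End-to-end orchestration: inputs -> burden -> rates -> correlations.

:func:`run_analysis` is the pure in-memory composition (a function of the
input tables and options only); :func:`run_pipeline` wraps it with CSV
reading/writing, logging and a YAML run manifest (config, package version,
SHA-256 of every input) sufficient to re-execute the identical run.
"""

from __future__ import annotations

import hashlib
import logging
import platform
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .bands import midpoint_representative_age
from .burden import compute_dalys, compute_ylds, compute_ylls, yll_fraction
from .correlation import correlate_all_sites
from .io import read_table, write_table
from .rates import age_specific_rate, age_standardized_rate, standard_for_sites
from .staging import allocate_stages
from .tables import sites_in

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_analysis", "run_pipeline"]


class PipelineConfig(BaseModel):
    """File-level configuration of one pipeline run."""

    incidence: Path
    deaths: Path
    population: Path
    stage_mix: Path
    life_table: Path
    screening: Path
    treatment_params: Path
    natural_history: Path
    standard_population: Path | None = None  # default: packaged WHO standard
    pairing: tuple[str, ...] = ("county",)
    out_dir: Path = Path("burden_out")

    def input_paths(self) -> dict[str, Path]:
        paths = {
            "incidence": self.incidence,
            "deaths": self.deaths,
            "population": self.population,
            "stage_mix": self.stage_mix,
            "life_table": self.life_table,
            "screening": self.screening,
            "treatment_params": self.treatment_params,
            "natural_history": self.natural_history,
        }
        if self.standard_population is not None:
            paths["standard_population"] = self.standard_population
        return paths


def run_analysis(
    inputs: dict[str, pd.DataFrame],
    pairing: Sequence[str] = ("county",),
    representative_age=midpoint_representative_age,
    standard: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis on in-memory tables.

    ``inputs`` holds the bundle produced by ``simulate_inputs`` (or read
    from disk): incidence, deaths, population, stage_mix, life_table,
    screening, params, nh.  Returns burden, staged incidence, age-specific
    and age-standardized rate tables, YLL/DALY fractions and the
    screening-correlation summary.
    """
    sites = sites_in(inputs["incidence"])

    logger.info("stage allocation: %d unstaged strata", len(inputs["incidence"]))
    staged = allocate_stages(inputs["incidence"], inputs["stage_mix"])
    ylds = compute_ylds(staged, inputs["params"], inputs["nh"],
                        unstaged=inputs["incidence"])
    ylls = compute_ylls(inputs["deaths"], inputs["life_table"],
                        representative_age=representative_age)
    burden = compute_dalys(ylls, ylds)

    pop = inputs["population"]
    age_rates = pd.concat(
        [
            age_specific_rate(inputs["incidence"], pop),
            age_specific_rate(inputs["deaths"], pop),
            age_specific_rate(burden, pop),
        ],
        ignore_index=True,
    )
    std = standard if standard is not None else standard_for_sites(sites)
    std_rates = age_standardized_rate(age_rates, std)

    fractions = yll_fraction(burden, ["cancer_site", "year"])
    daly_rates = std_rates[std_rates["measure"] == "daly"]
    correlations = correlate_all_sites(daly_rates, inputs["screening"], pairing)

    return {
        "staged_incidence": staged,
        "burden": burden,
        "age_specific_rates": age_rates,
        "age_standardized_rates": std_rates,
        "yll_fractions": fractions,
        "correlations": correlations,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Read inputs, run the analysis, write outputs + manifest under out_dir."""
    paths = cfg.input_paths()
    stage = "read inputs"
    try:
        inputs = {
            "incidence": read_table(paths["incidence"], "events"),
            "deaths": read_table(paths["deaths"], "events"),
            "population": read_table(paths["population"], "population"),
            "stage_mix": read_table(paths["stage_mix"], "stage_mix"),
            "life_table": read_table(paths["life_table"], "life_table"),
            "screening": read_table(paths["screening"], "screening"),
            "params": read_table(paths["treatment_params"], "treatment_params"),
            "nh": read_table(paths["natural_history"], "natural_history"),
        }
        standard = None
        if cfg.standard_population is not None:
            sites = sites_in(inputs["incidence"])
            standard = standard_for_sites(
                sites, read_table(paths["standard_population"], "standard_population"))

        stage = "analysis"
        outputs = run_analysis(inputs, pairing=cfg.pairing, standard=standard)

        stage = "write outputs"
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in outputs.items():
            write_table(df, out_dir / f"{name}.csv")

        manifest = {
            "package": "cancerburden",
            "version": __version__,
            "python": platform.python_version(),
            "config": {k: str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v
                       for k, v in cfg.model_dump().items()},
            "input_sha256": {k: _sha256(Path(p)) for k, p in paths.items()},
            "outputs": sorted(f"{name}.csv" for name in outputs),
        }
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    except Exception:
        logger.exception("pipeline failed during stage: %s", stage)
        raise
    logger.info("pipeline complete; outputs in %s", cfg.out_dir)
    return outputs
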