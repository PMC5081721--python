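"""End-to-end orchestration: inputs -> engine -> outcomes -> CEA/PSA -> files.

A pipeline run is fully described by one configuration file (YAML or JSON)
whose ``data`` section either points at a directory of input CSVs or asks
for synthetic inputs::

    data:
      synthetic: {seed: 12345}        # generate EU-like tables
      # or
      dir: path/to/input/csvs        # life_table.csv, morbidity.csv, population.csv

Outputs: ``results_by_option.csv``, ``incremental.csv`` and ``summary.json``
always; ``psa_draws.csv`` and ``ce_plane.csv`` when a probabilistic analysis
is requested; plus a ``manifest.json`` recording the config hash, input
digests, seed and package version, so identical manifests imply identical
result files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cea import incremental_analysis, incremental_table
from .config import (ConfigError, RunConfig, SyntheticConfig, run_config_from_dict)
from .engine import run_all_options
from .io import (LifeTable, MorbidityTable, PopulationPyramid, read_inputs,
                 write_results)
from .outcomes import RunResult
from .psa import PsaResult, export_ce_plane, run_psa
from .synthetic import generate_inputs

__all__ = ["run_pipeline", "results_table"]

RESULT_COLUMNS = ["option", "scenario", "total_cost_eur", "dalys", "yll", "yld",
                  "cost_acute_eur", "cost_chronic_eur", "cost_mortality_eur",
                  "cost_measures_eur", "first_events", "repeat_events",
                  "cad_deaths", "other_deaths"]


def results_table(results: Mapping[str, RunResult]) -> pd.DataFrame:
    """Per-option deterministic results as a DataFrame (stable columns)."""
    rows = [r.summary_row() for r in results.values()]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_raw_config(config_path: Path) -> Mapping[str, Any]:
    text = config_path.read_text(encoding="utf-8")
    raw = json.loads(text) if config_path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{config_path}: top level must be a mapping")
    return raw


def _resolve_inputs(raw: Mapping[str, Any], base_dir: Path,
                    ) -> tuple[LifeTable, MorbidityTable, PopulationPyramid, dict]:
    data = raw.get("data") or {"synthetic": {}}
    if not isinstance(data, Mapping) or ("synthetic" in data) == ("dir" in data):
        raise ConfigError("data: section must contain exactly one of 'synthetic' or 'dir'")
    if "synthetic" in data:
        syn_raw = dict(data["synthetic"] or {})
        try:
            syn = SyntheticConfig(**syn_raw)
        except TypeError as e:
            raise ConfigError(f"data.synthetic: {e}") from None
        life, morbidity, population = generate_inputs(syn)
        meta = {"source": "synthetic", "synthetic": dataclasses.asdict(syn)}
    else:
        data_dir = Path(data["dir"])
        if not data_dir.is_absolute():
            data_dir = base_dir / data_dir
        life, morbidity, population, _ = read_inputs(data_dir)
        meta = {"source": "files",
                "digests": {p.name: _sha256(p) for p in sorted(data_dir.glob("*.csv"))}}
    return life, morbidity, population, meta


def run_pipeline(config_path: str | Path, out_dir: str | Path,
                 seed: int | None = None, scenario: str | None = None,
                 options: tuple[str, ...] | None = None,
                 n_draws: int | None = None, with_psa: bool = False,
                 ) -> dict:
    """Run the configured analysis end to end and write all outputs.

    ``seed``, ``scenario``, ``options`` and ``n_draws`` override the
    corresponding configuration fields (CLI convenience).  Returns the run
    manifest.  A probabilistic analysis runs when ``with_psa`` is true or
    ``n_draws`` is given.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    raw = _load_raw_config(config_path)
    cfg = run_config_from_dict(raw)

    from .config import ScenarioSpec  # local to keep module surface tidy
    if scenario is not None:
        cfg = dataclasses.replace(cfg, scenario=ScenarioSpec.preset(scenario))
    if options is not None:
        cfg = dataclasses.replace(cfg, options=tuple(options))
    psa_cfg = cfg.psa
    if n_draws is not None:
        psa_cfg = dataclasses.replace(psa_cfg, n_draws=int(n_draws))
        with_psa = True
    if seed is not None:
        psa_cfg = dataclasses.replace(psa_cfg, seed=int(seed))
    cfg = dataclasses.replace(cfg, psa=psa_cfg)
    cfg.validate()

    life, morbidity, population, input_meta = _resolve_inputs(raw, config_path.parent)

    results = run_all_options(life, morbidity, population, cfg)
    det_frame = results_table(results)
    if "reference" in results and len(results) > 1:
        incrementals = incremental_analysis(results, cfg.thresholds)
        inc_frame = incremental_table(incrementals)
    else:
        incrementals = []
        inc_frame = incremental_table([])

    psa_result: PsaResult | None = None
    psa_frames: dict[str, pd.DataFrame] = {}
    if with_psa and "reference" in cfg.options:
        psa_result = run_psa(life, morbidity, population, cfg)
        psa_frames["psa_draws"] = psa_result.draws
        psa_frames["ce_plane"] = export_ce_plane(psa_result)

    summary: dict[str, Any] = {
        "scenario": cfg.scenario.name,
        "options": list(cfg.options),
        "horizon_years": cfg.horizon_years,
        "discount_rate": cfg.discount_rate,
        "deterministic": {
            r.option_id: {"total_cost_eur": r.total_cost, "dalys": r.dalys}
            for r in results.values()
        },
        "incremental": {
            r.option_id: {"delta_cost_eur": r.delta_cost, "delta_dalys": r.delta_dalys,
                          "icer_eur_per_daly": r.icer, "ce_class": r.ce_class}
            for r in incrementals
        },
    }
    if psa_result is not None:
        summary["psa"] = psa_result.summary()

    write_results(out_dir, det_frame, inc_frame,
                  psa_draws=psa_frames.get("psa_draws"),
                  ce_plane=psa_frames.get("ce_plane"),
                  summary=summary)

    manifest = {
        "version": __version__,
        "config_path": str(config_path),
        "config_sha256": _sha256(config_path),
        "inputs": input_meta,
        "seed": cfg.psa.seed,
        "scenario": cfg.scenario.name,
        "options": list(cfg.options),
        "with_psa": psa_result is not None,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                           encoding="utf-8")
    return manifest
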