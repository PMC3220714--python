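"""End-to-end orchestration: simulate -> fit -> select -> average -> immigrate.

Runs are driven by a YAML config (seeds mandatory whenever simulation is
requested).  Outputs are CSV/JSON files whose first header line records the
config hash and seed, so any result file can be traced to the exact run that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import capture_data, density_models, immigration, robust_design, synthetic_data

log = logging.getLogger("patchdemog")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


@dataclass
class RunConfig:
    seed: int | None = None
    output_dir: str = "patchdemog_out"
    # density analysis: either a CSV path or simulation from the default truth
    density_csv: str | None = None
    simulate_density: bool = False
    # demography analysis: .inp/CSV paths or simulation from the default truth
    captures_inp: str | None = None
    captures_csv: str | None = None
    simulate_demography: bool = False
    structures: list[str] = field(default_factory=list)  # subset of I1..I9
    floor_zero: bool = False
    drop_ever_young: bool = False
    n_random_starts: int = 5
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(blob, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)} - {"raw"}
        unknown = set(blob) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in blob.items() if k in known})
        cfg.raw = blob
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.simulate_density or self.simulate_demography) and self.seed is None:
            raise ConfigError("a seed is mandatory when simulation is requested")
        for path_attr in ("density_csv", "captures_inp", "captures_csv"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{path_attr} does not exist: {p}")
        bad = set(self.structures) - set(robust_design.table1_structures())
        if bad:
            raise ConfigError(f"unknown structures: {sorted(bad)}")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        raw YAML text excluded, so reruns elsewhere hash identically)."""
        d = dataclasses.asdict(self)
        d.pop("raw", None)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# patchdemog config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, index=False)


def _write_json(obj: Any, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"meta": {"config_hash": cfg.config_hash(), "seed": cfg.seed},
               "result": obj}
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_density_analysis(cfg: RunConfig) -> pd.DataFrame:
    """Fit and rank the eight density models; write table + coefficients.

    Returns the ranked selection table; the models within delta <= 2 of the
    top are reported as equally plausible.
    """
    out = Path(cfg.output_dir)
    if cfg.density_csv:
        records = capture_data.read_density_csv(cfg.density_csv)
        log.info("density: read %d patches from %s", len(records), cfg.density_csv)
    elif cfg.simulate_density:
        truth = synthetic_data.density_truth_study_default()
        records = synthetic_data.simulate_density(truth, seed=cfg.seed)
        log.info("density: simulated %d patches (seed=%s)", len(records), cfg.seed)
    else:
        raise ConfigError("density analysis needs density_csv or simulate_density")
    table, fits = density_models.select(records)
    plausible = list(table.loc[table["delta"] <= 2.0, "model"])
    log.info("density: equally plausible (delta<=2): %s", plausible)
    _write_csv(table, out / "density_selection.csv", cfg)
    coeffs = {
        f.spec.model_id: [
            {"kind": c.spec.kind.value, "scope": sorted(c.spec.scope),
             "intercept": c.intercept, "slope": c.slope,
             "dispersion": c.dispersion, "loglik": c.loglik,
             "boundary": c.boundary}
            for c in f.components
        ]
        for f in fits
    }
    _write_json({"coefficients": coeffs, "plausible": plausible},
                out / "density_coefficients.json", cfg)
    _write_csv(density_models.predicted_curves(fits[0]),
               out / "density_curves.csv", cfg)
    return table


def run_demography_analysis(cfg: RunConfig) -> dict[str, Any]:
    """Nine-structure robust-design analysis with immigration comparison.

    Produces the selection table, model-averaged abundances (with lognormal
    CIs), per-patch survival and growth rates, the per-interval immigrant
    series, and the exact permutation comparison between landscapes.
    """
    out = Path(cfg.output_dir)
    if cfg.captures_inp:
        design = capture_data.study_design()
        data = capture_data.read_inp(cfg.captures_inp, design)
    elif cfg.captures_csv:
        design = capture_data.study_design()
        data = capture_data.read_captures_csv(cfg.captures_csv, design)
    elif cfg.simulate_demography:
        truth = synthetic_data.rd_truth_study_default()
        _, data = synthetic_data.simulate_dataset(truth, seed=cfg.seed)
        log.info("demography: simulated %d individuals (seed=%s)",
                 len(data), cfg.seed)
    else:
        raise ConfigError(
            "demography analysis needs captures_inp, captures_csv "
            "or simulate_demography"
        )
    structures = robust_design.table1_structures()
    if cfg.structures:
        structures = {k: structures[k] for k in cfg.structures}

    fit_seed = (cfg.seed or 0) % 2**31
    table, fits = robust_design.fit_all(
        data, structures, n_random_starts=cfg.n_random_starts, seed=fit_seed
    )
    avg_full = robust_design.model_average_demography(table, fits)

    adults = capture_data.reduce_to_adults(data, drop_ever_young=cfg.drop_ever_young)
    result: dict[str, Any] = {"selection": table}
    if len(adults):
        tab_a, fits_a = robust_design.fit_all(
            data=adults, structures=structures,
            n_random_starts=cfg.n_random_starts, seed=fit_seed,
        )
        avg_adult = robust_design.model_average_demography(tab_a, fits_a)
        landscape_by_patch = dict(data.design.patches)
        series = immigration.immigration_series(
            avg_full, avg_adult, landscape_by_patch, floor_zero=cfg.floor_zero
        )
        comparison = immigration.compare_landscapes(series)
        series_df = pd.DataFrame([dataclasses.asdict(e) for e in series])
        _write_csv(series_df, out / "immigrants.csv", cfg)
        _write_json(dataclasses.asdict(comparison), out / "comparison.json", cfg)
        result["immigrants"] = series_df
        result["comparison"] = comparison
    else:
        log.warning("no adult captures after reduction; immigration step skipped")

    _write_csv(table, out / "rd_selection.csv", cfg)
    _write_csv(avg_full.abundance, out / "abundance.csv", cfg)
    _write_csv(avg_full.phi, out / "survival.csv", cfg)
    _write_csv(avg_full.lam, out / "lambda.csv", cfg)
    result.update(abundance=avg_full.abundance, phi=avg_full.phi, lam=avg_full.lam)
    return result


def run_all(cfg: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if cfg.density_csv or cfg.simulate_density:
        out["density"] = run_density_analysis(cfg)
    if cfg.captures_inp or cfg.captures_csv or cfg.simulate_demography:
        out["demography"] = run_demography_analysis(cfg)
    if not out:
        raise ConfigError("config requests no analysis")
    return out
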