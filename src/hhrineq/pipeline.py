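"""End-to-end study pipeline.

From a city CSV (or a synthetic-data configuration) to the full set of
outputs per outcome: concentration result with interval, curve CSV and
figure, regression table, decomposition table, and a JSON run manifest
recording the seed, a hash of the configuration and package versions.
Given the same configuration and seed the outputs are identical across
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, schema
from .concentration import curve_position
from .decomposition import WagstaffDecomposition
from .exceptions import ConfigurationError
from .io import read_city_csv, write_city_csv
from .plotting import plot_concentration_curve
from .ranks import fractional_rank
from .regression import ModelSpec
from .synthetic import SyntheticConfig, generate_cities
from .concentration import concentration_curve

logger = logging.getLogger("hhrineq")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` (a city CSV) or ``synthetic`` (a
    :class:`SyntheticConfig`) must be given.
    """

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    outcomes: tuple[str, ...] = schema.OUTCOME_COLUMNS
    rank_method: str = "midpoint"
    se_method: str = "convenient_regression"
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "results"
    plot: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of input_path or synthetic must be set"
            )
        unknown = [o for o in self.outcomes if o not in schema.OUTCOME_COLUMNS]
        if unknown:
            raise ConfigurationError(f"unknown outcome column(s) {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _json_safe(obj):
    """Replace NaN/inf with None so emitted JSON is standard-compliant."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns a manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        table = read_city_csv(config.input_path)
        logger.info("read %d cities from %s", len(table), config.input_path)
    else:
        table = generate_cities(config.synthetic)
        write_city_csv(table, out / "cities.csv")
        logger.info("generated %d synthetic cities", len(table))

    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "package_version": __version__,
        "n_cities": int(len(table)),
        "outcomes": {},
        "artifacts": [],
    }

    ranked = fractional_rank(
        table[schema.RANKING_VARIABLE].to_numpy(), method=config.rank_method
    )

    for outcome in config.outcomes:
        spec = ModelSpec.default(outcome)
        model = WagstaffDecomposition(
            table, spec, rank_method=config.rank_method
        )
        result = model.fit(
            se_method=config.se_method, n_boot=config.n_boot, seed=config.seed
        )

        curve = concentration_curve(table[outcome].to_numpy(), ranked)
        position = curve_position(curve)

        tag = outcome.replace("_per_10k", "")
        conc_path = out / f"concentration_{tag}.json"
        conc = result.outcome_c.to_dict()
        conc["curve_position"] = position
        conc_path.write_text(json.dumps(_json_safe(conc), indent=2))

        curve_csv = out / f"curve_{tag}.csv"
        curve.to_frame().to_csv(curve_csv, index=False)

        reg_csv = out / f"regression_{tag}.csv"
        result.regression.to_frame().to_csv(reg_csv)
        reg_txt = out / f"regression_{tag}.txt"
        reg_txt.write_text(result.regression.summary() + "\n")

        dec_csv = out / f"decomposition_{tag}.csv"
        result.to_frame().to_csv(dec_csv)
        dec_txt = out / f"decomposition_{tag}.txt"
        dec_txt.write_text(result.summary() + "\n")

        artifacts = [conc_path, curve_csv, reg_csv, reg_txt, dec_csv, dec_txt]
        if config.plot:
            fig_path = out / f"curve_{tag}.png"
            plot_concentration_curve(
                curve, path=fig_path, title=f"Concentration curve: {outcome}"
            )
            artifacts.append(fig_path)

        manifest["outcomes"][outcome] = {
            "concentration_index": result.outcome_c.c,
            "se": result.outcome_c.se,
            "ci95": [result.outcome_c.ci95_low, result.outcome_c.ci95_high],
            "curve_position": position,
            "total_explained_percent": result.total_explained_percent,
            "residual_percent": result.residual_percent,
            "additivity_gap": result.additivity_gap,
        }
        manifest["artifacts"] += [str(p) for p in artifacts]
        logger.info(
            "%s: C=%.4f (%s), explained %.1f%%",
            outcome,
            result.outcome_c.c,
            position,
            result.total_explained_percent,
        )

    (out / "manifest.json").write_text(
        json.dumps(_json_safe(manifest), indent=2, default=str)
    )
    return manifest
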