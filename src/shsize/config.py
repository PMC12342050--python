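"""Run configuration, validation, and fixture generation.

Configurations are plain JSON or YAML mappings with four blocks::

    {
      "model":      {"mu": 1.0, "k": 1.0, "alpha": 1.0}        # single-step
                    or {"mu": 1.0, "rates": [5, 5, 5, 5, 5]}   # multi-stage
                    or {"mu": 1.0, "k": 1.0, "M": 5}           # equal rates
      "partition":  {"mean": 0.5, "cv2": 0.0},
      "simulation": {"s0": 1.0, "n_cycles": 10000, "burn_in_cycles": 100},
      "seed": 0
    }

Validation is schema-strict (unknown keys rejected) and exhaustive: every
violation is reported in one error, not just the first.  The validated
configuration is echoed into each output's JSON sidecar for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .moments import MultiStepParams, SingleStepParams
from .partition import PartitionLaw, make_partition_law
from .simulate import SimConfig, simulate_lineage, ensemble_snapshot

__all__ = ["RunConfig", "load_config", "dump_config", "make_fixtures"]

_MODEL_KEYS = {"mu", "k", "alpha", "rates", "M"}
_PARTITION_KEYS = {"mean", "cv2"}
_SIM_KEYS = {"s0", "n_cycles", "burn_in_cycles"}
_TOP_KEYS = {"model", "partition", "simulation", "seed", "log_level", "out_dir"}

_SIM_DEFAULTS = {"s0": 1.0, "n_cycles": 10_000, "burn_in_cycles": 100}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults applied."""

    model: dict
    partition: dict
    simulation: dict
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."

    def build_model(self) -> SingleStepParams | MultiStepParams:
        m = self.model
        if "rates" in m:
            return MultiStepParams(mu=m["mu"], rates=tuple(m["rates"]))
        if "M" in m:
            return MultiStepParams.equal_rates(m["mu"], m["k"], m["M"])
        return SingleStepParams(mu=m["mu"], k=m["k"], alpha=m.get("alpha", 1.0))

    def build_partition(self) -> PartitionLaw:
        return make_partition_law(self.partition["mean"], self.partition["cv2"])

    def build_sim_config(self) -> SimConfig:
        return SimConfig(
            model=self.build_model(),
            partition=self.build_partition(),
            seed=self.seed,
            **self.simulation,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate(raw: dict) -> tuple[RunConfig | None, list[str]]:
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["configuration root must be a mapping"]
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")

    model = raw.get("model")
    if not isinstance(model, dict):
        errors.append("missing or non-mapping 'model' block")
        model = {}
    for key in model:
        if key not in _MODEL_KEYS:
            errors.append(f"unknown model key {key!r}")
    if "mu" not in model:
        errors.append("model.mu is required")
    if "rates" in model and ("alpha" in model or "M" in model):
        errors.append("model.rates is mutually exclusive with model.alpha / model.M")
    if "alpha" in model and "M" in model:
        errors.append("model.alpha and model.M are mutually exclusive")
    if "rates" not in model and "k" not in model:
        errors.append("model.k is required unless explicit rates are given")

    partition = dict(raw.get("partition") or {})
    for key in partition:
        if key not in _PARTITION_KEYS:
            errors.append(f"unknown partition key {key!r}")
    partition.setdefault("mean", 0.5)
    partition.setdefault("cv2", 0.0)

    sim = dict(raw.get("simulation") or {})
    for key in sim:
        if key not in _SIM_KEYS:
            errors.append(f"unknown simulation key {key!r}")
    for key, default in _SIM_DEFAULTS.items():
        sim.setdefault(key, default)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
        seed = 0

    if errors:
        return None, errors
    cfg = RunConfig(
        model=model,
        partition=partition,
        simulation=sim,
        seed=seed,
        log_level=raw.get("log_level", "INFO"),
        out_dir=raw.get("out_dir", "."),
    )
    try:  # construct domain objects so bad values surface here, not later
        cfg.build_sim_config()
    except (ValueError, TypeError) as exc:
        return None, [str(exc)]
    return cfg, []


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML configuration file.

    All schema violations are reported together in one :class:`ValueError`.
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    cfg, errors = _validate(raw)
    if errors:
        raise ValueError(
            f"invalid configuration {path}:\n" + "\n".join(f"  - {e}" for e in errors)
        )
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back to JSON/YAML; load(dump(load(x))) == load(x)."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int, out_dir: str | Path, n_cycles: int = 100_000) -> dict:
    """Write the canonical synthetic datasets used by tests and docs.

    Four seeded datasets, each a CSV plus a JSON manifest recording the
    generating parameters (ground truth for recovery tests):

    * ``adder_cycles`` — single-step adder, precise halving;
    * ``adder_noisy_cycles`` — single-step adder, ``CV2_beta = 0.05``;
    * ``multistep_m5_cycles`` — equal-rate 5-stage model, ``CV2_beta = 0.02``;
    * ``alpha2_snapshot`` — ensemble of end-time sizes at hazard ``k s^2``.

    Byte-identical across runs for a fixed seed.  Returns a manifest dict
    mapping dataset name to file paths and true parameters.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "package_version": __version__, "datasets": {}}

    def _write_cycles(name: str, cfg: SimConfig, params: dict) -> None:
        _, cycles = simulate_lineage(cfg)
        csv_path = out / f"{name}.csv"
        cycles.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        entry = {
            "csv": csv_path.name,
            "kind": "cycles",
            "true_params": params,
            "n_cycles": cfg.n_cycles,
            "columns": {
                "birth_size": "size units",
                "division_size": "size units",
                "added_size": "size units",
                "interdivision_time": "1/mu units",
                "beta": "dimensionless fraction",
            },
        }
        manifest["datasets"][name] = entry
        (out / f"{name}.manifest.json").write_text(
            json.dumps(entry, indent=2, sort_keys=True) + "\n"
        )

    _write_cycles(
        "adder_cycles",
        SimConfig(
            model=SingleStepParams(mu=1.0, k=1.0, alpha=1.0),
            partition=make_partition_law(0.5, 0.0),
            n_cycles=n_cycles,
            seed=seed,
        ),
        {"mu": 1.0, "k": 1.0, "alpha": 1.0, "beta_mean": 0.5, "beta_cv2": 0.0},
    )
    _write_cycles(
        "adder_noisy_cycles",
        SimConfig(
            model=SingleStepParams(mu=1.0, k=1.0, alpha=1.0),
            partition=make_partition_law(0.5, 0.05),
            n_cycles=n_cycles,
            seed=seed + 1,
        ),
        {"mu": 1.0, "k": 1.0, "alpha": 1.0, "beta_mean": 0.5, "beta_cv2": 0.05},
    )
    _write_cycles(
        "multistep_m5_cycles",
        SimConfig(
            model=MultiStepParams.equal_rates(1.0, 1.0, 5),
            partition=make_partition_law(0.5, 0.02),
            n_cycles=n_cycles,
            seed=seed + 2,
        ),
        {"mu": 1.0, "k": 1.0, "M": 5, "beta_mean": 0.5, "beta_cv2": 0.02},
    )

    snap_cfg = SimConfig(
        model=SingleStepParams(mu=1.0, k=1.0, alpha=2.0),
        partition=make_partition_law(0.5, 0.0),
        n_cycles=2,
        burn_in_cycles=0,
        seed=seed + 3,
    )
    n_snap = max(1000, n_cycles // 10)
    sizes = ensemble_snapshot(snap_cfg, n_lineages=n_snap, t_snapshot=10.0)
    csv_path = out / "alpha2_snapshot.csv"
    np.savetxt(
        csv_path, sizes, fmt="%.10g", header="size", comments="", delimiter=","
    )
    entry = {
        "csv": csv_path.name,
        "kind": "snapshot",
        "true_params": {
            "mu": 1.0,
            "k": 1.0,
            "alpha": 2.0,
            "beta_mean": 0.5,
            "beta_cv2": 0.0,
        },
        "n_lineages": n_snap,
        "t_snapshot": 10.0,
        "columns": {"size": "size units"},
    }
    manifest["datasets"]["alpha2_snapshot"] = entry
    (out / "alpha2_snapshot.manifest.json").write_text(
        json.dumps(entry, indent=2, sort_keys=True) + "\n"
    )

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
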