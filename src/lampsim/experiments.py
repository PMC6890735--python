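"""Named experiment presets and ensemble I/O.

Each preset is a list of parameter overrides reproducing one of the study's
parameter explorations: the treatment-intensity sweep, the gene-flow
comparison, the detection experiment, and the cost-of-resistance sweep with
treatment halted at year 100.  ``run_experiment`` executes every
combination, writing per-replicate trajectories, ensemble summaries, and a
JSON manifest with the fully resolved parameter set and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory, run_replicates
from .observers import summarize_ensemble
from .parameters import ModelParams, ParameterError, serialize_params

__all__ = ["SweepSpec", "PRESETS", "run_experiment", "summarize_experiment"]


@dataclass
class SweepSpec:
    """A named experiment: a list of override dicts, replicates, seed, output."""

    name: str
    overrides: Sequence[Mapping[str, Any]]
    n_replicates: int = 100
    base_seed: int = 0
    out_dir: Optional[Path] = None
    base_params: Optional[ModelParams] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        base = self.base_params or ModelParams()
        for ov in self.overrides:
            base.replace(**dict(ov))  # validates override keys/values eagerly


PRESETS: dict[str, list[dict[str, Any]]] = {
    # Annual treatment of 5, 10, 20 and 30% of tributaries.
    "fig2_treatment_sweep": [
        {"treated_fraction": f} for f in (0.05, 0.10, 0.20, 0.30)
    ],
    # No-homing baseline vs linear stepping-stone at 1-20% gene flow.
    "fig4_geneflow": [
        {"migration_mode": "no_homing"},
        *({"migration_mode": "stepping_stone", "gene_flow": m}
          for m in (0.01, 0.05, 0.10, 0.20)),
    ],
    # Default dynamics for the surveillance-sampling experiment.
    "fig5_detection": [{}],
    # Costs 0-0.5 with treatment stopped at year 100.
    "fig6_cost": [
        {"resistance_cost": c, "tfm_stop_year": 100}
        for c in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    ],
}


def _combo_dir(root: Path, i: int, overrides: Mapping[str, Any]) -> Path:
    tag = "_".join(f"{k}={v}" for k, v in overrides.items()) or "default"
    tag = tag.replace("/", "-")
    return root / f"{i:02d}_{tag}"


def save_trajectory(traj: Trajectory, path: Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def run_experiment(spec: SweepSpec) -> Path:
    """Run every parameter combination of a sweep and write results.

    Layout: ``<out>/<combo>/replicate_<i>.csv`` plus ``summary.csv`` and a
    ``manifest.json`` capturing resolved parameters and seeds.
    """
    if spec.out_dir is None:
        raise ParameterError("SweepSpec.out_dir is required to run an experiment")
    root = Path(spec.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    base = spec.base_params or ModelParams()

    manifest: dict[str, Any] = {
        "experiment": spec.name,
        "n_replicates": spec.n_replicates,
        "base_seed": spec.base_seed,
        "combinations": [],
    }
    for i, overrides in enumerate(spec.overrides):
        params = base.replace(**dict(overrides))
        combo_seed = int(np.random.SeedSequence([spec.base_seed, i]).generate_state(1)[0] % (2**31))
        cdir = _combo_dir(root, i, overrides)
        cdir.mkdir(parents=True, exist_ok=True)
        trajs = run_replicates(params, spec.n_replicates, combo_seed)
        for r, traj in enumerate(trajs):
            save_trajectory(traj, cdir / f"replicate_{r:03d}.csv")
        summary = summarize_ensemble(
            trajs, params.resistant_intro_year,
            rng=np.random.default_rng(combo_seed))
        summary.to_frame().to_csv(cdir / "summary.csv", index=False)
        summary.detection_curve.to_csv(cdir / "detection.csv", index=False)
        serialize_params(params, cdir / "params.json")
        manifest["combinations"].append({
            "dir": cdir.name, "overrides": dict(overrides), "seed": combo_seed,
        })
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return root


def summarize_experiment(results_dir: Path) -> pd.DataFrame:
    """Collate per-combination summary tables from a results directory."""
    root = Path(results_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    rows = []
    for combo in manifest["combinations"]:
        cdir = root / combo["dir"]
        summary = pd.read_csv(cdir / "summary.csv")
        summary.insert(0, "combination", combo["dir"])
        for k, v in combo["overrides"].items():
            summary[k] = v
        rows.append(summary)
    if not rows:
        raise FileNotFoundError(f"no combination results under {root}")
    return pd.concat(rows, ignore_index=True)


def preset_spec(name: str, n_replicates: int, base_seed: int, out_dir: Path,
                base_params: Optional[ModelParams] = None) -> SweepSpec:
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SweepSpec(name=name, overrides=PRESETS[name], n_replicates=n_replicates,
                     base_seed=base_seed, out_dir=out_dir, base_params=base_params)
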