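"""Experiment driver: evaluation ensembles, baseline, reporting.

Reproduces the localization statistics table: success fraction and
mean jumps (+/- sample SD) over ensembles of independently generated
fibrillating tissues with one or two drivers, along with the exact
random-placement baseline those numbers are compared against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import lattice_model as lm
from .electrogram import valid_centre_columns
from .forest_models import ModelBundle, generate_training_set, probe_on_circuit, train_models
from .search import DEFAULT_JUMP_LIMIT, locate_all, locate_driver

logger = logging.getLogger(__name__)

# Desk-scale defaults: 500 training tissues / 200 evaluation runs.
DEFAULT_N_TRAIN_TISSUES = 500
DEFAULT_N_EVAL_RUNS = 200


@dataclass(frozen=True)
class ExperimentConfig:
    n_train_tissues: int = DEFAULT_N_TRAIN_TISSUES
    n_eval_runs: int = DEFAULT_N_EVAL_RUNS
    n_drivers: int = 1
    jump_limit: int = DEFAULT_JUMP_LIMIT
    train_seed: int = 0
    eval_seed: int = 1
    scale_label: str = "desk"
    model: lm.ModelConfig = field(default_factory=lm.ModelConfig)

    def __post_init__(self) -> None:
        if min(self.n_train_tissues, self.n_eval_runs, self.jump_limit) < 1:
            raise ValueError("all experiment counts must be >= 1")
        if self.n_drivers not in (1, 2):
            raise ValueError("n_drivers must be 1 or 2")


@dataclass
class DriverStats:
    success_fraction: float
    mean_jumps: float
    sd_jumps: float
    failure_modes: dict[str, int]
    n_runs: int


@dataclass
class EvaluationSummary:
    per_driver: list[DriverStats]
    n_runs: int
    n_drivers: int
    config: dict

    def to_dict(self) -> dict:
        return {
            "per_driver": [asdict(d) for d in self.per_driver],
            "n_runs": self.n_runs,
            "n_drivers": self.n_drivers,
            "config": self.config,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def train_bundle(config: ExperimentConfig) -> ModelBundle:
    """Generate the training corpus and fit the four forests."""
    table = generate_training_set(
        config.n_train_tissues,
        config=config.model,
        rng=np.random.default_rng(config.train_seed),
    )
    return train_models(table, rng=config.train_seed)


def _run_once(
    config: ExperimentConfig, bundle: ModelBundle, run_index: int
) -> list[dict]:
    """One evaluation tissue: generate, fibrillate, search; one outcome
    record per expected driver."""
    mc = config.model
    rng = np.random.default_rng([config.eval_seed, run_index])
    for _ in range(5):
        tissue = lm.build_tissue(mc, rng)
        if config.n_drivers == 1:
            anchors = [lm.sample_anchor(mc, rng)]
        else:
            anchors = lm.sample_two_anchors(mc, rng)
        circuits = [lm.insert_circuit(tissue, a) for a in anchors]
        try:
            sim, _ = lm.initialize_af(tissue, circuits, rng=rng)
            break
        except lm.InitializationError:
            logger.warning("run %d: initialization failed; resampling", run_index)
    else:
        raise lm.InitializationError(f"run {run_index}: repeated initialization failures")

    if config.n_drivers == 1:
        results = [
            locate_driver(sim, bundle, rng, circuits=circuits, jump_limit=config.jump_limit)
        ]
    else:
        results = locate_all(
            sim, bundle, rng, circuits=circuits, n_expected=2,
            jump_limit=config.jump_limit,
        )
    outcomes = []
    for i in range(config.n_drivers):
        if i < len(results) and results[i].failure_mode != "no_driver_expected":
            r = results[i]
            outcomes.append(
                {"success": bool(r.success), "jumps": int(r.jumps),
                 "failure_mode": r.failure_mode or "none"}
            )
        else:
            mode = (
                results[i].failure_mode
                if i < len(results)
                else "not_attempted"
            )
            outcomes.append({"success": False, "jumps": 0, "failure_mode": mode})
    return outcomes


def run_localization_table(config: ExperimentConfig, bundle: ModelBundle) -> EvaluationSummary:
    """Evaluate the trained search over ``n_eval_runs`` independent
    tissues and summarize per-driver statistics."""
    per_run = [_run_once(config, bundle, i) for i in range(config.n_eval_runs)]
    per_driver = []
    for d in range(config.n_drivers):
        outs = [run[d] for run in per_run]
        succ = np.array([o["success"] for o in outs])
        jumps = np.array([o["jumps"] for o in outs], dtype=float)
        counted = jumps[jumps > 0]
        modes: dict[str, int] = {}
        for o in outs:
            modes[o["failure_mode"]] = modes.get(o["failure_mode"], 0) + 1
        per_driver.append(
            DriverStats(
                success_fraction=float(succ.mean()),
                mean_jumps=float(counted.mean()) if counted.size else 0.0,
                sd_jumps=float(counted.std(ddof=1)) if counted.size > 1 else 0.0,
                failure_modes=modes,
                n_runs=len(outs),
            )
        )
    cfg = asdict(config)
    cfg["model"] = asdict(config.model)
    return EvaluationSummary(
        per_driver=per_driver,
        n_runs=config.n_eval_runs,
        n_drivers=config.n_drivers,
        config=cfg,
    )


def random_placement_baseline(
    L: int = 200,
    circuit: lm.CircuitSpec | None = None,
) -> float:
    """Exact fraction of uniformly random multiprobe placements whose
    7x7 region overlaps the circuit footprint (enumeration over all
    valid centres: every row, columns that keep the window in-bounds)."""
    if circuit is None:
        circuit = lm.CircuitSpec(anchor=(L // 2, (L - 30) // 2))
    cols = valid_centre_columns(L)
    hits = 0
    total = 0
    for row in range(L):
        for col in cols:
            total += 1
            if probe_on_circuit((row, col), circuit, L):
                hits += 1
    return hits / total


def monte_carlo_baseline(
    n: int,
    rng: np.random.Generator,
    L: int = 200,
    circuit: lm.CircuitSpec | None = None,
) -> float:
    """Monte-Carlo estimate of the same placement probability (oracle
    cross-check for the exact enumeration)."""
    if circuit is None:
        circuit = lm.CircuitSpec(anchor=(L // 2, (L - 30) // 2))
    cols = valid_centre_columns(L)
    rows = rng.integers(0, L, size=n)
    cs = rng.integers(cols.start, cols.stop, size=n)
    return float(
        np.mean([probe_on_circuit((int(r), int(c)), circuit, L) for r, c in zip(rows, cs)])
    )


# Published reference values for the full-scale (5000/1500) experiment.
REFERENCE_TABLE = {
    "one_circuit": {"success": 0.954, "mean_jumps": 5.0, "sd_jumps": 1.7},
    "two_circuits_first": {"success": 0.951, "mean_jumps": 5.2, "sd_jumps": 2.2},
    "two_circuits_second": {"success": 0.926, "mean_jumps": 6.1, "sd_jumps": 4.2},
}


def report(summary: EvaluationSummary, targets: dict | None = None) -> dict:
    """Side-by-side comparison with reference values, with binomial
    confidence intervals at the evaluated run count."""
    if summary.n_runs < 1:
        raise ValueError("summary contains no runs")
    if targets is None:
        if summary.n_drivers == 1:
            keys = ["one_circuit"]
        else:
            keys = ["two_circuits_first", "two_circuits_second"]
        targets = {k: REFERENCE_TABLE[k] for k in keys}
    out: dict = {"n_runs": summary.n_runs, "drivers": []}
    for stats, (name, ref) in zip(summary.per_driver, targets.items()):
        p = stats.success_fraction
        half = 1.96 * float(np.sqrt(max(p * (1 - p), 1e-12) / stats.n_runs))
        out["drivers"].append(
            {
                "target": name,
                "success_fraction": p,
                "success_ci95_halfwidth": half,
                "mean_jumps": stats.mean_jumps,
                "sd_jumps": stats.sd_jumps,
                "failure_modes": stats.failure_modes,
                "reference": ref,
            }
        )
    return out


def format_report(rep: dict) -> str:
    lines = [f"evaluation over {rep['n_runs']} runs"]
    for d in rep["drivers"]:
        ref = d["reference"]
        lines.append(
            f"  {d['target']}: success {100 * d['success_fraction']:.1f}% "
            f"(+/- {100 * d['success_ci95_halfwidth']:.1f}pp, ref {100 * ref['success']:.1f}%), "
            f"jumps {d['mean_jumps']:.1f} +/- {d['sd_jumps']:.1f} "
            f"(ref {ref['mean_jumps']:.1f} +/- {ref['sd_jumps']:.1f})"
        )
    return "\n".join(lines)
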