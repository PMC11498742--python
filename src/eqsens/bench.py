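"""Desk-scale benchmark harness: log-uniform parameter sampling, per-pair
failure-rate tabulation, gradient-agreement statistics, and the
equilibration-vs-total timing decomposition.

The evaluation design mirrors large-scale method benchmarking: sample
parameter vectors log-uniformly within the declared bounds, run simulation
and gradient computation with every method pair, classify each sample as
ok or failed (numerical error, negative states, no steady state, Newton
non-convergence, tailored method inapplicable), and compare the gradients of
mutually successful samples between pairs. Gradient agreement is quantified
by the Pearson correlation of log10 absolute gradient entries (signed
entries are handled by correlating magnitudes and reporting sign mismatches
separately; an untransformed correlation is reported as well) plus maximum
and median elementwise relative deviations with floor 1e-12.

Wall-clock timings are diagnostic output only, never test assertions.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import Dataset
from .model import OdeModel, derive
from .objective import OK, GradientResult, MethodPair, objective_gradient
from .steady_state import EquilibrationConfig

__all__ = [
    "BenchmarkReport",
    "sample_parameters",
    "classify_outcome",
    "compare_gradients",
    "run_benchmark",
]

DEVIATION_FLOOR = 1e-12


@dataclass
class BenchmarkReport:
    """Aggregated benchmark outcome; serializes to plain JSON types."""

    n_samples: int
    seed: int
    pair_names: list
    failure_counts: dict  # pair -> {category: count}
    n_ok: dict  # pair -> count
    agreement: dict  # "pairA|pairB" -> statistics dict
    timings: dict  # pair -> {"total": s, "equilibration": s, "dynamic": s}
    statuses: dict = field(default_factory=dict)  # pair -> [status per sample]

    def failure_rate(self, pair_name: str) -> float:
        """Failure rate in percent for one pair."""
        failed = sum(self.failure_counts.get(pair_name, {}).values())
        return 100.0 * failed / self.n_samples if self.n_samples else 0.0

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "pair_names": list(self.pair_names),
            "failure_counts": self.failure_counts,
            "n_ok": self.n_ok,
            "agreement": self.agreement,
            "timings": self.timings,
            "statuses": self.statuses,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkReport":
        return cls(
            n_samples=d["n_samples"],
            seed=d["seed"],
            pair_names=list(d["pair_names"]),
            failure_counts=d["failure_counts"],
            n_ok=d["n_ok"],
            agreement=d["agreement"],
            timings=d["timings"],
            statuses=d.get("statuses", {}),
        )


def sample_parameters(model: OdeModel, n: int, seed: int) -> list:
    """Draw n parameter vectors uniformly on each parameter's declared scale
    (log-uniform for log10-scaled parameters) within the bounds; returned on
    linear scale, reproducibly for a given seed."""
    for p in model.parameters:
        if p.scale == "log10" and p.lower <= 0:
            raise ValidationError(
                f"parameter {p.name!r}: log-uniform sampling needs positive bounds"
            )
        if not (np.isfinite(p.lower) and np.isfinite(p.upper)):
            raise ValidationError(f"parameter {p.name!r}: bounds must be finite")
    rng = np.random.default_rng(seed)
    return [model.sample_theta(rng) for _ in range(int(n))]


def classify_outcome(result) -> str:
    """Failure category of a simulation or gradient result, or ``ok``.

    A parameter vector counts as failed as soon as any of its conditions'
    simulations failed; the orchestration already propagates the first
    failure, so the result's own status is the sample's category.
    """
    return result.status


def _pearson(a: np.ndarray, b: np.ndarray):
    if a.size < 2:
        return None
    if np.allclose(a, b):
        return 1.0
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def compare_gradients(grad_sets: dict, floor: float = DEVIATION_FLOOR) -> dict:
    """Pairwise agreement statistics between per-pair gradient collections.

    ``grad_sets`` maps pair name -> {sample index: gradient vector}. For each
    unordered pair of pairs the gradients of mutually successful samples are
    pooled elementwise and compared: Pearson correlation of log10 absolute
    values (entries with magnitude <= floor excluded), untransformed Pearson
    correlation, sign-mismatch count, and max/median relative deviations
    |g1-g2| / max(|g1|, |g2|, floor). Fewer than two common samples yields an
    undefined-agreement marker instead of a crash.
    """
    out = {}
    for pa, pb in itertools.combinations(sorted(grad_sets), 2):
        common = sorted(set(grad_sets[pa]) & set(grad_sets[pb]))
        key = f"{pa}|{pb}"
        if len(common) < 2:
            out[key] = {"n_common": len(common), "defined": False}
            continue
        g1 = np.concatenate([np.asarray(grad_sets[pa][i], float) for i in common])
        g2 = np.concatenate([np.asarray(grad_sets[pb][i], float) for i in common])
        mask = (np.abs(g1) > floor) & (np.abs(g2) > floor)
        rel = np.abs(g1 - g2) / np.maximum(
            np.maximum(np.abs(g1), np.abs(g2)), floor
        )
        entry = {
            "n_common": len(common),
            "defined": True,
            "pearson_log10_abs": _pearson(
                np.log10(np.abs(g1[mask])), np.log10(np.abs(g2[mask]))
            ),
            "pearson_linear": _pearson(g1, g2),
            "sign_mismatches": int(np.sum(np.sign(g1[mask]) != np.sign(g2[mask]))),
            "max_rel_dev": float(rel.max()) if rel.size else 0.0,
            "median_rel_dev": float(np.median(rel)) if rel.size else 0.0,
        }
        out[key] = entry
    return out


def run_benchmark(
    model: OdeModel,
    data: Dataset,
    pairs: Sequence[MethodPair],
    n: int,
    seed: int,
    config: Optional[EquilibrationConfig] = None,
    deriv=None,
) -> BenchmarkReport:
    """Evaluate every method pair on n log-uniformly sampled parameter
    vectors: objective gradients, failure categories, pairwise gradient
    agreement over mutually successful samples, and per-phase timings.

    Deterministic for a given seed up to the wall-clock timing fields;
    failures are data, not errors.
    """
    config = config or EquilibrationConfig()
    deriv = deriv if deriv is not None else derive(model)
    thetas = sample_parameters(model, n, seed)

    failure_counts: dict = {}
    n_ok: dict = {}
    statuses: dict = {}
    timings: dict = {}
    grad_sets: dict = {}
    for pair in pairs:
        name = pair.name
        failure_counts[name] = {}
        n_ok[name] = 0
        statuses[name] = []
        timings[name] = {"total": 0.0, "equilibration": 0.0, "dynamic": 0.0}
        grad_sets[name] = {}
        for i, theta in enumerate(thetas):
            result = objective_gradient(model, deriv, theta, data, pair, config)
            category = classify_outcome(result)
            statuses[name].append(category)
            t = result.timings
            timings[name]["total"] += t.get("total", 0.0)
            timings[name]["equilibration"] += t.get("equilibration", 0.0)
            timings[name]["dynamic"] += t.get("dynamic", 0.0)
            if category == OK:
                n_ok[name] += 1
                grad_sets[name][i] = result.gradient
            else:
                failure_counts[name][category] = (
                    failure_counts[name].get(category, 0) + 1
                )

    agreement = compare_gradients(grad_sets)
    return BenchmarkReport(
        n_samples=int(n),
        seed=int(seed),
        pair_names=[p.name for p in pairs],
        failure_counts=failure_counts,
        n_ok=n_ok,
        agreement=agreement,
        timings=timings,
        statuses=statuses,
    )
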