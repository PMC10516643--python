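"""Benchmark harness: truth matching, sensitivity/precision/F1, and the
structural-exclusion sensitivity bound of chromosome/strand-restricted
detectors.

A predicted call is a true positive when BOTH its fusion junction and its
backsplice junction fall within ``tolerance`` bp (every endpoint, matching
chromosome and strand) of one still-unmatched truth record; the one-to-one
assignment is solved exactly (minimum-distance maximum-cardinality
bipartite matching), which is cheap at benchmark scale and provably equal
to the optimal oracle.
"""

from __future__ import annotations

import logging
import math
import shutil
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import FilterConfig
from .detect import DetectParams
from .model import FcircRNACall, SimTruthRecord
from .simulate import SimConfig

log = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    iteration: int
    TP: int
    FP: int
    FN: int
    sensitivity: float
    precision: float
    f1: float


def _endpoint_distance(call: FcircRNACall, truth: SimTruthRecord) -> Optional[int]:
    """Max endpoint deviation between a call and a truth record, or None."""
    pairs = (
        (call.fusion.donor, truth.fusion_donor),
        (call.fusion.acceptor, truth.fusion_acceptor),
        (call.backsplice.donor, truth.backsplice_donor),
        (call.backsplice.acceptor, truth.backsplice_acceptor),
    )
    dist = 0
    for got, want in pairs:
        if got.chrom != want.chrom or got.strand != want.strand:
            return None
        dist = max(dist, abs(got.pos - want.pos))
    return dist


def match_calls(
    predicted: Sequence[FcircRNACall],
    truth: Sequence[SimTruthRecord],
    tolerance: int = 5,
) -> tuple[int, int, int]:
    """Optimal one-to-one matching of calls to truth within ``tolerance`` bp.

    Maximum-cardinality assignment with minimum total distance, solved with
    the Hungarian algorithm.  Returns (TP, FP, FN); leftovers on the
    prediction side are FP, on the truth side FN.
    """
    if not predicted or not truth:
        return 0, len(predicted), len(truth)
    big = (tolerance + 1) * (len(predicted) + len(truth) + 1)
    cost = np.full((len(predicted), len(truth)), big, dtype=float)
    for pi, call in enumerate(predicted):
        for ti, tr in enumerate(truth):
            d = _endpoint_distance(call, tr)
            if d is not None and d <= tolerance:
                cost[pi, ti] = d
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(cost)
    tp = int(np.sum(cost[rows, cols] < big))
    return tp, len(predicted) - tp, len(truth) - tp


def compute_metrics(TP: int, FP: int, FN: int, iteration: int = 0) -> BenchmarkResult:
    """Sensitivity, precision and F1 with the 0/0 -> 0 convention."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be >= 0")
    sens = TP / (TP + FN) if TP + FN else 0.0
    prec = TP / (TP + FP) if TP + FP else 0.0
    f1 = 2 * sens * prec / (sens + prec) if sens + prec else 0.0
    return BenchmarkResult(iteration, TP, FP, FN, sens, prec, f1)


def floor_percent(fraction: float) -> float:
    """Percentage floored (truncated) to one decimal, e.g. 26/30 -> 86.6."""
    return math.floor(fraction * 1000) / 10


def acfs_exclusion_bound(truth: Sequence[SimTruthRecord]) -> float:
    """Maximum sensitivity of a detector that skips same-strand same-chromosome events.

    Returns (N - n_excluded)/N where excluded events are those whose partner
    genes lie on the same strand of the same chromosome -- the geometry such
    tools systematically cannot report.
    """
    if not truth:
        raise ValueError("empty truth set")
    excluded = sum(1 for t in truth if t.same_chrom_same_strand)
    return (len(truth) - excluded) / len(truth)


def run_iterations(
    config: SimConfig,
    n_iterations: int,
    base_seed: int = 0,
    detect_params: Optional[DetectParams] = None,
    filters: Optional[FilterConfig] = None,
    tolerance: int = 5,
    keep_dirs: bool = False,
) -> tuple[list[BenchmarkResult], dict]:
    """Repeat the full simulate->detect->classify->match loop.

    Iteration i reseeds the simulator with ``base_seed + i``.  The summary
    reports the mean and sample SD of each metric over successful
    iterations; failed iterations are logged and excluded.
    """
    from .pipeline import run_detection, simulate_dataset

    results: list[BenchmarkResult] = []
    for i in range(n_iterations):
        cfg = replace(config, seed=base_seed + i)
        tmp = Path(tempfile.mkdtemp(prefix="fcircbench_"))
        try:
            ds = simulate_dataset(cfg, tmp)
            det = run_detection(ds.sam_path, ds.genes, ds.genome, detect_params, filters)
            tp, fp, fn = match_calls(det.calls, ds.truths, tolerance)
            results.append(compute_metrics(tp, fp, fn, iteration=i))
        except Exception as exc:
            log.warning("iteration %d failed and is excluded: %s", i, exc)
        finally:
            if not keep_dirs:
                shutil.rmtree(tmp, ignore_errors=True)

    summary: dict = {"n_iterations": n_iterations, "n_successful": len(results)}
    for metric in ("sensitivity", "precision", "f1"):
        vals = np.array([getattr(r, metric) for r in results], dtype=float)
        if len(vals) == 0:
            summary[metric] = None
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary[metric] = {
            "mean": mean,
            "sd": sd,
            "mean_percent": round(mean * 100, 1),
            "formatted": f"{mean * 100:.1f}% ± {sd * 100:.0f}%",
        }
    return results, summary
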