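"""Repeated-run benchmark protocol and report formatting.

Each algorithm is run ``runs`` times with seeds ``base_seed + r`` and the
four table statistics — min / max / mean final within-class distance and
mean iteration count — are aggregated per algorithm.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .clustering import RunProfile, run_de_clustering
from .datasets import LabeledTable, write_history_csv
from .kmeans import KMeansConfig, run_kmeans

__all__ = [
    "ALGORITHMS",
    "RunRecord",
    "AlgorithmSummary",
    "BenchmarkReport",
    "run_benchmark",
    "format_report",
    "report_to_json",
    "report_from_json",
]

ALGORITHMS = ("kmeans", "kmeans_pp", "de_kmeans", "improved")

_DISPLAY = {
    "kmeans": "K-Means",
    "kmeans_pp": "K-Means++",
    "de_kmeans": "DE-K-Means",
    "improved": "Proposed",
}


@dataclass(frozen=True)
class RunRecord:
    algorithm: str
    seed: int
    wcd: float
    iterations: int
    history_path: str | None = None


@dataclass(frozen=True)
class AlgorithmSummary:
    algorithm: str
    min_wcd: float
    max_wcd: float
    mean_wcd: float
    mean_iterations: float


@dataclass(frozen=True)
class BenchmarkReport:
    k: int
    runs: int
    base_seed: int
    profile: str
    summaries: dict[str, AlgorithmSummary]
    records: list[RunRecord] = field(default_factory=list)


def _run_single(table: LabeledTable, k: int, algorithm: str, seed: int, profile: RunProfile):
    data = table.features
    if algorithm == "kmeans":
        return run_kmeans(data, KMeansConfig(k=k, seed=seed, init="random_points"))
    if algorithm == "kmeans_pp":
        return run_kmeans(data, KMeansConfig(k=k, seed=seed, init="kmeans_pp"))
    if algorithm == "de_kmeans":
        cfg = profile.make_config(k, data.d, seed=seed, strategy="rand_1")
        return run_de_clustering(data, k, cfg)
    if algorithm == "improved":
        cfg = profile.make_config(k, data.d, seed=seed, strategy="double_mutation")
        return run_de_clustering(data, k, cfg)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def run_benchmark(
    table: LabeledTable,
    k: int,
    algorithms: list[str],
    runs: int,
    base_seed: int,
    profile: RunProfile,
    history_dir: str | Path | None = None,
) -> BenchmarkReport:
    """Run the repeated-run protocol and aggregate the table statistics.

    Run r of every algorithm uses seed ``base_seed + r``, so reports are
    bit-reproducible from ``base_seed`` alone.  When ``history_dir`` is
    given, each run's convergence history is written there as a two-column
    CSV.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    for a in algorithms:
        if a not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {a!r}; choose from {ALGORITHMS}")
    if history_dir is not None:
        history_dir = Path(history_dir)
        history_dir.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, AlgorithmSummary] = {}
    records: list[RunRecord] = []
    for algorithm in algorithms:
        wcds = np.empty(runs)
        iters = np.empty(runs)
        for r in range(runs):
            seed = base_seed + r
            result = _run_single(table, k, algorithm, seed, profile)
            wcds[r] = result.wcd
            iters[r] = result.iterations
            hist_path = None
            if history_dir is not None:
                hist_path = str(history_dir / f"{algorithm}_run{r:03d}.csv")
                write_history_csv(result.history, hist_path)
            records.append(
                RunRecord(algorithm=algorithm, seed=seed, wcd=float(result.wcd),
                          iterations=int(result.iterations), history_path=hist_path)
            )
        summaries[algorithm] = AlgorithmSummary(
            algorithm=algorithm,
            min_wcd=float(wcds.min()),
            max_wcd=float(wcds.max()),
            mean_wcd=float(wcds.mean()),
            mean_iterations=float(iters.mean()),
        )
    return BenchmarkReport(
        k=k, runs=runs, base_seed=base_seed, profile=profile.name,
        summaries=summaries, records=records,
    )


_COLUMNS = [
    "Algorithm",
    "Minimum inner-class distance",
    "Maximum inner-class distance",
    "Mean inner-class distance",
    "Mean number of iterations",
]


def format_report(report: BenchmarkReport) -> str:
    """Fixed-column text table in the benchmark's column order."""
    rows = [_COLUMNS]
    for name, s in report.summaries.items():
        rows.append([
            _DISPLAY.get(name, name),
            f"{s.min_wcd:.4f}",
            f"{s.max_wcd:.4f}",
            f"{s.mean_wcd:.6f}",
            f"{s.mean_iterations:.1f}",
        ])
    widths = [max(len(r[c]) for r in rows) for c in range(len(_COLUMNS))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() for row in rows]
    lines.insert(1, "  ".join("-" * w for w in widths))
    return "\n".join(lines)


def report_to_json(report: BenchmarkReport, path: str | Path | None = None) -> str:
    """Serialize a report at full precision; inverse of :func:`report_from_json`."""
    payload = {
        "k": report.k,
        "runs": report.runs,
        "base_seed": report.base_seed,
        "profile": report.profile,
        "summaries": {name: asdict(s) for name, s in report.summaries.items()},
        "records": [asdict(r) for r in report.records],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def report_from_json(source: str | Path) -> BenchmarkReport:
    s = str(source)
    text = s if s.lstrip().startswith("{") else Path(source).read_text()
    payload = json.loads(text)
    return BenchmarkReport(
        k=payload["k"],
        runs=payload["runs"],
        base_seed=payload["base_seed"],
        profile=payload["profile"],
        summaries={n: AlgorithmSummary(**s) for n, s in payload["summaries"].items()},
        records=[RunRecord(**r) for r in payload["records"]],
    )
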