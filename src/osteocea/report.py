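"""Plain-text result writers: tidy CSVs, a JSON summary and a run manifest.

Outputs are deliberately diff-friendly (CSV/JSON only).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import EconomicSummary
from .engine import CohortTrace
from .parameters import FRACTURE_TYPES
from .psa import CEAC, PSAResult

__all__ = [
    "RunManifest",
    "write_manifest",
    "trace_frame",
    "incident_frame",
    "summary_frame",
    "write_summary",
    "write_psa",
]


@dataclass(frozen=True)
class RunManifest:
    """Provenance emitted alongside every output set."""

    config_digest: str
    seed: int | None
    timestamp: str
    version: str
    command: str


def make_manifest(config_text: str, seed: int | None) -> RunManifest:
    digest = hashlib.sha256(config_text.encode()).hexdigest()
    return RunManifest(
        config_digest=digest,
        seed=seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        version=__version__,
        command=" ".join(sys.argv),
    )


def write_manifest(out_dir: Path, config_text: str, seed: int | None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = make_manifest(config_text, seed)
    (out_dir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2) + "\n")


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tidy (cycle, age, state, occupancy) view of a cohort trace."""
    rows = []
    n = trace.n_cycles
    for c in range(n + 1):
        age = trace.space.params.settings.start_age \
            + c * trace.space.cycle_length
        for j, lab in enumerate(trace.space.labels):
            rows.append((c, age, lab, trace.occupancy[c, j]))
    return pd.DataFrame(rows, columns=["cycle", "age", "state", "occupancy"])


def incident_frame(trace: CohortTrace) -> pd.DataFrame:
    """Per-cycle Markov-visible incident fractures."""
    df = pd.DataFrame(trace.incident, columns=list(FRACTURE_TYPES))
    df.insert(0, "cycle", range(trace.n_cycles))
    return df


def summary_frame(summary: EconomicSummary) -> pd.DataFrame:
    """Base-case results in the published table's shape."""
    t, o = summary.treatment, summary.off_treatment
    rows = []
    for f in (*FRACTURE_TYPES, "total"):
        rows.append((f"10yr_{f}_fractures_per_1000",
                     t.fractures_10yr_per_1000[f],
                     o.fractures_10yr_per_1000[f],
                     t.fractures_10yr_per_1000[f] - o.fractures_10yr_per_1000[f]))
    rows += [
        ("fracture_cost", t.fracture_cost, o.fracture_cost,
         t.fracture_cost - o.fracture_cost),
        ("drug_cost", t.drug_cost, o.drug_cost, t.drug_cost - o.drug_cost),
        ("management_cost", t.management_cost, o.management_cost,
         t.management_cost - o.management_cost),
        ("total_cost", t.total_cost, o.total_cost, summary.incremental_cost),
        ("life_years", t.life_years, o.life_years,
         summary.incremental_life_years),
        ("qalys", t.qalys, o.qalys, summary.incremental_qalys),
    ]
    df = pd.DataFrame(rows, columns=["outcome", "treatment", "off_treatment",
                                     "difference"])
    return df


def write_summary(out_dir: Path, summary: EconomicSummary,
                  name: str = "base_case") -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_frame(summary).to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / f"{name}.json").write_text(
        json.dumps(summary.as_dict(), indent=2) + "\n")


def write_psa(out_dir: Path, psa: PSAResult, curve: CEAC) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "iteration": range(psa.n_iterations),
        "incremental_cost": psa.incremental_cost,
        "incremental_qalys": psa.incremental_qalys,
    }).to_csv(out_dir / "psa_iterations.csv", index=False)
    pd.DataFrame({
        "wtp_threshold": curve.thresholds,
        "probability_cost_effective": curve.probability,
    }).to_csv(out_dir / "ceac.csv", index=False)
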