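"""Analytic per-node time model for a fixed-latency likelihood pipeline.

A deeply pipelined accelerator emits one result per cycle after a fixed
startup latency, so the time to process one tree node of c characters is
latency*lambda + lambda*c, with lambda the clock period and a larger
latency when the root's log-likelihood pipeline is engaged. Averaging over
the fraction r of node evaluations that are root evaluations:

    t_node = (L_nonroot*lambda + lambda*c) * (1 - r) + (L_root*lambda + lambda*c) * r
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd


@dataclass(frozen=True)
class DeviceProfile:
    """Clock rate and pipeline latencies of one accelerator build."""

    name: str
    clock_hz: float
    nonroot_latency: int
    root_latency: int

    def __post_init__(self):
        if not self.root_latency > self.nonroot_latency > 0:
            raise ValueError("need root_latency > nonroot_latency > 0")


# Built-in device builds: a Virtex-2 Pro 100 at 165 MHz and a Virtex-6 SX 475
# at 310 MHz, with non-root/root pipeline latencies of 119/251 and 109/261
# cycles respectively.
V2P = DeviceProfile("v2p", 165e6, 119, 251)
V6 = DeviceProfile("v6", 310e6, 109, 261)
PROFILES = {"v2p": V2P, "v6": V6}


@dataclass(frozen=True)
class DatasetParams:
    """Per-dataset inputs: sequence length c and root-evaluation ratio r."""

    name: str
    n_chars: int
    root_ratio: float

    def __post_init__(self):
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")
        if not 0.0 <= self.root_ratio <= 1.0:
            raise ValueError(
                f"root_ratio must lie in [0, 1] (got {self.root_ratio})")


# Benchmark alignments (sequence length, measured fraction of node
# evaluations that were root evaluations).
DEFAULT_DATASETS = (
    DatasetParams("m993", 963, 0.038),
    DatasetParams("m1319", 1366, 0.062),
    DatasetParams("m346", 1620, 0.038),
    DatasetParams("m1038", 2021, 0.010),
    DatasetParams("m1485", 3009, 0.038),
    DatasetParams("m4056", 9563, 0.012),
    DatasetParams("m3631", 13568, 0.017),
)


def avg_node_time(profile: DeviceProfile, params: DatasetParams) -> float:
    """Average seconds per node evaluation under the pipeline model."""
    lam = 1.0 / profile.clock_hz
    c, r = params.n_chars, params.root_ratio
    return ((profile.nonroot_latency * lam + lam * c) * (1.0 - r)
            + (profile.root_latency * lam + lam * c) * r)


def round_us(seconds: float, decimals: int = 1) -> float:
    """Microseconds rounded half-up to the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(seconds * 1e6)).quantize(q, rounding=ROUND_HALF_UP))


def table3_report(profiles=None, datasets=None) -> pd.DataFrame:
    """Average per-node time (µs, one decimal) per dataset and device."""
    profiles = list(profiles) if profiles is not None else [V2P, V6]
    datasets = list(datasets) if datasets is not None else list(DEFAULT_DATASETS)
    rows = []
    for ds in datasets:
        row = {"dataset": ds.name, "chars": ds.n_chars,
               "root_ratio": ds.root_ratio}
        for prof in profiles:
            mhz = int(round(prof.clock_hz / 1e6))
            row[f"us_per_node_{mhz}MHz"] = round_us(avg_node_time(prof, ds))
        rows.append(row)
    return pd.DataFrame(rows)
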