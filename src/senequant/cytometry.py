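"""Flow-cytometry summaries: forward scatter (cell size) and FL1 (C12FDG).

Senescent cells are larger (higher forward scatter, FSC) and show higher
SA-beta-galactosidase activity, read out as FL1 fluorescence of the
cleaved fluorogenic substrate C12FDG. Both senescence metrics are simple
channel means over debris-gated events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("FSC", "FL1")

#: default mapping from common acquisition column names to canonical channels
DEFAULT_CHANNEL_MAP = {"FSC-A": "FSC", "FL1-A": "FL1", "FSC": "FSC", "FL1": "FL1"}


@dataclass
class FlowSample:
    """Event-level table with per-event FSC and FL1 values (a.u.)."""

    events: pd.DataFrame
    meta: dict = field(default_factory=dict)
    gate: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.events.columns]
        if missing:
            raise ValueError(
                f"flow table lacks channel(s) {missing}; available columns: "
                f"{list(self.events.columns)}"
            )
        if len(self.events) < 1:
            raise ValueError("flow sample has no events")
        vals = self.events[list(CHANNELS)].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite channel value in flow table")
        if (vals < 0).any():
            raise ValueError("negative channel value in flow table")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_csv(self, path: str | Path) -> None:
        self.events[list(CHANNELS)].to_csv(path, index=False)


def gate_debris(sample: FlowSample, fsc_min: float) -> FlowSample:
    """Exclude debris: keep events with FSC >= ``fsc_min``.

    Returns a new gated sample (the input is untouched); raises on an
    empty gate. Gating is idempotent for a fixed threshold.
    """
    if fsc_min < 0:
        raise ValueError("fsc_min must be >= 0")
    kept = sample.events[sample.events["FSC"] >= fsc_min]
    if len(kept) == 0:
        raise ValueError(f"empty gate: no events with FSC >= {fsc_min:g}")
    return FlowSample(
        kept.reset_index(drop=True),
        meta=dict(sample.meta),
        gate=f"FSC >= {fsc_min:g}",
    )


def default_debris_threshold(control: FlowSample, percentile: float = 1.0) -> float:
    """Debris threshold as a low FSC percentile of an unstained control."""
    return float(np.percentile(control.events["FSC"].to_numpy(), percentile))


def channel_mean(sample: FlowSample, channel: str) -> tuple[float, float, float]:
    """(arithmetic mean, sample sd, n) of a channel on the linear scale."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    values = sample.events[channel].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, float(values.size)


def read_flow_table(
    path: str | Path,
    dialect: str = "csv",
    channel_map: dict[str, str] | None = None,
    meta: dict | None = None,
) -> FlowSample:
    """Load an event table; CSV is the canonical dialect.

    Columns are renamed through ``channel_map`` (default maps FSC-A -> FSC
    and FL1-A -> FL1); an explicit error lists the available columns when
    a required channel is missing.
    """
    if dialect == "fcs":
        raise ValueError(
            "FCS support not available in this build; export the events to "
            "CSV with a 'FSC,FL1' header instead"
        )
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv'")
    table = pd.read_csv(path)
    mapping = DEFAULT_CHANNEL_MAP if channel_map is None else channel_map
    table = table.rename(columns={k: v for k, v in mapping.items() if k in table.columns})
    return FlowSample(table, meta=dict(meta or {}))


def summarize_flow(
    samples: dict[str, FlowSample], fsc_min: float = 0.0
) -> pd.DataFrame:
    """Gate each sample and tabulate FSC/FL1 means (one row per sample)."""
    rows = []
    for label, sample in samples.items():
        gated = gate_debris(sample, fsc_min) if fsc_min > 0 else sample
        row: dict = {"sample": label, "n_events": gated.n_events}
        for ch in CHANNELS:
            mean, sd, _ = channel_mean(gated, ch)
            row[f"{ch.lower()}_mean"] = mean
            row[f"{ch.lower()}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
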