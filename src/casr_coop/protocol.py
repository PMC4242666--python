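"""Stepwise extracellular-agonist protocols for single-cell Ca2+ imaging.

A protocol describes how the bath [Ca2+]o (and optionally L-Phe) is raised in
a stepwise manner during a ratiometric imaging experiment: each step holds a
fixed (ca_mM, phe_mM) pair for a dwell period while the fluorescence ratio is
sampled on a uniform time grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ProtocolStep", "StepProtocol"]


@dataclass(frozen=True)
class ProtocolStep:
    """One concentration step: bath conditions applied from ``start_s`` onward."""

    start_s: float
    ca_mM: float
    phe_mM: float = 0.0


@dataclass
class StepProtocol:
    """An ordered sequence of bath-concentration steps.

    Parameters
    ----------
    steps
        Steps with strictly increasing start times and non-decreasing
        [Ca2+]o (the experiment only ever raises the bath calcium).
    dwell_s
        Duration of the final step, s. Interior step durations are implied
        by consecutive start times.
    sampling_dt_s
        Sampling interval of the ratio recording, s.
    """

    steps: list[ProtocolStep]
    dwell_s: float = 180.0
    sampling_dt_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        self.steps = [
            s if isinstance(s, ProtocolStep) else ProtocolStep(*s) for s in self.steps
        ]
        starts = [s.start_s for s in self.steps]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("step start times must be strictly increasing")
        cas = [s.ca_mM for s in self.steps]
        if any(b < a for a, b in zip(cas, cas[1:])):
            raise ValueError("ca_mM must be non-decreasing across steps")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be positive")
        if self.sampling_dt_s <= 0:
            raise ValueError("sampling_dt_s must be positive")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def ramp(
        cls,
        ca_levels_mM: Sequence[float],
        phe_mM: float = 0.0,
        dwell_s: float = 180.0,
        sampling_dt_s: float = 1.0,
    ) -> "StepProtocol":
        """Uniform-dwell ramp over the given [Ca2+]o levels at fixed L-Phe."""
        steps = [
            ProtocolStep(i * dwell_s, float(ca), float(phe_mM))
            for i, ca in enumerate(ca_levels_mM)
        ]
        return cls(steps, dwell_s=dwell_s, sampling_dt_s=sampling_dt_s)

    # -- geometry -------------------------------------------------------------

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def total_duration_s(self) -> float:
        return self.steps[-1].start_s + self.dwell_s

    def step_window(self, index: int) -> tuple[float, float]:
        """[start, end) time window of step ``index`` in seconds."""
        start = self.steps[index].start_s
        if index + 1 < len(self.steps):
            return start, self.steps[index + 1].start_s
        return start, start + self.dwell_s

    def step_index_at_time(self, t: float) -> int:
        starts = np.array([s.start_s for s in self.steps])
        idx = int(np.searchsorted(starts, t, side="right")) - 1
        if idx < 0:
            raise ValueError(f"time {t} s precedes the first step")
        return idx

    def step_index_for_ca(self, ca_mM: float, atol: float = 1e-9) -> int:
        """Index of the (first) step at the given [Ca2+]o; raises if absent."""
        for i, s in enumerate(self.steps):
            if abs(s.ca_mM - ca_mM) <= atol:
                return i
        available = ", ".join(f"{s.ca_mM:g}" for s in self.steps)
        raise KeyError(
            f"no protocol step at {ca_mM:g} mM; available steps: {available} mM"
        )

    def time_grid(self) -> np.ndarray:
        """Uniform sampling grid covering the whole protocol."""
        n = int(round(self.total_duration_s / self.sampling_dt_s))
        return np.arange(n) * self.sampling_dt_s

    # -- serialization --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [s.start_s for s in self.steps],
                "ca_mM": [s.ca_mM for s in self.steps],
                "phe_mM": [s.phe_mM for s in self.steps],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dwell_s": self.dwell_s,
            "sampling_dt_s": self.sampling_dt_s,
            "steps": [
                {"start_s": s.start_s, "ca_mM": s.ca_mM, "phe_mM": s.phe_mM}
                for s in self.steps
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StepProtocol":
        payload = json.loads(Path(path).read_text())
        steps = [
            ProtocolStep(d["start_s"], d["ca_mM"], d.get("phe_mM", 0.0))
            for d in payload["steps"]
        ]
        return cls(
            steps,
            dwell_s=payload.get("dwell_s", 180.0),
            sampling_dt_s=payload.get("sampling_dt_s", 1.0),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.3f")

    @classmethod
    def from_csv(
        cls, path: str | Path, dwell_s: float = 180.0, sampling_dt_s: float = 1.0
    ) -> "StepProtocol":
        df = pd.read_csv(path)
        required = {"start_s", "ca_mM", "phe_mM"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"protocol CSV missing columns: {sorted(missing)}")
        steps = [
            ProtocolStep(r.start_s, r.ca_mM, r.phe_mM) for r in df.itertuples()
        ]
        return cls(steps, dwell_s=dwell_s, sampling_dt_s=sampling_dt_s)
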