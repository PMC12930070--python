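"""Core evidence containers shared across the pipeline.

Two interchange formats travel between modules: per-subject survival
records (``PseudoIPD``) and digitized Kaplan-Meier evidence
(``DigitizedCurve`` = curve coordinates plus a number-at-risk table).
Both round-trip through plain delimited text so that every stage of the
analysis can be driven from files on disk.

All times are in months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PseudoIPD", "DigitizedCurve", "StepCurve"]


@dataclass
class PseudoIPD:
    """Per-subject (time, event, arm) survival records.

    ``time`` is follow-up in months (>= 0), ``event`` is 1 for an observed
    event and 0 for right-censoring, ``arm`` labels the treatment group.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.arm = np.asarray(self.arm, dtype=object)
        if self.time.size == 0:
            raise ValueError("PseudoIPD must contain at least one record")
        if not (len(self.time) == len(self.event) == len(self.arm)):
            raise ValueError("time, event and arm must have equal length")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def arms(self) -> list[str]:
        seen: list[str] = []
        for a in self.arm:
            if a not in seen:
                seen.append(a)
        return seen

    def for_arm(self, arm: str) -> "PseudoIPD":
        mask = self.arm == arm
        if not mask.any():
            raise KeyError(f"no records for arm {arm!r}")
        return PseudoIPD(self.time[mask], self.event[mask], self.arm[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), df["arm"].to_numpy())

    @classmethod
    def concat(cls, parts: list["PseudoIPD"]) -> "PseudoIPD":
        return cls(
            np.concatenate([p.time for p in parts]),
            np.concatenate([p.event for p in parts]),
            np.concatenate([p.arm for p in parts]),
        )


@dataclass
class DigitizedCurve:
    """Kaplan-Meier curve coordinates with a number-at-risk table.

    ``times``/``survival`` are the digitized curve points (time 0 with
    survival 1 first); ``risk_times``/``n_at_risk`` give the published
    number-at-risk schedule. This is the interchange format the IPD
    reconstruction step consumes.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")
        if len(self.risk_times) != len(self.n_at_risk):
            raise ValueError("risk table columns must have equal length")
        if len(self.times) and self.times[0] != 0:
            raise ValueError("curve must start at time 0")

    def validate(self) -> None:
        """Strict invariant check (no repair)."""
        if self.survival[0] != 1.0:
            raise ValueError("survival must start at 1 at time 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("curve times must be nondecreasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival out of [0, 1]")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("number at risk must be nonincreasing")

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write the curve and risk table as a delimited file pair."""
        prefix = Path(prefix)
        curve_path = prefix.with_name(prefix.name + "_curve.csv")
        risk_path = prefix.with_name(prefix.name + "_risk.csv")
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            curve_path, index=False
        )
        pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk}).to_csv(
            risk_path, index=False
        )
        return curve_path, risk_path

    @classmethod
    def read(cls, prefix: str | Path, label: str = "") -> "DigitizedCurve":
        prefix = Path(prefix)
        curve = pd.read_csv(prefix.with_name(prefix.name + "_curve.csv"))
        risk = pd.read_csv(prefix.with_name(prefix.name + "_risk.csv"))
        return cls(
            curve["time"].to_numpy(),
            curve["survival"].to_numpy(),
            risk["time"].to_numpy(),
            risk["n_at_risk"].to_numpy(),
            label=label or prefix.name,
        )


@dataclass
class StepCurve:
    """Right-continuous nonincreasing step function starting at 1."""

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.breakpoints) != len(self.values):
            raise ValueError("breakpoints/values length mismatch")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)
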