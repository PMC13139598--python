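"""Event log: timestamped binding, unbinding, reaction and conformational
transition events — the substrate of all kinetic analysis."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["EventLog", "EVENT_TYPES"]

EVENT_TYPES = ("bind", "unbind", "react_fwd", "react_rev", "transition")

COLUMNS = ["step", "time_ms", "site", "event", "species", "S", "fS", "E_bind"]


@dataclass
class EventLog:
    """Tab-separated-friendly record of discrete events during a run."""

    records: list[tuple] = field(default_factory=list)

    def append(self, step: int, time_ms: float, site: str, event: str,
               species: str = "", S: float = np.nan, fS: float = np.nan,
               e_bind: float = np.nan) -> None:
        if event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event!r}")
        self.records.append((int(step), float(time_ms), site, event, species,
                             float(S), float(fS), float(e_bind)))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=COLUMNS)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "EventLog":
        df = pd.read_csv(path, sep="\t")
        log = cls()
        for row in df.itertuples(index=False):
            log.records.append(tuple(row))
        return log

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventLog":
        log = cls()
        for row in df[COLUMNS].itertuples(index=False):
            log.records.append(tuple(row))
        return log

    def extend(self, other: "EventLog") -> None:
        self.records.extend(other.records)
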