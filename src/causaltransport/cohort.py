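"""Cohort container: an individuals x variables table with provenance metadata.

A :class:`CohortTable` wraps a :class:`pandas.DataFrame` and records where the
cohort came from (setting label, seed) and on which scale its continuous
columns live (``"z"`` for z-scores, ``"natural"`` for original units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class CohortError(ValueError):
    """Invalid cohort table (missing values, bad binary coding, ...)."""


@dataclass
class CohortTable:
    data: pd.DataFrame
    setting: str = ""
    seed: int | None = None
    scale: str = "natural"  # "z" or "natural"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("z", "natural"):
            raise CohortError(f"unknown scale {self.scale!r}")
        if self.data.isna().any().any():
            bad = [c for c in self.data.columns if self.data[c].isna().any()]
            raise CohortError(f"cohort contains missing values in columns {bad}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def check_binary(self, columns) -> None:
        """Assert the named columns are coded {0,1}."""
        for c in columns:
            vals = np.unique(np.asarray(self.data[c]))
            if not np.isin(vals, (0, 1)).all():
                raise CohortError(f"column {c!r} is not 0/1 coded")

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.setting, self.seed,
                           self.scale, dict(self.extra))

    # -- persistence: CSV plus a JSON sidecar with the metadata ------------
    def write_csv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta = {"setting": self.setting, "seed": self.seed,
                "scale": self.scale, "n": self.n, **self.extra}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2))

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        extra = {k: v for k, v in meta.items()
                 if k not in ("setting", "seed", "scale", "n")}
        return cls(data, meta.get("setting", ""), meta.get("seed"),
                   meta.get("scale", "natural"), extra)


def as_frame(data) -> pd.DataFrame:
    """Accept a CohortTable or a bare DataFrame."""
    return data.data if isinstance(data, CohortTable) else data
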