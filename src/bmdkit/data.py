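"""Dose-response data container and CSV ingestion.

A :class:`DoseResponseData` holds one row per experimental unit (continuous
and count endpoints) or one row per dose group (grouped binomial data:
``events`` out of ``trials``).  Optional columns carry an observation weight
or exposure (e.g. lifespan-days for reproduction counts) and a cluster label
identifying independent sub-experiments in hierarchical designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["DoseResponseData", "read_table"]

_KINDS = ("binomial", "count", "continuous")


@dataclass
class DoseResponseData:
    dose: np.ndarray
    response_kind: str
    response: Optional[np.ndarray] = None
    events: Optional[np.ndarray] = None
    trials: Optional[np.ndarray] = None
    weight: Optional[np.ndarray] = None
    cluster: Optional[np.ndarray] = None

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.response_kind not in _KINDS:
            raise DataError(f"response_kind must be one of {_KINDS}")
        if np.any(self.dose < 0) or not np.all(np.isfinite(self.dose)):
            bad = int(np.flatnonzero((self.dose < 0) | ~np.isfinite(self.dose))[0])
            raise DataError(f"negative or non-finite dose at row {bad + 1}")
        n = len(self.dose)
        if self.response_kind == "binomial":
            if self.events is None or self.trials is None:
                raise DataError("binomial data requires events and trials")
            self.events = np.asarray(self.events, dtype=float)
            self.trials = np.asarray(self.trials, dtype=float)
            if len(self.events) != n or len(self.trials) != n:
                raise DataError("events/trials length mismatch with dose")
            if np.any(self.trials <= 0):
                bad = int(np.flatnonzero(self.trials <= 0)[0])
                raise DataError(f"non-positive trials at row {bad + 1}")
            bad = (self.events < 0) | (self.events > self.trials)
            if np.any(bad):
                raise DataError(
                    f"events outside [0, trials] at row {int(np.flatnonzero(bad)[0]) + 1}"
                )
        else:
            if self.response is None:
                raise DataError(f"{self.response_kind} data requires a response column")
            self.response = np.asarray(self.response, dtype=float)
            if len(self.response) != n:
                raise DataError("response length mismatch with dose")
            if not np.all(np.isfinite(self.response)):
                bad = int(np.flatnonzero(~np.isfinite(self.response))[0])
                raise DataError(f"non-finite response at row {bad + 1}")
            if self.response_kind == "count":
                if np.any(self.response < 0) or np.any(self.response % 1 != 0):
                    bad = int(np.flatnonzero((self.response < 0) | (self.response % 1 != 0))[0])
                    raise DataError(f"count response must be a non-negative integer (row {bad + 1})")
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)
            if np.any(self.weight <= 0):
                raise DataError("weights must be positive")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster)

    # ------------------------------------------------------------------
    def __len__(self):
        return len(self.dose)

    @property
    def n_dose_levels(self) -> int:
        return len(np.unique(self.dose))

    @property
    def yvalues(self) -> np.ndarray:
        """Per-row response on the natural scale (proportions for binomial)."""
        if self.response_kind == "binomial":
            return self.events / self.trials
        return self.response

    def group_means(self):
        """(sorted dose levels, weighted mean response, group sizes)."""
        levels = np.unique(self.dose)
        if self.response_kind == "binomial":
            means = np.array([
                self.events[self.dose == lv].sum() / self.trials[self.dose == lv].sum()
                for lv in levels
            ])
            sizes = np.array([self.trials[self.dose == lv].sum() for lv in levels])
        else:
            means = np.array([self.response[self.dose == lv].mean() for lv in levels])
            sizes = np.array([(self.dose == lv).sum() for lv in levels], dtype=float)
        return levels, means, sizes

    def subset(self, mask) -> "DoseResponseData":
        pick = lambda a: None if a is None else a[mask]
        return DoseResponseData(
            dose=self.dose[mask], response_kind=self.response_kind,
            response=pick(self.response), events=pick(self.events),
            trials=pick(self.trials), weight=pick(self.weight),
            cluster=pick(self.cluster),
        )

    def clusters(self):
        """Yield (label, per-cluster data) pairs."""
        if self.cluster is None:
            raise DataError("data has no cluster column")
        for label in pd.unique(self.cluster):
            yield label, self.subset(self.cluster == label)

    def to_frame(self) -> pd.DataFrame:
        cols = {"dose": self.dose}
        if self.response_kind == "binomial":
            cols["events"] = self.events
            cols["trials"] = self.trials
        else:
            cols["response"] = self.response
        if self.weight is not None:
            cols["weight"] = self.weight
        if self.cluster is not None:
            cols["cluster"] = self.cluster
        return pd.DataFrame(cols)


def read_table(path, response_kind: str = None,
               mapping: Optional[Dict[str, str]] = None) -> DoseResponseData:
    """Read a CSV file into a :class:`DoseResponseData`.

    The file must have a header row.  Default column names are ``dose``,
    ``response`` (continuous/count) or ``events``+``trials`` (binomial),
    and optional ``weight`` and ``cluster``; ``mapping`` renames them,
    e.g. ``{"dose": "conc"}`` reads doses from a ``conc`` column.

    ``response_kind`` is inferred when omitted: ``binomial`` if events and
    trials columns are present, ``count`` if every response is a
    non-negative integer, else ``continuous``.
    """
    df = pd.read_csv(path)
    mapping = mapping or {}
    col = lambda name: mapping.get(name, name)

    def get(name, required=False):
        c = col(name)
        if c in df.columns:
            return df[c].to_numpy()
        if required:
            raise DataError(f"required column {c!r} not found in {path}")
        return None

    dose = get("dose", required=True)
    events, trials = get("events"), get("trials")
    response = get("response")
    if response_kind is None:
        if events is not None and trials is not None:
            response_kind = "binomial"
        elif response is not None:
            r = pd.to_numeric(pd.Series(response), errors="coerce")
            response_kind = (
                "count" if bool(((r >= 0) & (r % 1 == 0)).all()) else "continuous"
            )
        else:
            raise DataError(
                "need either a response column or events+trials columns"
            )
    for name, arr in (("dose", dose), ("response", response),
                      ("events", events), ("trials", trials)):
        if arr is not None:
            coerced = pd.to_numeric(pd.Series(arr), errors="coerce")
            if coerced.isna().any():
                row = int(coerced.index[coerced.isna()][0]) + 1
                raise DataError(f"non-numeric {name} at row {row}")
    return DoseResponseData(
        dose=dose, response_kind=response_kind, response=response,
        events=events, trials=trials, weight=get("weight"),
        cluster=get("cluster"),
    )
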