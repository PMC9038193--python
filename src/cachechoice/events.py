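"""Event logs: ordered site interactions for one bird.

An *interaction* is a cache (seed count change +), a retrieval (-), or a
check (0) at one of the arena's sites. Events carry a session id, a trial
id, a trial phase, a timestamp in seconds, a site index, and the seed-count
change. Phases: 0 for the free Caching task (each session is one trial),
1 for the feeder-open phase of the Retrieval task, 2 for the feeder-closed
phase. The delay phase contains no interactions.

The canonical on-disk format is one flat delimited table with columns
``bird, session, trial, phase, time, site, delta`` (plus an optional,
redundant ``event`` class column that is validated against ``delta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaGeometry

CANONICAL_COLUMNS = ["bird", "session", "trial", "phase", "time", "site", "delta"]

PHASE_CACHING = 0
PHASE_FEEDER_OPEN = 1
PHASE_FEEDER_CLOSED = 2


class EventValidationError(ValueError):
    """Raised when an event table violates the schema or its invariants."""


def classify_event(delta: int) -> str:
    """Event class implied by the seed-count change."""
    if delta > 0:
        return "cache"
    if delta < 0:
        return "retrieval"
    return "check"


@dataclass
class BirdDataset:
    """Ordered event log for a single bird.

    ``events`` is a DataFrame with the canonical columns (minus ``bird``),
    sorted by time. Trials are renumbered to a contiguous global index
    0..R-1 in temporal order; the original trial labels are kept in
    ``trial_label``.
    """

    bird: str
    events: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        ev = self.events.reset_index(drop=True).copy()
        required = ["session", "trial", "phase", "time", "site", "delta"]
        missing = [c for c in required if c not in ev.columns]
        if missing:
            raise EventValidationError(f"missing columns: {missing}")
        for col in ("session", "trial", "phase", "site", "delta"):
            ev[col] = ev[col].astype(int)
        ev["time"] = ev["time"].astype(float)
        if len(ev):
            # strict ordering within a bird
            dt = np.diff(ev["time"].to_numpy())
            if np.any(dt < 0):
                row = int(np.argmin(dt >= 0)) + 1
                raise EventValidationError(
                    f"bird {self.bird}: time goes backwards at row {row}"
                )
            # renumber trials contiguously in order of first appearance
            labels = list(dict.fromkeys(zip(ev["session"], ev["trial"])))
            index = {lab: r for r, lab in enumerate(labels)}
            ev["trial_label"] = ev["trial"]
            ev["trial"] = [index[k] for k in zip(ev["session"], ev["trial_label"])]
            if np.any(np.diff(ev["trial"].to_numpy()) < 0):
                raise EventValidationError(
                    f"bird {self.bird}: trials interleave in time"
                )
        else:
            ev["trial_label"] = ev.get("trial_label", ev["trial"])
        if "event" in ev.columns:
            implied = ev["delta"].map(classify_event)
            bad = ev.index[ev["event"].astype(str) != implied]
            if len(bad):
                raise EventValidationError(
                    f"bird {self.bird}: event class disagrees with delta at "
                    f"rows {list(bad[:5])}"
                )
        else:
            ev["event"] = ev["delta"].map(classify_event)
        self.events = ev

    # -- counts ----------------------------------------------------------
    @property
    def n_events(self) -> int:
        """Total number of interactions I."""
        return len(self.events)

    @property
    def n_trials(self) -> int:
        """Number of trials R."""
        return self.events["trial"].nunique()

    @property
    def n_sessions(self) -> int:
        return self.events["session"].nunique()

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.events["session"].to_numpy())

    def subset_sessions(self, sessions) -> "BirdDataset":
        """New dataset restricted to the given session ids (order preserved)."""
        keep = self.events["session"].isin(list(sessions))
        return BirdDataset(self.bird, self.events.loc[keep])

    def resample_sessions(self, rng: np.random.Generator) -> "BirdDataset":
        """Bootstrap resample of sessions (with replacement).

        Resampled copies are laid end to end in draw order with times
        shifted to remain strictly increasing; sessions and trials are
        relabeled so repeated draws stay distinct.
        """
        sessions = self.sessions
        draws = rng.choice(sessions, size=len(sessions), replace=True)
        parts = []
        t_offset = 0.0
        for new_id, s in enumerate(draws):
            block = self.events[self.events["session"] == s].copy()
            t0 = block["time"].iloc[0]
            span = block["time"].iloc[-1] - t0
            block["time"] = block["time"] - t0 + t_offset
            block["session"] = new_id
            block["trial"] = block["trial_label"]
            t_offset += span + 1.0
            parts.append(block.drop(columns=["trial_label", "event"]))
        return BirdDataset(self.bird, pd.concat(parts, ignore_index=True))

    def validate(self, arena: ArenaGeometry) -> None:
        """Check site indices and delta conventions against an arena."""
        ev = self.events
        sites = ev["site"].to_numpy()
        if len(sites) and (sites.min() < 0 or sites.max() >= arena.n_sites):
            bad = sites[(sites < 0) | (sites >= arena.n_sites)][0]
            raise EventValidationError(
                f"bird {self.bird}: unknown site index {bad} "
                f"(arena has {arena.n_sites} sites)"
            )
        is_feeder = ~arena.is_cache_site[sites] if len(sites) else np.array([])
        if len(sites) and np.any(is_feeder & (ev["delta"].to_numpy() >= 0)):
            raise EventValidationError(
                f"bird {self.bird}: feeder events must be retrievals (delta < 0)"
            )
        phases = ev["phase"].to_numpy()
        if len(phases) and not np.all(np.isin(phases, [0, 1, 2])):
            raise EventValidationError(f"bird {self.bird}: phase must be 0, 1, or 2")
        # phase 0 never mixes with 1/2 within a trial
        for r, block in ev.groupby("trial"):
            ph = set(block["phase"])
            if 0 in ph and len(ph) > 1:
                raise EventValidationError(
                    f"bird {self.bird}: trial {r} mixes Caching-task phase 0 "
                    f"with Retrieval-task phases"
                )


def to_frame(datasets: list[BirdDataset]) -> pd.DataFrame:
    """Flatten one or more bird datasets into a canonical table."""
    parts = []
    for ds in datasets:
        block = ds.events.copy()
        block.insert(0, "bird", ds.bird)
        parts.append(block[CANONICAL_COLUMNS + ["event"]])
    return pd.concat(parts, ignore_index=True)


def write_events(datasets: list[BirdDataset] | BirdDataset, path) -> None:
    """Write dataset(s) to a canonical CSV event table."""
    if isinstance(datasets, BirdDataset):
        datasets = [datasets]
    to_frame(datasets).to_csv(path, index=False)


def from_frame(frame: pd.DataFrame) -> list[BirdDataset]:
    """Split a canonical table into per-bird datasets (file order kept)."""
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise EventValidationError(f"missing columns: {missing}")
    out = []
    for bird in dict.fromkeys(frame["bird"]):
        block = frame[frame["bird"] == bird].drop(columns=["bird"])
        out.append(BirdDataset(str(bird), block))
    return out


def read_events(path, format: str = "csv") -> list[BirdDataset]:
    """Read a canonical event table into per-bird datasets.

    Rejects malformed rows (naming the row), out-of-order timestamps, and
    unknown columns missing from the schema.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise EventValidationError(f"malformed event table {path}: {exc}") from exc
    numeric = ["session", "trial", "phase", "time", "site", "delta"]
    for col in numeric:
        if col not in frame.columns:
            raise EventValidationError(f"missing column {col!r} in {path}")
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise EventValidationError(
                f"malformed value in column {col!r} at row {int(bad[0]) + 2} of {path}"
            )
        if coerced.isna().any():
            row = int(frame.index[coerced.isna()][0]) + 2
            raise EventValidationError(f"missing {col!r} at row {row} of {path}")
        frame[col] = coerced
    return from_frame(frame)


def import_annotations(
    path,
    column_map: dict[str, str],
    bird: str | None = None,
    sep: str = ",",
    time_unit: float = 1.0,
) -> list[BirdDataset]:
    """Import adapter for externally deposited annotation tables.

    ``column_map`` maps canonical column names to the file's column names,
    e.g. ``{"time": "Timestamp", "site": "SiteID", ...}``. A constant
    ``bird`` id may be supplied for single-bird files lacking the column.
    ``time_unit`` converts the file's time values to seconds.
    """
    raw = pd.read_csv(path, sep=sep)
    frame = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            frame[canon] = raw[src]
        elif canon == "bird" and bird is not None:
            frame[canon] = bird
        else:
            raise EventValidationError(
                f"adapter: no source column for {canon!r} in {path}"
            )
    frame["time"] = frame["time"].astype(float) * time_unit
    return from_frame(frame)
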