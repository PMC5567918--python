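"""Pairwise at-sea association detection and re-association consistency.

A foraging association is two instrumented birds within ``radius`` metres of
each other for at least ``min_duration`` seconds during the foraging phase of
concurrent trips.  Brief interruptions (out-of-radius excursions or missing
samples shorter than ``max_gap``) do not split an association run, but do not
count toward its in-criterion duration either, which keeps the duration test
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import haversine_m
from .track_preprocess import PHASE_FORAGING

EVENT_COLUMNS = ["bird_a", "bird_b", "t_start", "t_end",
                 "duration_in_criterion", "mean_distance"]


@dataclass
class AssociationCriteria:
    """Spatial/temporal association criterion.

    radius : proximity threshold (m); the study value is the average
        horizontal distance travelled during foraging.
    min_duration : minimum in-criterion time (s); the study value is the
        mean dive-bout duration during foraging.
    max_gap : interruptions shorter than this bridge a run (s).
    """

    radius: float = 500.0
    min_duration: float = 748.0
    max_gap: float = 60.0

    def __post_init__(self):
        if self.radius <= 0 or self.min_duration <= 0 or self.max_gap < 0:
            raise ValueError("invalid association criteria")


def pair_distance_series(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.Series:
    """Distances at the common foraging-phase timestamps of two tracks.

    Both tracks must be on the shared grid.  Returns an empty series when
    the foraging phases do not overlap in time.
    """
    a = track_a[track_a["phase"] == PHASE_FORAGING]
    b = track_b[track_b["phase"] == PHASE_FORAGING]
    merged = pd.merge(
        a[["t", "lat", "lon"]], b[["t", "lat", "lon"]],
        on="t", suffixes=("_a", "_b"),
    )
    if len(merged) == 0:
        return pd.Series([], dtype=float, name="distance")
    d = haversine_m(merged["lat_a"], merged["lon_a"],
                    merged["lat_b"], merged["lon_b"])
    return pd.Series(d, index=pd.Index(merged["t"].to_numpy(), name="t"),
                     name="distance")


def _events_from_series(t, d, criteria, dt):
    """Bridged-run event extraction from an in-radius boolean series."""
    inside = d <= criteria.radius
    ti = t[inside]
    di = d[inside]
    if len(ti) == 0:
        return []
    # split when the time between consecutive in-radius samples, minus one
    # grid step, reaches max_gap
    splits = np.flatnonzero((np.diff(ti) - dt) >= criteria.max_gap)
    starts = np.r_[0, splits + 1]
    ends = np.r_[splits, len(ti) - 1]
    events = []
    for s, e in zip(starts, ends):
        duration = (e - s + 1) * dt
        if duration >= criteria.min_duration:
            events.append((int(ti[s]), int(ti[e]), float(duration),
                           float(di[s:e + 1].mean())))
    return events


def detect_associations(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    criteria: AssociationCriteria | None = None,
    dt: int = 4,
) -> pd.DataFrame:
    """Detect association events between two shared-grid tracks.

    Symmetric in argument order; birds in the output are stored
    lexicographically.  ``duration_in_criterion`` counts in-radius samples
    only (each contributing one grid step ``dt``).
    """
    criteria = criteria or AssociationCriteria()
    series = pair_distance_series(track_a, track_b)
    ids = sorted({str(track_a["bird_id"].iloc[0]), str(track_b["bird_id"].iloc[0])}) \
        if len(track_a) and len(track_b) else ["", ""]
    rows = []
    if len(series):
        t = series.index.to_numpy()
        d = series.to_numpy()
        for t0, t1, dur, mean_d in _events_from_series(t, d, criteria, dt):
            rows.append((ids[0], ids[-1], t0, t1, dur, mean_d))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_all_associations(
    tracks: pd.DataFrame,
    criteria: AssociationCriteria | None = None,
    dt: int = 4,
) -> pd.DataFrame:
    """Run pairwise detection over every unordered pair of birds."""
    criteria = criteria or AssociationCriteria()
    birds = sorted(tracks["bird_id"].unique())
    per_bird = {b: tracks[tracks["bird_id"] == b] for b in birds}
    out = []
    for i, a in enumerate(birds):
        for b in birds[i + 1:]:
            ev = detect_associations(per_bird[a], per_bird[b], criteria, dt)
            if len(ev):
                out.append(ev)
    return (pd.concat(out).reset_index(drop=True)
            if out else pd.DataFrame(columns=EVENT_COLUMNS))


def _events_in_trip(events, bird, t_start, t_end):
    mine = events[(events["bird_a"] == bird) | (events["bird_b"] == bird)]
    overlap = (mine["t_start"] <= t_end) & (mine["t_end"] >= t_start)
    return mine[overlap]


def associations_per_trip(events: pd.DataFrame, trips: pd.DataFrame) -> pd.DataFrame:
    """Per bird-trip: number of distinct partners with >= 1 event in the trip.

    ``trips`` may carry ``colony_id``/``stage`` columns, which are passed
    through for group summaries.  Raises when an event cannot be attributed
    to any trip of either of its birds.
    """
    counts = []
    for _, trip in trips.iterrows():
        ev = _events_in_trip(events, trip["bird_id"], trip["t_start"], trip["t_end"])
        partners = set(ev["bird_a"]) | set(ev["bird_b"])
        partners.discard(trip["bird_id"])
        row = {"bird_id": trip["bird_id"], "trip_index": trip["trip_index"],
               "n_partners": len(partners)}
        for extra in ("colony_id", "stage", "clutch"):
            if extra in trip.index:
                row[extra] = trip[extra]
        counts.append(row)
    out = pd.DataFrame(counts)
    # consistency: every event must fall within a trip of each of its birds
    for _, ev in events.iterrows():
        for bird in (ev["bird_a"], ev["bird_b"]):
            mine = trips[trips["bird_id"] == bird]
            hit = ((mine["t_start"] <= ev["t_end"]) &
                   (mine["t_end"] >= ev["t_start"])).any()
            if not hit:
                raise ValueError(
                    f"event [{ev['t_start']}, {ev['t_end']}] not contained in "
                    f"any trip of bird {bird}"
                )
    return out


def summarize_per_trip(per_trip: pd.DataFrame) -> pd.DataFrame:
    """Colony x stage mean +/- SE of partners per trip."""
    keys = [k for k in ("colony_id", "stage") if k in per_trip.columns]
    if not keys:
        keys = ["bird_id"]
    g = per_trip.groupby(keys)["n_partners"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_associations",
                               "sem": "se", "count": "n_trips"})


def percent_individuals_associating(
    events: pd.DataFrame, tracked_birds: set[str],
) -> float | None:
    """100 x (birds with >= 1 event) / (birds tracked); None when no birds.

    ``tracked_birds`` should already be restricted to the colony/stage of
    interest, as should ``events`` (e.g. by trip time containment).
    """
    if not tracked_birds:
        return None
    with_event = (set(events["bird_a"]) | set(events["bird_b"])) & tracked_birds
    return 100.0 * len(with_event) / len(tracked_birds)


def _partners_by_scope(events, trips):
    """For each bird: {scope key -> {partner -> set of own trip indices}}.

    Scope key is (clutch, stage); requires trips labelled with both.
    """
    out: dict = {}
    for _, trip in trips.iterrows():
        bird = trip["bird_id"]
        key = (trip["clutch"], trip["stage"])
        ev = _events_in_trip(events, bird, trip["t_start"], trip["t_end"])
        partners = (set(ev["bird_a"]) | set(ev["bird_b"])) - {bird}
        scopes = out.setdefault(bird, {})
        per = scopes.setdefault(key, {})
        for p in partners:
            per.setdefault(p, set()).add(trip["trip_index"])
    return out


def reassociation_rates(
    events: pd.DataFrame, trips: pd.DataFrame,
) -> pd.DataFrame:
    """Percentage of individuals re-associating at three temporal scales.

    short  : same partner on more than one trip within a (clutch, stage);
             denominator is birds with >= 2 trips in some (clutch, stage).
    medium : same partner in both stages of one clutch; denominator is birds
             tracked in both stages of a clutch.
    long   : same partner in both clutches; denominator is birds tracked in
             both clutches.

    Trips must carry ``stage`` and ``clutch`` columns.  Scales with empty
    denominators report ``n = 0`` and a missing percentage.
    """
    scoped = _partners_by_scope(events, trips)
    trip_counts = trips.groupby(["bird_id", "clutch", "stage"]).size()

    birds = sorted(trips["bird_id"].unique())
    rows = []

    # short term: within a stage
    denom = [b for b in birds
             if (trip_counts.loc[b] >= 2).any()]
    num = 0
    for b in denom:
        for key, per in scoped.get(b, {}).items():
            if any(len(trip_set) >= 2 for trip_set in per.values()):
                num += 1
                break
    rows.append(("short", len(denom),
                 100.0 * num / len(denom) if denom else np.nan))

    # medium term: between stages within a clutch
    denom_m, num_m = 0, 0
    for b in birds:
        by_clutch: dict = {}
        for (bb, clutch, stage) in trip_counts.index:
            if bb == b:
                by_clutch.setdefault(clutch, set()).add(stage)
        eligible = [c for c, stages in by_clutch.items() if len(stages) >= 2]
        if not eligible:
            continue
        denom_m += 1
        for c in eligible:
            stages = sorted(by_clutch[c])
            partner_sets = [
                set(scoped.get(b, {}).get((c, s), {})) for s in stages
            ]
            if any(partner_sets[i] & partner_sets[j]
                   for i in range(len(stages)) for j in range(i + 1, len(stages))):
                num_m += 1
                break
    rows.append(("medium", denom_m, 100.0 * num_m / denom_m if denom_m else np.nan))

    # long term: between clutches
    denom_l, num_l = 0, 0
    for b in birds:
        clutches = {c for (bb, c, s) in trip_counts.index if bb == b}
        if len(clutches) < 2:
            continue
        denom_l += 1
        per_clutch = []
        for c in sorted(clutches):
            ps: set = set()
            for (cc, s), per in scoped.get(b, {}).items():
                if cc == c:
                    ps |= set(per)
            per_clutch.append(ps)
        if any(per_clutch[i] & per_clutch[j]
               for i in range(len(per_clutch))
               for j in range(i + 1, len(per_clutch))):
            num_l += 1
    rows.append(("long", denom_l, 100.0 * num_l / denom_l if denom_l else np.nan))

    return pd.DataFrame(rows, columns=["scale", "n_individuals",
                                       "percent_reassociating"])
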