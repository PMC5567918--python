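"""Seeded synthetic central-place foraging studies with ground truth.

The generator emits a complete study — deployments, GPS fixes, TDR records
and per-pair-day association truth — with the statistical structure the
analysis assumes:

* birds breed in nests (mate pairs) scattered around the colony; body
  condition (mass / flipper) is Normal around the colony mean;
* on each at-sea day birds depart pre-dawn, with Normal departure times, so
  departure-time gaps between pairs are half-Normal;
* whether a concurrent pair associates on a day is Bernoulli with
  logit p = beta0 + beta_logT * ln(gap_minutes + 1) + u_dyad + v_a + v_b,
  random effects drawn once per dyad and bird;
* movement realises the truth geometrically.  Each day is organised as
  commute -> scheduled rendezvous sessions -> synchronized return.  Foraging
  zones sit on a lattice with >= ``zone_spacing_m`` separation; associated
  pairs co-wander at a shared zone for at least one session (planted
  window), while the lattice spacing plus simultaneous constant-speed
  transits bound any within-radius dwell of a non-associated pair to well
  under the minimum association duration.  Association is therefore planted,
  not emergent, which is what makes the ground truth unambiguous.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_formats import condition_index

DAY_SECONDS = 86400
GRID_DT = 4


class SimulationError(RuntimeError):
    """The requested geometry/schedule cannot be realised."""


@dataclass
class ColonyConfig:
    name: str = "LB"
    lat: float = -38.55
    lon: float = 142.92
    n_birds: int = 20
    nest_spread_m: float = 30.0


@dataclass
class DepartureConfig:
    mean_time_s: int = 16200       # 04:30, pre-dawn
    sd_minutes: float = 35.0


@dataclass
class AssociationProcess:
    beta0: float = 2.78
    beta_logT: float = -0.38
    sigma_dyad: float = 0.5
    sigma_bird: float = 0.5


@dataclass
class MovementConfig:
    commute_speed_mps: float = 2.5
    max_range_km: float = 40.0
    zone_spacing_m: float = 3000.0
    zone_rmin_m: float = 4000.0
    zone_rmax_m: float = 16000.0
    session_s: int = 900           # planted co-foraging window length
    wander_sd_m: float = 35.0      # OU positional wander
    wander_tau_s: float = 120.0
    max_clique: int = 8


@dataclass
class DiveConfig:
    dive_depth_range_m: tuple = (5.0, 30.0)
    dive_s: int = 32
    surface_s: int = 12
    drift_m_per_day: float = 1.0   # sensor surface drift, removed by ZOC


@dataclass
class SensorConfig:
    gps_dt: int = 120
    tdr_dt: int = 4
    gps_noise_m: float = 10.0
    dropout_prob: float = 0.05


@dataclass
class SimConfig:
    seed: int = 0
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    # per-day (clutch, stage) labels; guard days put one mate per nest at sea
    stage_schedule: tuple = (
        (1, "guard"), (1, "guard"),
        (1, "post-guard"), (1, "post-guard"),
        (2, "guard"), (2, "guard"),
        (2, "post-guard"), (2, "post-guard"),
    )
    departure: DepartureConfig = field(default_factory=DepartureConfig)
    association: AssociationProcess = field(default_factory=AssociationProcess)
    movement: MovementConfig = field(default_factory=MovementConfig)
    dive: DiveConfig = field(default_factory=DiveConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    bci_mean: float = 10.24
    bci_sd: float = 0.36

    @property
    def n_days(self) -> int:
        return len(self.stage_schedule)

    def __post_init__(self):
        if self.colony.n_birds < 2:
            raise ValueError("need at least two birds")
        if not 0 <= self.sensor.dropout_prob <= 1:
            raise ValueError("dropout_prob must be a probability")


def gi_like(seed: int = 0, **colony_kwargs) -> SimConfig:
    """A low-association colony preset (large-colony regime).

    The association intercept is lowered so that only a minority of birds
    associate, and body condition matches the leaner colony mean.
    """
    colony = ColonyConfig(name="GI", lat=-37.55, lon=149.90, **colony_kwargs)
    return SimConfig(
        seed=seed, colony=colony,
        association=AssociationProcess(beta0=-2.5),
        bci_mean=9.12, bci_sd=0.17,
    )


# --- deployments and schedule -------------------------------------------

def simulate_deployments(config: SimConfig) -> pd.DataFrame:
    """Nests, sexes and morphometrics for the configured colony.

    Birds come in mate pairs (one nest each, F then M); body condition is
    Normal(bci_mean, bci_sd) and mass is reconstructed as BCI * flipper.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.colony.n_birds
    n_nests = (n + 1) // 2
    r = config.colony.nest_spread_m * np.sqrt(rng.uniform(size=n_nests))
    th = rng.uniform(0, 2 * np.pi, size=n_nests)
    nest_x, nest_y = r * np.cos(th), r * np.sin(th)
    rows = []
    for i in range(n):
        nest = i // 2
        flipper = rng.normal(117.0, 3.0)
        bci = rng.normal(config.bci_mean, config.bci_sd)
        lat, lon = _enu_to_latlon(nest_x[nest], nest_y[nest],
                                  config.colony.lat, config.colony.lon)
        rows.append({
            "bird_id": f"{config.colony.name}{i:02d}",
            "colony_id": config.colony.name,
            "stage": "guard",
            "clutch": 1,
            "sex": "F" if i % 2 == 0 else "M",
            "mass": bci * flipper,
            "flipper": flipper,
            "nest_lat": lat, "nest_lon": lon,
            "colony_lat": config.colony.lat, "colony_lon": config.colony.lon,
        })
    return pd.DataFrame(rows)


def birds_at_sea(config: SimConfig, deployments: pd.DataFrame, day: int) -> list[str]:
    """Which birds forage on a day.

    Guard days: mates alternate, so exactly one bird per nest is at sea and
    mates are never concurrent dyad candidates.  Post-guard days: everyone.
    """
    clutch, stage = config.stage_schedule[day]
    ids = list(deployments["bird_id"])
    if stage != "guard":
        return ids
    out = []
    for nest in range((len(ids) + 1) // 2):
        members = ids[2 * nest:2 * nest + 2]
        out.append(members[day % len(members)])
    return out


def simulate_departures(config: SimConfig, at_sea: list[str], day: int) -> dict:
    """Per-bird departure timestamps (epoch s, 4-s grid) for one day."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, day]))
    base = day * DAY_SECONDS + config.departure.mean_time_s
    out = {}
    for bird in at_sea:
        t = base + rng.normal(0.0, config.departure.sd_minutes * 60.0)
        out[bird] = int(round(t / GRID_DT)) * GRID_DT
    return out


# --- truth --------------------------------------------------------------

def assign_truth(config: SimConfig, departures_by_day: dict) -> pd.DataFrame:
    """Bernoulli association truth for every concurrent pair-day.

    Random effects are drawn once per dyad / bird and reused across days,
    which is what makes re-association sticky.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    birds = sorted({b for deps in departures_by_day.values() for b in deps})
    v = {b: rng.normal(0.0, config.association.sigma_bird) for b in birds}
    u: dict = {}
    rows = []
    for day in sorted(departures_by_day):
        deps = departures_by_day[day]
        for a, b in itertools.combinations(sorted(deps), 2):
            if (a, b) not in u:
                u[(a, b)] = rng.normal(0.0, config.association.sigma_dyad)
            gap_min = abs(deps[a] - deps[b]) / 60.0
            eta = (config.association.beta0
                   + config.association.beta_logT * np.log(gap_min + 1.0)
                   + u[(a, b)] + v[a] + v[b])
            p = 1.0 / (1.0 + np.exp(-eta))
            rows.append({
                "bird_a": a, "bird_b": b, "day": day,
                "gap_minutes": gap_min,
                "associated": int(rng.uniform() < p),
            })
    return pd.DataFrame(rows)


# --- geometry helpers ---------------------------------------------------

def _enu_to_latlon(x, y, lat0, lon0):
    lat = lat0 + np.degrees(np.asarray(y) / 6_371_008.8)
    lon = lon0 + np.degrees(np.asarray(x) / (6_371_008.8 * np.cos(np.radians(lat0))))
    return lat, lon


def _zone_lattice(mv: MovementConfig) -> np.ndarray:
    """Hex-like lattice of candidate foraging zones in the annulus."""
    pitch = mv.zone_spacing_m
    rmax = min(mv.zone_rmax_m, mv.max_range_km * 1000.0 - 1000.0)
    pts = []
    j = 0
    y = -rmax
    while y <= rmax:
        offset = (pitch / 2.0) if j % 2 else 0.0
        x = -rmax + offset
        while x <= rmax:
            rr = np.hypot(x, y)
            if mv.zone_rmin_m <= rr <= rmax:
                pts.append((x, y))
            x += pitch
        y += pitch * np.sqrt(3.0) / 2.0
        j += 1
    return np.array(pts)


def _session_rounds(edges: set, max_clique: int) -> list[list[frozenset]]:
    """Cover the association edges by rounds of disjoint clique sessions.

    Each round partitions (part of) the day's birds into groups that are
    cliques of the association graph; all groups of a round forage in
    parallel, so the daily schedule length scales with the number of rounds
    rather than with any single bird's degree.  Greedy: rounds are built by
    repeatedly seeding a group from an uncovered edge and growing it while
    it still covers new edges.
    """
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    key = lambda x, y: (min(x, y), max(x, y))
    uncovered = set(edges)
    rounds: list[list[frozenset]] = []
    while uncovered:
        assigned: set = set()
        groups: list[frozenset] = []
        # seed from high-demand vertices first so rounds stay few
        for a, b in sorted(
            uncovered,
            key=lambda e: (-sum(1 for x in e for nb in adj[x]
                                if key(x, nb) in uncovered), e),
        ):
            if a in assigned or b in assigned or (a, b) not in uncovered:
                continue
            clique = {a, b}
            cands = (adj[a] & adj[b]) - assigned
            while cands and len(clique) < max_clique:
                best = max(
                    cands,
                    key=lambda c: (sum(1 for m in clique
                                       if key(c, m) in uncovered), c),
                )
                if sum(1 for m in clique if key(best, m) in uncovered) == 0:
                    break
                clique.add(best)
                cands = (cands - {best}) & adj[best]
            for pair in itertools.combinations(sorted(clique), 2):
                uncovered.discard(pair)
            groups.append(frozenset(clique))
            assigned |= clique
        rounds.append(groups)
        if len(rounds) > 40:
            raise SimulationError("association graph too dense to schedule")
    return rounds


def _assign_homes(lattice, order, departures, rng):
    """Home zone per bird; birds departing within 10 min get bearings >= 30
    degrees apart so concurrent outbound commutes stay separated beyond the
    colony exclusion radius."""
    bearings = np.arctan2(lattice[:, 1], lattice[:, 0])
    used: set = set()
    homes: dict = {}
    for bird in order:
        conflict = [homes[o] for o in homes
                    if abs(departures[bird] - departures[o]) < 600]
        conflict_bearings = [bearings[c] for c in conflict]

        def ok(i):
            return all(
                min(abs(bearings[i] - cb), 2 * np.pi - abs(bearings[i] - cb))
                >= np.radians(30.0)
                for cb in conflict_bearings
            )

        free = [i for i in range(len(lattice)) if i not in used]
        if not free:
            raise SimulationError(
                "zone lattice exhausted; enlarge zone_rmax_m or max_range_km"
            )
        feasible = [i for i in free if ok(i)]
        if feasible:
            # keep the day's geometry compact: prefer inner-radius zones so
            # session hops (and hence transit legs) stay short
            radii = np.hypot(lattice[feasible, 0], lattice[feasible, 1])
            inner = [feasible[k] for k in np.argsort(radii)[:6]]
            choice = int(rng.choice(inner))
        else:
            choice = max(
                free,
                key=lambda i: min(
                    (min(abs(bearings[i] - cb), 2 * np.pi - abs(bearings[i] - cb))
                     for cb in conflict_bearings),
                    default=np.pi,
                ),
            )
        homes[bird] = choice
        used.add(choice)
    return homes, used


def _plan_dwell_s(seg1, off1, seg2, off2, v, radius=700.0, step=20.0):
    """Seconds two planned transit trajectories spend within ``radius``.

    Each trajectory lingers at its source until its offset, moves along its
    segment at speed ``v``, then lingers at its target for the rest of the
    window.  Evaluated deterministically on a coarse time grid.
    """
    (a0, a1, ha), (b0, b1, hb) = seg1, seg2
    horizon = max(off1 + ha / v, off2 + hb / v) + 120.0
    t = np.arange(0.0, horizon, step)

    def pos(t, p0, p1, hop, off):
        frac = np.clip((t - off) * v / max(hop, 1e-9), 0.0, 1.0)
        return p0[None, :] + frac[:, None] * (p1 - p0)[None, :]

    d = np.hypot(*(pos(t, a0, a1, ha, off1) - pos(t, b0, b1, hb, off2)).T)
    # mirror the detector's run semantics: passes separated by >= 80 s are
    # distinct encounters; report the worst single (bridged) encounter
    idx = np.flatnonzero(d < radius)
    if len(idx) == 0:
        return 0.0
    splits = np.flatnonzero(np.diff(idx) >= 4)
    starts = np.r_[0, splits + 1]
    ends = np.r_[splits, len(idx) - 1]
    return float(max(e - s + 1 for s, e in zip(starts, ends)) * step)


def _transit_offsets(movers, segs, v, edges, max_dwell=600.0):
    """Stagger transit start times so non-associated birds never travel
    together.

    Simultaneous equal-speed hops can keep two birds within the association
    radius for long stretches (near-parallel or collinear legs).  Offsets
    are assigned greedily, longest hop first; an offset is accepted only if
    the planned trajectory never dwells within 700 m of any
    already-scheduled mover for more than ``max_dwell`` seconds —
    comfortably below the association criterion even after positional
    wander.  Pairs that are edges of the day's association graph are
    exempt: proximity between associated birds is harmless.  Brief
    crossings pass the check by design.
    """
    offsets: dict = {}
    for b in sorted(movers, key=lambda b: (-segs[b][2], b)):
        placed = False
        for k in range(60):
            off = 400.0 * k
            if all(
                (min(b, o), max(b, o)) in edges
                or _plan_dwell_s(segs[b], off, segs[o], offsets[o], v)
                <= max_dwell
                for o in offsets
            ):
                offsets[b] = off
                placed = True
                break
        if not placed:
            raise SimulationError(
                "could not schedule conflict-free transits; "
                "fewer birds or a larger foraging area is needed"
            )
    return offsets


def _ou_jitter(n, sd, tau, dt, rng):
    if n == 0:
        return np.zeros(0)
    rho = np.exp(-dt / tau)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -rho], eps)


# --- track realisation --------------------------------------------------

def _day_waypoints(config, truth_day, departures, rng):
    """Waypoint schedules (t, x, y) per bird for one day, plus planted
    windows [(pair, t0, t1), ...]."""
    mv = config.movement
    lattice = _zone_lattice(mv)
    birds = sorted(departures)
    order = sorted(birds, key=lambda b: departures[b])
    homes, used = _assign_homes(lattice, order, departures, rng)

    edges = {(r["bird_a"], r["bird_b"])
             for _, r in truth_day.iterrows() if r["associated"]}
    rounds = _session_rounds(edges, mv.max_clique)

    v = mv.commute_speed_mps
    snap = lambda t: int(np.ceil(t / GRID_DT)) * GRID_DT
    dist = lambda i, j: float(np.hypot(*(lattice[i] - lattice[j])))
    home_dist = {b: float(np.hypot(*lattice[homes[b]])) for b in birds}

    arrive = {b: departures[b] + home_dist[b] / v for b in birds}
    t_cursor = snap(max(arrive.values()) + 120)

    loc = {b: homes[b] for b in birds}            # current lattice zone
    waypoints = {b: [(departures[b], (0.0, 0.0)),
                     (snap(arrive[b]), tuple(lattice[homes[b]]))]
                 for b in birds}
    windows = []

    home_zones = set(used)
    for groups in rounds:
        # participants move to a session zone near their current locations;
        # idle birds linger where they are (their zone stays reserved), so
        # transit legs — and hence the day's length — stay short
        target = dict(loc)
        occupant: dict = {}
        for b in birds:
            occupant.setdefault(loc[b], set()).add(b)
        taken: set = set(home_zones)
        for s in sorted(groups, key=lambda g: (-len(g), sorted(g))):
            member_xy = lattice[[loc[b] for b in s]]
            # a zone is eligible only if every bird currently there belongs
            # to this group — staggered departures must never hand a zone to
            # a new group while its old occupant still lingers
            candidates = [
                i for i in range(len(lattice))
                if i not in taken and occupant.get(i, set()) <= set(s)
            ]
            if not candidates:
                raise SimulationError(
                    "zone lattice exhausted; enlarge zone_rmax_m"
                )
            # minimise the group's worst hop, which sets the transit length
            best = min(candidates, key=lambda i: float(
                np.max(np.hypot(*(member_xy - lattice[i]).T))))
            taken.add(best)
            for b in s:
                target[b] = best
        hops = {b: dist(loc[b], target[b]) for b in birds}
        movers = sorted(b for b in birds if hops[b] > 0.0)
        segs = {b: (lattice[loc[b]], lattice[target[b]], hops[b])
                for b in movers}
        offsets = _transit_offsets(movers, segs, v, edges)
        transit = max(
            300.0,
            max((offsets[b] + hops[b] / v for b in movers), default=0.0) + 60.0,
        )
        for b in movers:
            t_go = snap(t_cursor + offsets[b])  # staggered start
            waypoints[b].append((t_go, tuple(lattice[loc[b]])))
            waypoints[b].append((snap(t_go + hops[b] / v),
                                 tuple(lattice[target[b]])))
        for b in birds:
            loc[b] = target[b]
        t_cursor = snap(t_cursor + transit)
        t0, t1 = t_cursor, t_cursor + mv.session_s
        for s in groups:
            for a, b in itertools.combinations(sorted(s), 2):
                windows.append((a, b, t0, t1))
        t_cursor = snap(t1)

    # synchronized radial return straight from the final zones: with equal
    # speeds and pairwise zone separation >= the lattice pitch, any two
    # birds come within the association radius only moments before entering
    # the colony exclusion zone
    t_return = snap(t_cursor + 60)
    return_dist = {b: float(np.hypot(*lattice[loc[b]])) for b in birds}
    for b in birds:
        waypoints[b].append((t_return, tuple(lattice[loc[b]])))
        waypoints[b].append((snap(t_return + return_dist[b] / v), (0.0, 0.0)))

    day = int(truth_day["day"].iloc[0]) if len(truth_day) else None
    if day is not None and t_return + max(return_dist.values()) / v > \
            (day + 1) * DAY_SECONDS - 2 * 3600:
        raise SimulationError(
            "daily schedule overflows the day; fewer birds or a larger "
            "foraging area is needed"
        )
    return waypoints, windows


def _realise_bird_day(config, waypoints, rng):
    """4-s truth positions for one bird-day from its waypoint schedule."""
    mv = config.movement
    times = np.array([w[0] for w in waypoints], dtype=float)
    xs = np.array([w[1][0] for w in waypoints], dtype=float)
    ys = np.array([w[1][1] for w in waypoints], dtype=float)
    keep = np.r_[True, np.diff(times) > 0]
    times, xs, ys = times[keep], xs[keep], ys[keep]
    grid = np.arange(int(times[0]), int(times[-1]) + GRID_DT, GRID_DT,
                     dtype=np.int64)
    x = np.interp(grid, times, xs)
    y = np.interp(grid, times, ys)
    x = x + _ou_jitter(len(grid), mv.wander_sd_m, mv.wander_tau_s, GRID_DT, rng)
    y = y + _ou_jitter(len(grid), mv.wander_sd_m, mv.wander_tau_s, GRID_DT, rng)
    return grid, x, y


def _depth_profile(config, grid, sessions_mask, rng):
    """Dive bouts during sessions; surface swimming otherwise."""
    dv = config.dive
    depth = np.zeros(len(grid))
    cycle = dv.dive_s + dv.surface_s
    phase = (grid % cycle) < dv.dive_s
    lo, hi = dv.dive_depth_range_m
    bout_depths = rng.uniform(lo, hi, size=len(grid))
    depth[sessions_mask & phase] = bout_depths[sessions_mask & phase]
    return depth


def simulate_tracks(
    config: SimConfig,
    deployments: pd.DataFrame,
    truth: pd.DataFrame,
    departures_by_day: dict,
):
    """Realise GPS fixes and TDR samples for the whole study.

    Returns (gps, tdr, truth_windows) where ``truth_windows`` lists one
    planted co-foraging window per associated pair-session.
    """
    sens = config.sensor
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    gps_rows, windows_all = [], []
    tdr_parts = []
    sea_intervals: dict = {b: [] for b in deployments["bird_id"]}
    session_intervals: dict = {b: [] for b in deployments["bird_id"]}

    for day in sorted(departures_by_day):
        deps = departures_by_day[day]
        truth_day = truth[truth["day"] == day]
        day_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 5, day]))
        waypoints, windows = _day_waypoints(config, truth_day, deps, day_rng)
        for a, b, t0, t1 in windows:
            windows_all.append({"bird_a": a, "bird_b": b, "day": day,
                                "t_start": t0, "t_end": t1})
        for bird in sorted(deps):
            grid, x, y = _realise_bird_day(config, waypoints[bird], day_rng)
            sea_intervals[bird].append((int(grid[0]), int(grid[-1])))
            for a, b, t0, t1 in windows:
                if bird in (a, b):
                    session_intervals[bird].append((t0, t1))
            lat, lon = _enu_to_latlon(x, y, config.colony.lat, config.colony.lon)
            # thin to the GPS duty cycle, then add noise and dropout
            fix_mask = (grid % sens.gps_dt) == 0
            idx = np.flatnonzero(fix_mask)
            if sens.dropout_prob > 0 and len(idx) > 2:
                keep = day_rng.uniform(size=len(idx)) >= sens.dropout_prob
                keep[0] = keep[-1] = True  # retain track ends
                idx = idx[keep]
            noise = (day_rng.normal(0.0, sens.gps_noise_m / np.sqrt(2.0),
                                    size=(len(idx), 2))
                     if sens.gps_noise_m > 0 else np.zeros((len(idx), 2)))
            glat, glon = _enu_to_latlon(x[idx] + noise[:, 0],
                                        y[idx] + noise[:, 1],
                                        config.colony.lat, config.colony.lon)
            gps_rows.append(pd.DataFrame({
                "bird_id": bird, "t": grid[idx], "lat": glat, "lon": glon,
            }))

    # TDR: continuous 4-s record per bird over the whole study
    t_all = np.arange(0, config.n_days * DAY_SECONDS, sens.tdr_dt,
                      dtype=np.int64)
    drift_rate = config.dive.drift_m_per_day / DAY_SECONDS
    for bird in sorted(deployments["bird_id"]):
        wet = np.zeros(len(t_all), dtype=bool)
        for lo, hi in sea_intervals[bird]:
            wet[(t_all >= lo) & (t_all <= hi)] = True
        sess = np.zeros(len(t_all), dtype=bool)
        for lo, hi in session_intervals[bird]:
            sess[(t_all >= lo) & (t_all <= hi)] = True
        depth = _depth_profile(config, t_all, sess & wet, rng)
        raw = depth + drift_rate * t_all  # sensor drift, ZOC removes it
        tdr_parts.append(pd.DataFrame({
            "bird_id": bird, "t": t_all, "depth": raw, "wet": wet,
        }))

    gps = (pd.concat(gps_rows).sort_values(["bird_id", "t"])
           .reset_index(drop=True)) if gps_rows else pd.DataFrame(
        columns=["bird_id", "t", "lat", "lon"])
    tdr = pd.concat(tdr_parts).reset_index(drop=True)
    truth_windows = pd.DataFrame(
        windows_all, columns=["bird_a", "bird_b", "day", "t_start", "t_end"])
    return gps, tdr, truth_windows


def simulate_study(config: SimConfig):
    """End-to-end generation: (deployments, gps, tdr, truth, truth_windows)."""
    deployments = simulate_deployments(config)
    departures_by_day = {
        day: simulate_departures(config, birds_at_sea(config, deployments, day), day)
        for day in range(config.n_days)
    }
    truth = assign_truth(config, departures_by_day)
    gps, tdr, truth_windows = simulate_tracks(
        config, deployments, truth, departures_by_day)
    return deployments, gps, tdr, truth, truth_windows


def day_labels(config: SimConfig) -> pd.DataFrame:
    """(day, clutch, stage) labels from the configured schedule."""
    return pd.DataFrame(
        [(d, c, s) for d, (c, s) in enumerate(config.stage_schedule)],
        columns=["day", "clutch", "stage"],
    )


def emit_study(config: SimConfig, out_dir) -> dict:
    """Write gps.csv, tdr.csv, deployments.csv, truth.csv; returns paths."""
    from pathlib import Path

    from .io_formats import write_gps_csv, write_tdr_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    deployments, gps, tdr, truth, truth_windows = simulate_study(config)

    win_map: dict = {}
    for _, w in truth_windows.iterrows():
        key = (w["bird_a"], w["bird_b"], w["day"])
        win_map.setdefault(key, []).append(f"{w['t_start']}-{w['t_end']}")
    truth = truth.copy()
    truth["windows"] = [
        ";".join(win_map.get((r["bird_a"], r["bird_b"], r["day"]), []))
        for _, r in truth.iterrows()
    ]

    paths = {
        "gps": out / "gps.csv",
        "tdr": out / "tdr.csv",
        "deployments": out / "deployments.csv",
        "truth": out / "truth.csv",
    }
    write_gps_csv(gps, paths["gps"])
    write_tdr_csv(tdr, paths["tdr"])
    deployments.to_csv(paths["deployments"], index=False, lineterminator="\n")
    truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    return paths
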