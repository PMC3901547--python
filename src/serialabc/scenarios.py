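"""Demographic scenarios for IRS-cycle Ne reconstruction.

Six competing piecewise-constant effective-size (Ne) trajectories for an
*Anopheles gambiae* population sampled at six time points across two
indoor-residual-spraying (IRS) rounds:

1. Ne constant;
2. Ne drops at each spray round and starts recovering soon after;
3. Ne drops at each round with no recovery between rounds;
4. Ne tracks rainfall (rank-concordant with interval mean rainfall);
5. Ne anti-tracks rainfall (rank-discordant);
6. like 2, but the post-round-1 decline continues for three months before
   recovery sets in by month four.

Epochs are anchored at the sampling dates, giving one free Ne per sampling
interval (five intervals for the six-date design) plus one shared ancestral
Ne that extends back beyond the pre-study spray round; scenario 6 adds one
extra breakpoint three months after the first in-study round.  Spray rounds
enter through the inequality constraints among interval sizes, not through
extra breakpoints.  Calendar time is converted to (fractional) coalescent
generations by a linear clock.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenerationClock",
    "EpochTrajectory",
    "RainfallSeries",
    "SamplingDesign",
    "ScenarioSpec",
    "calendar_to_generations",
    "build_scenario",
    "draw_scenario_params",
    "draw_scenario_params_batch",
    "percent_decline",
    "percent_rebound",
    "mongola_design",
    "punta_europa_rainfall",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class GenerationClock:
    """Linear calendar <-> generation conversion.

    ``reference_date`` (normally the most recent sample) maps to generation 0;
    earlier dates map to positive "generations before reference".
    """

    generations_per_year: float
    reference_date: dt.date

    def __post_init__(self) -> None:
        if self.generations_per_year <= 0:
            raise ValueError("generations_per_year must be positive")

    def to_generations(self, date: dt.date) -> float:
        if date > self.reference_date:
            raise ValueError(
                f"date {date} is after the reference date {self.reference_date}; "
                "the clock measures generations before the reference"
            )
        days = (self.reference_date - date).days
        return days * self.generations_per_year / DAYS_PER_YEAR

    def to_date(self, generations: float) -> dt.date:
        """Inverse conversion, rounded to the nearest day."""
        if generations < 0:
            raise ValueError("generations must be non-negative")
        days = generations * DAYS_PER_YEAR / self.generations_per_year
        return self.reference_date - dt.timedelta(days=round(days))


def calendar_to_generations(date: dt.date, clock: GenerationClock) -> float:
    """Generations before the clock's reference date (non-negative real)."""
    return clock.to_generations(date)


@dataclass
class EpochTrajectory:
    """Piecewise-constant diploid Ne over generation-time epochs.

    ``boundaries`` is strictly decreasing (times in generations before the
    reference); ``sizes`` has one more entry, oldest epoch first:
    ``sizes[0]`` applies for t >= boundaries[0], ``sizes[i]`` on
    [boundaries[i], boundaries[i-1]) and ``sizes[-1]`` on [0, boundaries[-1]).
    The oldest epoch is unbounded, so the trajectory is defined for all t >= 0.
    """

    boundaries: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.size != self.boundaries.size + 1:
            raise ValueError("need exactly one more size than boundaries")
        if np.any(np.diff(self.boundaries) >= 0):
            raise ValueError("boundaries must be strictly decreasing")
        if self.boundaries.size and self.boundaries[-1] < 0:
            raise ValueError("boundaries must be non-negative times")
        if np.any(self.sizes < 2):
            raise ValueError("all epoch sizes must be >= 2")

    def size_at(self, t: float) -> float:
        """Ne in effect at time t generations before the reference."""
        if t < 0:
            raise ValueError("t must be non-negative")
        # a boundary time belongs to the older epoch (same convention as the
        # simulator); boundaries are stored oldest-first
        n_older = int(np.searchsorted(self.boundaries[::-1], t, side="right"))
        return float(self.sizes[len(self.sizes) - 1 - n_older])

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """(boundaries ascending, sizes most-recent-first) for the simulator."""
        return self.boundaries[::-1].copy(), self.sizes[::-1].copy()


def percent_decline(n_from: float, n_to: float) -> float:
    """Percent reduction from ``n_from`` to ``n_to`` (e.g. 5692 -> 428 is ~92%)."""
    return 100.0 * (1.0 - n_to / n_from)


def percent_rebound(n_from: float, n_to: float) -> float:
    """Rebound of ``n_to`` relative to ``n_from``, as a percentage of n_from
    (e.g. 428 -> 12060 is ~2818%)."""
    return 100.0 * n_to / n_from


@dataclass
class RainfallSeries:
    """Monthly precipitation (mm) covering the study window."""

    months: list[tuple[int, int]]  # (year, month), consecutive
    values_mm: list[float]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.values_mm):
            raise ValueError("months and values_mm must have equal length")
        if any(v < 0 for v in self.values_mm):
            raise ValueError("rainfall must be non-negative")
        for (y0, m0), (y1, m1) in zip(self.months, self.months[1:]):
            if (y1, m1) != ((y0 + 1, 1) if m0 == 12 else (y0, m0 + 1)):
                raise ValueError("months must be consecutive")

    def _month_index(self, year: int, month: int) -> int:
        try:
            return self.months.index((year, month))
        except ValueError:
            raise ValueError(f"rainfall series does not cover {year}-{month:02d}") from None

    def interval_means(self, dates: list[dt.date]) -> np.ndarray:
        """Day-weighted mean monthly rainfall for each interval between
        consecutive dates (len(dates) - 1 values)."""
        out = []
        for d0, d1 in zip(dates, dates[1:]):
            if d1 <= d0:
                raise ValueError("dates must be strictly increasing")
            total = 0.0
            ndays = 0
            d = d0
            while d < d1:
                # days remaining in d's month, clipped to the interval
                if d.month == 12:
                    nxt = dt.date(d.year + 1, 1, 1)
                else:
                    nxt = dt.date(d.year, d.month + 1, 1)
                end = min(nxt, d1)
                k = (end - d).days
                total += k * self.values_mm[self._month_index(d.year, d.month)]
                ndays += k
                d = end
            out.append(total / ndays)
        return np.array(out)


def punta_europa_rainfall() -> RainfallSeries:
    """Synthetic representative monthly rainfall for the study window.

    The study reports only the March–November 2009 total (1919 mm) and the
    seasonality (wet season April–October, the June 2009 deluge, dry
    December–March).  These monthly values are a synthetic stand-in
    constrained to that total and shape; they are NOT measured data.
    """
    months = [(2009, m) for m in range(3, 13)] + [(2010, m) for m in range(1, 5)]
    #           Mar  Apr  May  Jun  Jul  Aug  Sep  Oct  Nov  Dec  Jan Feb Mar Apr
    values = [60, 150, 230, 390, 300, 280, 260, 180, 69, 30, 15, 20, 60, 150]
    assert sum(values[:9]) == 1919  # Mar-Nov 2009 printed total
    return RainfallSeries(months=months, values_mm=[float(v) for v in values])


@dataclass
class SamplingDesign:
    """Temporal sampling design: dated sample groups plus spray-round dates.

    ``spray_dates`` holds the pre-study round first, then the in-study rounds.
    """

    sample_dates: list[dt.date]
    sample_sizes: list[int]
    n_loci: int = 13
    spray_dates: list[dt.date] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_dates) != len(self.sample_sizes):
            raise ValueError("sample_dates and sample_sizes must match")
        if any(d1 <= d0 for d0, d1 in zip(self.sample_dates, self.sample_dates[1:])):
            raise ValueError("sample dates must be strictly increasing")
        if any(n <= 0 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")

    @property
    def n_groups(self) -> int:
        return len(self.sample_dates)

    def tip_times(self, clock: GenerationClock) -> np.ndarray:
        """Sampling time of every gene copy (2 per individual), group order."""
        times = []
        for date, n in zip(self.sample_dates, self.sample_sizes):
            times.extend([clock.to_generations(date)] * (2 * n))
        return np.array(times)


def mongola_design() -> SamplingDesign:
    """The Bioko Island study design: six samples in 2009–2010, 13 loci,
    one pre-study spray round (Oct 2008) and two in-study rounds.

    Multi-day collection/spray windows are represented by their midpoint day.
    """
    return SamplingDesign(
        sample_dates=[
            dt.date(2009, 3, 25),
            dt.date(2009, 5, 18),
            dt.date(2009, 7, 7),
            dt.date(2009, 8, 31),
            dt.date(2009, 11, 10),
            dt.date(2010, 4, 13),
        ],
        sample_sizes=[125, 142, 137, 147, 146, 95],
        n_loci=13,
        spray_dates=[dt.date(2008, 10, 1), dt.date(2009, 6, 14), dt.date(2009, 12, 18)],
    )


# -- constraints -------------------------------------------------------------

@dataclass(frozen=True)
class Less:
    """params[lo] < params[hi]."""

    lo: int
    hi: int

    def satisfied(self, params: np.ndarray) -> np.ndarray:
        return params[..., self.lo] < params[..., self.hi]

    def describe(self, names: list[str]) -> str:
        return f"{names[self.lo]} < {names[self.hi]}"


@dataclass(frozen=True)
class RankOrder:
    """Rank order of params[idx] matches ``ranks`` (concordant) or its
    reverse (discordant); used for the rainfall-correlation scenarios."""

    idx: tuple[int, ...]
    ranks: tuple[int, ...]
    concordant: bool

    def satisfied(self, params: np.ndarray) -> np.ndarray:
        sub = params[..., list(self.idx)]
        order = np.argsort(np.argsort(sub, axis=-1), axis=-1)
        target = np.asarray(self.ranks)
        if not self.concordant:
            target = len(self.idx) - 1 - target
        return np.all(order == target, axis=-1)

    def describe(self, names: list[str]) -> str:
        rel = "concordant" if self.concordant else "discordant"
        return f"rank({[names[i] for i in self.idx]}) {rel} with rainfall"


@dataclass
class ScenarioSpec:
    """One competing demographic model, ready for prior sampling.

    ``epoch_param_idx`` maps each epoch (oldest first, one more than
    boundaries) to an entry of the parameter vector, so scenarios may share
    one parameter across several epochs (scenario 1 uses a single one).
    """

    scenario_id: int
    boundaries: np.ndarray  # generations before reference, strictly decreasing
    param_names: list[str]
    epoch_param_idx: list[int]
    constraints: list
    prior_low: float = 10.0
    prior_high: float = 1.0e5

    def __post_init__(self) -> None:
        if len(self.epoch_param_idx) != len(self.boundaries) + 1:
            raise ValueError("need one epoch per boundary gap")
        p = len(self.param_names)
        if any(i < 0 or i >= p for i in self.epoch_param_idx):
            raise ValueError("epoch_param_idx references undeclared parameters")
        for c in self.constraints:
            for i in getattr(c, "idx", (c.lo, c.hi) if isinstance(c, Less) else ()):
                if i < 0 or i >= p:
                    raise ValueError("constraint references undeclared parameters")
        if not (0 < self.prior_low < self.prior_high):
            raise ValueError("invalid prior bounds")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def satisfies(self, params: np.ndarray) -> np.ndarray:
        """Vectorised constraint check; params shape (..., n_params)."""
        ok = np.ones(params.shape[:-1], dtype=bool)
        for c in self.constraints:
            ok &= c.satisfied(params)
        return ok

    def trajectory(self, params: np.ndarray) -> EpochTrajectory:
        params = np.asarray(params, dtype=float)
        return EpochTrajectory(
            boundaries=self.boundaries.copy(),
            sizes=params[list(self.epoch_param_idx)],
        )

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "boundaries": [float(b) for b in self.boundaries],
            "param_names": list(self.param_names),
            "epoch_param_idx": list(self.epoch_param_idx),
            "prior_low": self.prior_low,
            "prior_high": self.prior_high,
            "constraints": [
                {"kind": "less", "lo": c.lo, "hi": c.hi}
                if isinstance(c, Less)
                else {
                    "kind": "rank",
                    "idx": list(c.idx),
                    "ranks": list(c.ranks),
                    "concordant": c.concordant,
                }
                for c in self.constraints
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        cons = []
        for c in d.get("constraints", []):
            if c["kind"] == "less":
                cons.append(Less(c["lo"], c["hi"]))
            else:
                cons.append(RankOrder(tuple(c["idx"]), tuple(c["ranks"]), c["concordant"]))
        return cls(
            scenario_id=d["scenario_id"],
            boundaries=np.array(d["boundaries"], dtype=float),
            param_names=list(d["param_names"]),
            epoch_param_idx=list(d["epoch_param_idx"]),
            constraints=cons,
            prior_low=d.get("prior_low", 10.0),
            prior_high=d.get("prior_high", 1.0e5),
        )


def _add_months(date: dt.date, months: int) -> dt.date:
    m = date.month - 1 + months
    y = date.year + m // 12
    m = m % 12 + 1
    day = min(date.day, [31, 29 if y % 4 == 0 and (y % 100 != 0 or y % 400 == 0) else 28,
                         31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1])
    return dt.date(y, m, day)


def build_scenario(
    scenario_id: int,
    design: SamplingDesign,
    clock: GenerationClock,
    prior_low: float = 10.0,
    prior_high: float = 1.0e5,
    rainfall: RainfallSeries | None = None,
) -> ScenarioSpec:
    """Construct one of the six competing scenario specifications.

    Interval parameters N1..N5 cover the five sampling intervals
    (oldest first); N_anc is the shared ancestral size reaching back beyond
    the pre-study spray round.  Scenario 6 splits the interval containing
    "3 months after round 1" at that breakpoint (parameters N4a/N4b).
    """
    if scenario_id not in range(1, 7):
        raise ValueError("scenario_id must be in 1..6")
    dates = design.sample_dates
    if len(dates) < 2:
        raise ValueError("need at least two sample dates")
    n_int = len(dates) - 1
    # boundaries at all but the newest sample date, oldest first
    bnd = np.array([clock.to_generations(d) for d in dates[:-1]])

    if scenario_id == 1:
        return ScenarioSpec(
            scenario_id=1,
            boundaries=np.array([]),
            param_names=["N"],
            epoch_param_idx=[0],
            constraints=[],
            prior_low=prior_low,
            prior_high=prior_high,
        )

    names = ["N_anc"] + [f"N{i}" for i in range(1, n_int + 1)]
    epoch_idx = list(range(n_int + 1))

    if scenario_id in (2, 3, 6) and len(design.spray_dates) < 3:
        raise ValueError(f"scenario {scenario_id} needs the pre-study and two in-study spray dates")
    if scenario_id in (4, 5) and rainfall is None:
        raise ValueError(f"scenario {scenario_id} needs a rainfall series")

    def interval_of(date: dt.date) -> int:
        """1-based sampling interval containing ``date`` (clipped)."""
        for i in range(n_int):
            if dates[i] <= date < dates[i + 1]:
                return i + 1
        return n_int if date >= dates[-1] else 1

    if scenario_id == 2:
        r1, r2 = design.spray_dates[1], design.spray_dates[2]
        i1, i2 = interval_of(r1), interval_of(r2)
        cons: list = [Less(0, 1)]  # recovery from the pre-study round
        for i in range(1, n_int):
            a, b = i, i + 1  # params N_i, N_{i+1}
            if b == i1 or b == i2:
                cons.append(Less(b, a))  # drop entering a spray interval
            else:
                cons.append(Less(a, b))  # recovery otherwise
        return ScenarioSpec(2, bnd, names, epoch_idx, cons, prior_low, prior_high)

    if scenario_id == 3:
        cons = [Less(i + 1, i) for i in range(n_int)]  # N_anc > N1 > ... > N5
        return ScenarioSpec(3, bnd, names, epoch_idx, cons, prior_low, prior_high)

    if scenario_id in (4, 5):
        means = rainfall.interval_means(dates)
        ranks = tuple(int(r) for r in np.argsort(np.argsort(means)))
        cons = [RankOrder(tuple(range(1, n_int + 1)), ranks, concordant=(scenario_id == 4))]
        return ScenarioSpec(scenario_id, bnd, names, epoch_idx, cons, prior_low, prior_high)

    # scenario 6: continued decline for 3 months after round 1, recovery by month 4
    r1, r2 = design.spray_dates[1], design.spray_dates[2]
    brk = _add_months(r1, 3)
    if not dates[0] < brk < dates[-1]:
        raise ValueError("3-month breakpoint falls outside the sampling window")
    j = interval_of(brk)  # interval split by the breakpoint
    t_brk = clock.to_generations(brk)
    if j <= interval_of(r1):
        raise ValueError("3-month breakpoint must fall after the round-1 interval")
    names6 = ["N_anc"]
    epoch_idx6 = [0]
    bnd6: list[float] = []
    first_param_of_interval: dict[int, int] = {}
    split_hi = -1  # param index of the post-breakpoint piece
    for i in range(1, n_int + 1):
        bnd6.append(float(clock.to_generations(dates[i - 1])))
        if i == j:
            names6 += [f"N{i}a", f"N{i}b"]
            first_param_of_interval[i] = len(names6) - 2
            epoch_idx6 += [len(names6) - 2, len(names6) - 1]
            bnd6.append(t_brk)
            split_hi = len(names6) - 1
        else:
            names6.append(f"N{i}")
            first_param_of_interval[i] = len(names6) - 1
            epoch_idx6.append(len(names6) - 1)
    cons = [Less(0, 1)]  # recovery from the pre-study round
    # decline from round 1 until the breakpoint, recovery after, drop at round 2
    decline_from = first_param_of_interval[interval_of(r1)]
    round2_param = first_param_of_interval[interval_of(r2)]
    seq = epoch_idx6[1:]  # param index per epoch, oldest first
    for a, b in zip(seq, seq[1:]):
        declining = decline_from <= b < split_hi or b == round2_param
        cons.append(Less(b, a) if declining else Less(a, b))
    return ScenarioSpec(6, np.array(bnd6), names6, epoch_idx6, cons, prior_low, prior_high)


def draw_scenario_params_batch(
    spec: ScenarioSpec,
    n: int,
    rng: np.random.Generator,
    acceptance_floor: float = 1.0e-4,
) -> np.ndarray:
    """Draw ``n`` parameter vectors satisfying all constraints.

    Log-uniform prior on [prior_low, prior_high] per parameter, with
    rejection sampling against the constraint set.  Aborts with a diagnostic
    if the empirical acceptance rate falls below ``acceptance_floor``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    lo, hi = math.log(spec.prior_low), math.log(spec.prior_high)
    out = np.empty((n, spec.n_params))
    got = 0
    tried = 0
    while got < n:
        m = max(1024, 4 * (n - got))
        draw = np.exp(rng.uniform(lo, hi, size=(m, spec.n_params)))
        ok = spec.satisfies(draw)
        acc = draw[ok]
        take = min(acc.shape[0], n - got)
        out[got : got + take] = acc[:take]
        got += take
        tried += m
        if tried >= 1e5 and got / tried < acceptance_floor:
            raise RuntimeError(
                f"scenario {spec.scenario_id}: constraint acceptance rate "
                f"{got / tried:.2e} below floor {acceptance_floor:.0e} after {tried} draws"
            )
    return out


def draw_scenario_params(
    spec: ScenarioSpec, rng: np.random.Generator
) -> tuple[np.ndarray, EpochTrajectory]:
    """Draw one parameter vector and its realized trajectory."""
    params = draw_scenario_params_batch(spec, 1, rng)[0]
    assert spec.satisfies(params[None, :])[0]
    return params, spec.trajectory(params)
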