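"""Synthetic landscapes, nest networks, switching sequences and telemetry.

The generator emulates the statistical structure the analysis assumes, at
the magnitudes reported for the urban flying-squirrel study system:

* a patchy 25 m habitat raster with class mixture about 52 % forest
  (split into suitable and movement forest), 38 % urban, 7 % unsuitable
  and 3 % water, grown as contiguous patches so that connectivity
  definitions meaningfully differ;
* females hold ~4.2 nests (SD 1.6) in tight clouds (~300 m radius), males
  ~7.0 nests (SD 2.7) spread over ~1 km, with nests biased toward suitable
  forest (67/20/10/3 across H1/H2/H3/H4);
* nest-switching sequences simulated forward from the Markov model itself,
  with individual coefficients drawn from the population hierarchy
  beta_l ~ N(alpha0 + alpha1 * s, Sigma);
* nightly telemetry tracks as correlated random walks with planted
  stationary stops, female bursts shorter than male.

Every draw descends from the scenario seed, so datasets are bit-reproducible.
The hidden truth (per-individual betas and the population parameters) is
returned alongside each dataset for recovery scoring but is never seen by
the fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes_fit import IndividualData
from .connectivity import NestSite, build_connectivity, log_distance_matrix
from .landscape import HabitatClass, HabitatRaster, HomeRangePolygon, compute_mcp
from .movement import Fix, NightTrack, merge_repeated_fixes
from .nest_markov import simulate_sequence

#: Study-system habitat mixture: 52 % forest (suitable + movement),
#: 38 % urban, 5 % clear-cut/field + 3 % saplings, 3 % water (sums to 1).
DEFAULT_MIXTURE = {
    HabitatClass.H1: 0.32,
    HabitatClass.H2: 0.20,
    HabitatClass.H3: 0.38,
    HabitatClass.H4: 0.07,
    HabitatClass.H5: 0.03,
}

#: Nest habitat placement weights over H1/H2/H3/H4 (most nests in mature
#: spruce forest; ~20 % movement habitat, 10 % urban, 3 % unsuitable).
NEST_HABITAT_WEIGHTS = {
    HabitatClass.H1: 0.67,
    HabitatClass.H2: 0.20,
    HabitatClass.H3: 0.10,
    HabitatClass.H4: 0.03,
}

#: Nest-structure mix: 48 % cavities, 41 % twig nests, 8 % boxes, 2 % buildings.
NEST_TYPE_WEIGHTS = {"cavity": 0.48, "twig": 0.41, "box": 0.08, "building": 0.02}


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of a synthetic study, with defaults at study magnitudes."""

    extent: float = 2000.0          # m; square landscape side
    resolution: float = 25.0        # m per cell
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    patch_scale: float = 200.0      # m; typical habitat patch diameter
    n_females: int = 10
    n_males: int = 10
    nests_mean: dict = field(default_factory=lambda: {"F": 4.2, "M": 7.0})
    nests_sd: dict = field(default_factory=lambda: {"F": 1.6, "M": 2.7})
    nest_cloud_radius: dict = field(default_factory=lambda: {"F": 300.0, "M": 1000.0})
    # population truth for the switching model (beta_I, beta_D, beta_C)
    alpha0: tuple = (1.2, -0.4, 0.6)
    alpha1: tuple = (0.2, -0.1, 0.2)
    Sigma: tuple = ((0.3, 0.0, 0.0), (0.0, 0.05, 0.0), (0.0, 0.0, 0.2))
    true_connectivity: str = "C5g"
    connectivity_definitions: tuple = ("C5g",)
    observation_days: int = 120     # daily nest checks over this span
    missing_day_rate: float = 0.10  # fraction of days with no nest record
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        if any(v < 0 for v in self.class_mixture.values()):
            raise ValueError("class mixture targets must be non-negative")
        S = np.asarray(self.Sigma, float)
        np.linalg.cholesky(S)  # raises if not PD
        if self.true_connectivity not in self.connectivity_definitions:
            raise ValueError("true_connectivity must be among connectivity_definitions")


@dataclass(frozen=True)
class SyntheticIndividual:
    individual_id: str
    sex: str  # 'F' / 'M'
    nests: tuple[NestSite, ...]
    home_range: HomeRangePolygon
    fixes: np.ndarray  # (k, 2) relocation cloud used for the MCP


@dataclass(frozen=True)
class SyntheticDataset:
    scenario: SimulationScenario
    raster: HabitatRaster
    individuals: tuple[SyntheticIndividual, ...]
    data: tuple[IndividualData, ...]
    true_betas: np.ndarray  # (n_ind, 3) hidden truth; never passed to the fitter


def generate_landscape(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> HabitatRaster:
    """Patch-growing landscape with exact per-class cell quotas.

    Each class receives round(target * n_cells) cells grown as contiguous
    patches of roughly ``patch_scale`` diameter from random seeds, so the
    realized class proportions match the mixture to within rounding.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n = int(round(scenario.extent / scenario.resolution))
    n_cells = n * n
    classes = sorted(scenario.class_mixture, key=lambda c: -scenario.class_mixture[c])
    quotas = {c: int(round(scenario.class_mixture[c] * n_cells)) for c in classes}
    quotas[classes[0]] += n_cells - sum(quotas.values())  # rounding remainder

    grid = np.zeros((n, n), dtype=np.int8)
    unassigned = n_cells
    patch_cells = max(int((scenario.patch_scale / scenario.resolution) ** 2), 1)
    order = [c for c in classes if quotas[c] > 0]
    rng.shuffle(order)
    for cls in order:
        remaining = quotas[cls]
        while remaining > 0 and unassigned > 0:
            target = min(remaining, max(1, int(rng.exponential(patch_cells))))
            free = np.flatnonzero(grid.ravel() == 0)
            seed = free[rng.integers(len(free))]
            frontier = [(seed // n, seed % n)]
            grown = 0
            while frontier and grown < target:
                k = rng.integers(len(frontier))
                r, c = frontier.pop(k)
                if grid[r, c] != 0:
                    continue
                grid[r, c] = int(cls)
                grown += 1
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n and 0 <= cc < n and grid[rr, cc] == 0:
                        frontier.append((rr, cc))
            remaining -= grown
            unassigned -= grown
    return HabitatRaster(grid=grid, origin=(0.0, 0.0), resolution=scenario.resolution)


def _sample_nest_cells(
    raster: HabitatRaster,
    center: tuple[float, float],
    radius: float,
    k: int,
    rng: np.random.Generator,
) -> list[tuple[float, float, HabitatClass]]:
    """Sample k nest locations in a disc, class-weighted then uniform in class."""
    X, Y = raster.cell_centers()
    dist = np.hypot(X - center[0], Y - center[1])
    in_disc = dist <= radius
    picks = []
    for _ in range(k):
        present = [c for c in NEST_HABITAT_WEIGHTS if np.any(in_disc & (raster.grid == int(c)))]
        if not present:
            raise ValueError("no habitable cells within the nest cloud radius")
        w = np.array([NEST_HABITAT_WEIGHTS[c] for c in present])
        cls = present[rng.choice(len(present), p=w / w.sum())]
        rows, cols = np.nonzero(in_disc & (raster.grid == int(cls)))
        j = rng.integers(len(rows))
        cx, cy = raster.cell_center(rows[j], cols[j])
        jit = (rng.uniform(-0.45, 0.45, 2)) * raster.resolution
        picks.append((cx + jit[0], cy + jit[1], cls))
    return picks


def generate_individuals(
    scenario: SimulationScenario,
    raster: HabitatRaster,
    rng: np.random.Generator | None = None,
) -> tuple[SyntheticIndividual, ...]:
    """Nest networks and MCP home ranges for the simulated population.

    Nest counts are drawn per sex around the study means, placement is
    biased toward suitable forest, and female nest clouds are tighter than
    male ones.  The home range is the MCP of the nests plus a jittered
    relocation cloud around them.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    h1_rows, h1_cols = np.nonzero(raster.grid == int(HabitatClass.H1))
    if len(h1_rows) == 0:
        raise ValueError("raster contains no suitable (H1) cells for nest placement")
    margin = 0.05 * scenario.extent
    individuals = []
    roster = [("F", k) for k in range(scenario.n_females)] + [
        ("M", k) for k in range(scenario.n_males)
    ]
    for sex, k in roster:
        n_nests = max(2, int(round(rng.normal(scenario.nests_mean[sex], scenario.nests_sd[sex]))))
        radius = scenario.nest_cloud_radius[sex]
        for _attempt in range(100):
            j = rng.integers(len(h1_rows))
            cx, cy = raster.cell_center(h1_rows[j], h1_cols[j])
            if margin <= cx <= scenario.extent - margin and margin <= cy <= scenario.extent - margin:
                try:
                    picks = _sample_nest_cells(raster, (cx, cy), radius, n_nests, rng)
                    break
                except ValueError:
                    continue
        else:
            raise ValueError("could not place a nest cloud; insufficient suitable habitat")
        nests = tuple(
            NestSite(
                nest_id=f"{sex}{k}_n{i}", x=x, y=y,
                nest_type=rng.choice(
                    list(NEST_TYPE_WEIGHTS),
                    p=np.array(list(NEST_TYPE_WEIGHTS.values()))
                    / sum(NEST_TYPE_WEIGHTS.values()),
                ),
            )
            for i, (x, y, _cls) in enumerate(picks)
        )
        nest_xy = np.array([(s.x, s.y) for s in nests])
        cloud = nest_xy[rng.integers(len(nests), size=30)] + rng.normal(0, 60.0, (30, 2))
        fixes = np.vstack([nest_xy, cloud])
        hr = compute_mcp(fixes, individual_id=f"{sex}{k}")
        individuals.append(
            SyntheticIndividual(f"{sex}{k}", sex, nests, hr, fixes)
        )
    return tuple(individuals)


def observation_schedule(scenario: SimulationScenario, rng: np.random.Generator) -> list[int]:
    """Daily check days over the span, with a fraction dropped at random."""
    days = [0]
    for d in range(1, scenario.observation_days):
        if rng.random() >= scenario.missing_day_rate:
            days.append(d)
    return days


def generate_dataset(scenario: SimulationScenario) -> SyntheticDataset:
    """Full forward-simulated dataset: everything the sampler consumes.

    Per individual: beta_l ~ N(alpha0 + alpha1*s, Sigma), the log-distance
    matrix D, the requested connectivity matrices from the generated
    landscape, and a nest sequence simulated from the true model under the
    ``true_connectivity`` matrix on a daily schedule with missing days.
    """
    rng = np.random.default_rng(scenario.seed)
    raster = generate_landscape(scenario, rng)
    individuals = generate_individuals(scenario, raster, rng)
    alpha0 = np.asarray(scenario.alpha0, float)
    alpha1 = np.asarray(scenario.alpha1, float)
    Sigma = np.asarray(scenario.Sigma, float)
    chol = np.linalg.cholesky(Sigma)
    data = []
    true_betas = np.zeros((len(individuals), 3))
    for l, ind in enumerate(individuals):
        s = -1 if ind.sex == "F" else 1
        beta = alpha0 + s * alpha1 + chol @ rng.standard_normal(3)
        true_betas[l] = beta
        D = log_distance_matrix(list(ind.nests))
        C_mats = {
            name: build_connectivity(list(ind.nests), raster, ind.home_range, name)
            for name in scenario.connectivity_definitions
        }
        days = observation_schedule(scenario, rng)
        seq = simulate_sequence(
            beta, D, C_mats[scenario.true_connectivity],
            start_index=int(rng.integers(len(ind.nests))),
            observation_days=days, rng=rng,
        )
        seq = type(seq)(individual_id=ind.individual_id, observations=seq.observations)
        data.append(
            IndividualData(
                individual_id=ind.individual_id, sequence=seq,
                D=D, C_matrices=C_mats, sex=s,
            )
        )
    return SyntheticDataset(
        scenario=scenario, raster=raster, individuals=individuals,
        data=tuple(data), true_betas=true_betas,
    )


@dataclass(frozen=True)
class TrackFixture:
    """A simulated night plus the ground-truth stop positions planted in it."""

    track: NightTrack
    stop_fix_indices: tuple[int, ...]


def generate_tracks(
    individuals: tuple[SyntheticIndividual, ...],
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    *,
    nights_per_individual: int = 3,
    fixes_per_night: int = 40,
    step_scale: dict | None = None,
    stop_every: int = 10,
    stop_minutes: float = 25.0,
) -> list[TrackFixture]:
    """Correlated-random-walk nightly tracks with planted stationary stops.

    Step scales are sex-specific (females shorter) so female bursts are on
    average shorter than male bursts.  Every ``stop_every``-th fix is a stop
    of ``stop_minutes`` (exceeding the default burst threshold), whose index
    is reported as ground truth for burst extraction.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    if step_scale is None:
        step_scale = {"F": 20.0, "M": 45.0}
    fixtures = []
    for ind in individuals:
        start_xy = np.array([ind.nests[0].x, ind.nests[0].y])
        for night in range(nights_per_individual):
            t0 = pd.Timestamp("2010-04-01 22:00") + pd.Timedelta(days=night)
            heading = rng.uniform(0, 2 * np.pi)
            xy = start_xy.copy()
            fixes, stops = [], []
            t = t0
            for i in range(fixes_per_night):
                is_stop = i > 0 and i % stop_every == 0
                stationary = stop_minutes if is_stop else 0.0
                fixes.append(
                    Fix(ind.individual_id, ind.sex, t, float(xy[0]), float(xy[1]), stationary)
                )
                if is_stop:
                    stops.append(i)
                heading += rng.normal(0, 0.6)
                step = rng.exponential(step_scale[ind.sex])
                xy = xy + step * np.array([np.cos(heading), np.sin(heading)])
                # keep the walk inside the landscape (animals do not leave
                # the mapped study area)
                xy = np.clip(xy, 5.0, scenario.extent - 5.0)
                t = t + pd.Timedelta(minutes=2 + stationary)
            track = NightTrack(fixes=merge_repeated_fixes(fixes))
            fixtures.append(TrackFixture(track=track, stop_fix_indices=tuple(stops)))
    return fixtures
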