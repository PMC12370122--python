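"""Synthetic longitudinal cohort generator for the CIAF multi-state analysis.

Emulates a three-round survey of under-five children: each child carries a
set of household/maternal covariates, follows a latent continuous-time
Markov chain over the three CIAF states whose intensities may depend on the
covariates through a proportional-hazards term, and is observed at roughly
0, 18 and 36 months with per-round timing jitter and dropout.  Z-scores
consistent with each observed state are synthesised so the classification
step can be exercised end to end.

The defaults encode the survey this generator emulates: ~3,000 children,
baseline state mix ~40/46/14%, covariate marginals of a rural Ethiopian
safety-net cohort, and per-month baseline intensities of the magnitude
estimated for that population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ctmc import IntensityMatrix, build_intensity_matrix

__all__ = [
    "CohortConfig",
    "Trajectory",
    "DEFAULT_BASELINE_INTENSITIES",
    "sample_covariates",
    "simulate_trajectory",
    "panel_observe",
    "synthesize_anthropometry",
    "generate_cohort",
    "write_cohort",
    "intensity_with_covariates",
]

#: Baseline per-month transition intensities of the three-state malnutrition
#: process (1 undernourished, 2 nourished, 3 overnourished) used as the
#: generator's default truth.
DEFAULT_BASELINE_INTENSITIES = {
    (1, 2): 0.0126,
    (1, 3): 0.007183,
    (2, 1): 0.022356,
    (2, 3): 0.008154,
    (3, 1): 0.063464,
    (3, 2): 0.048562,
}

#: Baseline state mix (undernourished / nourished / overnourished).
DEFAULT_INITIAL_DIST = (1207 / 3044, 1414 / 3044, 423 / 3044)

#: Bernoulli marginals for the binary covariates, coded so 1 means female /
#: Oromia / any schooling / non-homemaker / household larger than 5.
DEFAULT_COVARIATE_MARGINALS = {
    "sex": 0.485,          # P(female)
    "region": 0.439,       # P(Oromia)
    "mother_educ": 0.272,  # P(any schooling)
    "mother_occ": 0.321,   # P(main activity not unpaid housework)
    "hh_size_gt5": 0.35,
}

COVARIATE_COLUMNS = ("sex", "age_months", "mother_educ", "mother_occ",
                     "hh_size_gt5", "region")

PANEL_COLUMNS = ("child_id", "time_months", "state", "haz", "whz", "waz",
                 "sex", "age_months", "mother_educ", "mother_occ",
                 "hh_size_gt5", "region", "excluded")


@dataclass
class CohortConfig:
    """Everything needed to draw one synthetic cohort.

    ``true_betas`` maps a 1-based transition ``(h, j)`` to a dict of
    per-covariate log-hazard-ratios; transitions absent from the dict have
    no covariate effect.
    """

    n_children: int = 3044
    round_times: tuple = (0.0, 18.0, 36.0)
    round_jitter_sd: float = 1.0
    dropout_prob_per_round: float = 0.03
    true_Q0: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_INTENSITIES))
    true_betas: dict = field(default_factory=dict)
    covariate_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS))
    initial_state_dist: tuple = DEFAULT_INITIAL_DIST
    baseline_age_range: tuple = (0.0, 35.0)
    seed: int | None = None

    def __post_init__(self):
        times = tuple(float(t) for t in self.round_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("round_times must be strictly increasing")
        if not 0.0 <= self.dropout_prob_per_round <= 1.0:
            raise ValueError("dropout_prob_per_round must be a probability")
        # partial marginal specs override the defaults covariate by covariate
        self.covariate_marginals = {**DEFAULT_COVARIATE_MARGINALS,
                                    **self.covariate_marginals}
        for name, p in self.covariate_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal for {name!r} must be in [0, 1], got {p}")
        dist = np.asarray(self.initial_state_dist, dtype=float)
        if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("initial_state_dist must be a probability vector")
        self.round_times = times

    @property
    def Q0(self) -> IntensityMatrix:
        return build_intensity_matrix(self.true_Q0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_Q0"] = {f"{h}->{j}": v for (h, j), v in self.true_Q0.items()}
        d["true_betas"] = {
            f"{h}->{j}": dict(b) for (h, j), b in self.true_betas.items()
        }
        return d


@dataclass
class Trajectory:
    """A latent sample path: state ``visited_states[k]`` from ``jump_times[k]``."""

    child_id: int
    jump_times: np.ndarray
    visited_states: np.ndarray
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.visited_states = np.asarray(self.visited_states, dtype=int)
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if np.any(np.diff(self.visited_states) == 0):
            raise ValueError("consecutive visited states must differ")

    def state_at(self, t: float) -> int:
        """State occupied at time ``t`` (>= first jump time)."""
        idx = int(np.searchsorted(self.jump_times, t, side="right")) - 1
        if idx < 0:
            raise ValueError(f"time {t} precedes the path start {self.jump_times[0]}")
        return int(self.visited_states[idx])


def sample_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One covariate row per child, reference-coded (0 = reference level)."""
    n = config.n_children
    cols = {}
    for name, p in config.covariate_marginals.items():
        cols[name] = (rng.random(n) < p).astype(int)
    lo, hi = config.baseline_age_range
    cols["age_months"] = rng.uniform(lo, hi, n)
    cols["child_id"] = np.arange(1, n + 1)
    df = pd.DataFrame(cols)
    return df[["child_id", *COVARIATE_COLUMNS]]


def intensity_with_covariates(Q0, betas: dict, z: dict) -> IntensityMatrix:
    """Proportional-hazards modulation q_hj(z) = q0_hj * exp(beta_hj . z)."""
    q0 = np.asarray(Q0, dtype=float)
    rates = {}
    n = q0.shape[0]
    for h in range(1, n + 1):
        for j in range(1, n + 1):
            if h == j or q0[h - 1, j - 1] == 0:
                continue
            lin = sum(b * z[name] for name, b in betas.get((h, j), {}).items())
            rates[(h, j)] = q0[h - 1, j - 1] * np.exp(lin)
    return build_intensity_matrix(rates)


def simulate_trajectory(Q, horizon: float, initial_state: int,
                        rng: np.random.Generator, child_id: int = 0,
                        t0: float = 0.0) -> Trajectory:
    """Gillespie simulation of the CTMC over [t0, t0 + horizon].

    Holding time in state h is exponential with rate -q_hh; the next state is
    drawn from the embedded jump chain q_hj / (-q_hh).  An absorbing state
    simply holds until the horizon.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    qm = np.asarray(Q, dtype=float)
    times = [t0]
    states = [int(initial_state)]
    t, s = t0, int(initial_state)
    end = t0 + horizon
    while True:
        exit_rate = -qm[s - 1, s - 1]
        if exit_rate <= 0:
            break
        t = t + rng.exponential(1.0 / exit_rate)
        if t >= end:
            break
        probs = qm[s - 1].copy()
        probs[s - 1] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(len(probs), p=probs)) + 1
        times.append(t)
        states.append(s)
    return Trajectory(child_id, np.array(times), np.array(states))


def _chain_segments(segments: list[Trajectory]) -> Trajectory:
    """Concatenate piecewise trajectories, merging boundary no-op jumps."""
    times = list(segments[0].jump_times)
    states = list(segments[0].visited_states)
    for seg in segments[1:]:
        for t, s in zip(seg.jump_times, seg.visited_states):
            if s != states[-1]:
                times.append(t)
                states.append(s)
    return Trajectory(segments[0].child_id, np.array(times), np.array(states),
                      segments[0].covariates)


def observation_schedule(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Realised observation times for one child: baseline fixed at the first
    round time, later rounds jittered by N(0, sd) and forced to stay ordered
    (at least half a month apart)."""
    times = np.array(config.round_times, dtype=float)
    if config.round_jitter_sd > 0:
        times[1:] += rng.normal(0.0, config.round_jitter_sd, len(times) - 1)
        for r in range(1, len(times)):
            times[r] = max(times[r], times[r - 1] + 0.5)
    return times


def panel_observe(trajectory: Trajectory, round_times, jitter_sd: float = 0.0,
                  dropout_prob: float = 0.0,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Observe a latent path at survey rounds.

    Jitter (rounds after the first) and independent per-round dropout are
    applied when requested; once a child drops out no later rows are
    emitted.  Children left with fewer than two rows are flagged
    ``excluded`` for downstream filtering.
    """
    times = np.array(round_times, dtype=float)
    if rng is None and (jitter_sd > 0 or dropout_prob > 0):
        raise ValueError("rng required when jitter or dropout is requested")
    if jitter_sd > 0:
        times[1:] += rng.normal(0.0, jitter_sd, len(times) - 1)
        for r in range(1, len(times)):
            times[r] = max(times[r], times[r - 1] + 0.5)
    n_obs = len(times)
    if dropout_prob > 0:
        for r in range(1, len(times)):
            if rng.random() < dropout_prob:
                n_obs = r
                break
    times = times[:n_obs]
    base_age = trajectory.covariates.get("age_months", 0.0)
    rows = {
        "child_id": trajectory.child_id,
        "time_months": times,
        "state": [trajectory.state_at(t) for t in times],
    }
    df = pd.DataFrame(rows)
    for name, value in trajectory.covariates.items():
        df[name] = value
    if "age_months" in trajectory.covariates:
        df["age_months"] = base_age + times
    df["excluded"] = len(df) < 2
    return df


_ANTHRO_RECIPES = {
    # group -> (haz, whz, waz) as (mean, sd, lo, hi) truncated-normal specs.
    # A margin keeps draws strictly inside the strict cut-offs.
    "A": ((-0.5, 1.0, -2.0, 6.0), (-0.3, 0.6, -2.0, 1.0), (-0.8, 0.8, -2.0, 6.0)),
    "B": ((-0.5, 1.0, -2.0, 6.0), (-2.6, 0.5, -6.0, -2.0), (-1.2, 0.6, -2.0, 6.0)),
    "C": ((-0.5, 1.0, -2.0, 6.0), (-2.6, 0.5, -6.0, -2.0), (-2.7, 0.5, -6.0, -2.0)),
    "D": ((-2.8, 0.6, -6.0, -2.0), (-2.6, 0.5, -6.0, -2.0), (-2.9, 0.6, -6.0, -2.0)),
    "E": ((-2.8, 0.6, -6.0, -2.0), (-1.0, 0.5, -2.0, 1.0), (-2.7, 0.5, -6.0, -2.0)),
    "F": ((-2.8, 0.6, -6.0, -2.0), (-0.5, 0.6, -2.0, 1.0), (-1.2, 0.6, -2.0, 6.0)),
    "G": ((-2.6, 0.5, -6.0, -2.0), (1.6, 0.5, 1.0, 6.0), (-0.8, 0.7, -2.0, 6.0)),
    "H": ((-0.3, 0.9, -2.0, 6.0), (1.6, 0.5, 1.0, 6.0), (-0.3, 0.8, -2.0, 6.0)),
    "Y": ((-1.2, 0.5, -2.0, 6.0), (-1.3, 0.4, -2.0, 1.0), (-2.5, 0.4, -6.0, -2.0)),
}

# Relative weights of the groups inside each collapsed state: stunting-led
# failure dominates undernutrition in this population, and overweight-only
# outnumbers the stunted-overweight dual burden.
_STATE_GROUP_WEIGHTS = {
    1: (("B", 0.06), ("C", 0.06), ("D", 0.10), ("E", 0.28), ("F", 0.40), ("Y", 0.10)),
    2: (("A", 1.0),),
    3: (("G", 0.3), ("H", 0.7)),
}

_EDGE = 1e-6  # keep draws strictly inside strict cut-offs


def _tn(rng, mean, sd, lo, hi, size=None):
    lo, hi = lo + _EDGE, hi - _EDGE
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def synthesize_anthropometry(state: int, rng: np.random.Generator
                             ) -> tuple[float, float, float]:
    """Draw (haz, whz, waz) that classify back to the given collapsed state."""
    haz, whz, waz = synthesize_anthropometry_batch(np.array([state]), rng)
    return float(haz[0]), float(whz[0]), float(waz[0])


def synthesize_anthropometry_batch(states, rng: np.random.Generator):
    """Vectorised z-score synthesis: one (haz, whz, waz) triple per state."""
    states = np.asarray(states, dtype=int)
    if not np.isin(states, (1, 2, 3)).all():
        raise ValueError("states must be 1, 2 or 3")
    n = len(states)
    group_idx = np.empty(n, dtype=object)
    for s in (1, 2, 3):
        sel = np.flatnonzero(states == s)
        if len(sel) == 0:
            continue
        groups, weights = zip(*_STATE_GROUP_WEIGHTS[s])
        w = np.array(weights) / sum(weights)
        group_idx[sel] = np.array(groups)[rng.choice(len(groups), size=len(sel), p=w)]
    haz = np.empty(n)
    whz = np.empty(n)
    waz = np.empty(n)
    for group, specs in _ANTHRO_RECIPES.items():
        sel = np.flatnonzero(group_idx == group)
        if len(sel) == 0:
            continue
        for out, spec in zip((haz, whz, waz), specs):
            out[sel] = _tn(rng, *spec, size=len(sel))
    return haz, whz, waz


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a full synthetic panel plus the generating truth.

    Covariate effects follow the proportional-hazards form; the age
    covariate (when referenced by ``true_betas``) is updated at each
    observation time and held fixed over the interval that follows, matching
    the piecewise-constant intensity assumption of the fitted model.
    """
    rng = np.random.default_rng(config.seed)
    covs = sample_covariates(config, rng)
    q0 = config.Q0
    dist = np.asarray(config.initial_state_dist, dtype=float)
    uses_covariates = bool(config.true_betas)
    horizon_pad = 1.0  # simulate slightly past the last planned observation

    q0_arr = q0.matrix
    init_states = rng.choice(3, size=config.n_children, p=dist) + 1
    rows_id, rows_t, rows_state, rows_n = [], [], [], []
    cov_rows = []
    for row, init in zip(covs.itertuples(index=False), init_states):
        z = row._asdict()
        child_id = int(z.pop("child_id"))
        obs_times = observation_schedule(config, rng)
        if not uses_covariates:
            traj = simulate_trajectory(q0_arr, obs_times[-1] + horizon_pad,
                                       int(init), rng, child_id=child_id)
        else:
            segments = []
            state = int(init)
            bounds = list(obs_times) + [obs_times[-1] + horizon_pad]
            base_age = z["age_months"]
            for t_start, t_end in zip(bounds[:-1], bounds[1:]):
                z_t = dict(z)
                z_t["age_months"] = base_age + t_start
                q_z = intensity_with_covariates(q0, config.true_betas, z_t)
                seg = simulate_trajectory(q_z, t_end - t_start, state, rng,
                                          child_id=child_id, t0=t_start)
                state = int(seg.visited_states[-1])
                segments.append(seg)
            traj = _chain_segments(segments)

        # dropout on the realised schedule (baseline is always observed)
        n_obs = len(obs_times)
        for r in range(1, len(obs_times)):
            if rng.random() < config.dropout_prob_per_round:
                n_obs = r
                break
        times = obs_times[:n_obs]
        rows_id.extend([child_id] * n_obs)
        rows_t.extend(times)
        rows_state.extend(
            int(traj.visited_states[np.searchsorted(traj.jump_times, t, "right") - 1])
            for t in times
        )
        rows_n.extend([n_obs] * n_obs)
        cov_rows.extend([z] * n_obs)

    panel = pd.DataFrame({
        "child_id": rows_id,
        "time_months": rows_t,
        "state": rows_state,
    })
    cov_df = pd.DataFrame(cov_rows)
    panel = pd.concat([panel, cov_df.reset_index(drop=True)], axis=1)
    panel["age_months"] = cov_df["age_months"].to_numpy() + panel["time_months"]
    panel["excluded"] = np.asarray(rows_n) < 2
    haz, whz, waz = synthesize_anthropometry_batch(panel["state"].to_numpy(), rng)
    panel["haz"], panel["whz"], panel["waz"] = haz, whz, waz
    panel = panel[list(PANEL_COLUMNS)]
    truth = {
        "Q0": q0,
        "betas": dict(config.true_betas),
        "initial_state_dist": tuple(dist),
        "seed": config.seed,
    }
    return panel, truth


def write_cohort(panel: pd.DataFrame, truth: dict, config: CohortConfig,
                 csv_path, sidecar_path=None) -> None:
    """Write the panel as CSV plus a JSON sidecar with config and truth."""
    panel.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    sidecar = {
        "config": config.to_dict(),
        "truth": {
            "Q0": np.asarray(truth["Q0"]).tolist(),
            "betas": {f"{h}->{j}": dict(b) for (h, j), b in truth["betas"].items()},
            "initial_state_dist": list(truth["initial_state_dist"]),
            "seed": truth["seed"],
        },
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
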