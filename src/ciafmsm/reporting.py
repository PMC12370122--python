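"""Result surfaces: prevalence curves, occupancy summaries, trajectory data.

Observed prevalence on panel data is computed by last-observation-carried-
forward (each child contributes its most recent observed state, and is
censored after its final observation); the model-expected curve is the
initial state distribution pushed through expm(tQ).  Agreement between the
two is the informal goodness-of-fit check for the fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ctmc import (expected_prevalence, mean_sojourn, next_state_distribution,
                   total_length_of_stay, transition_probability)
from .inference import (MultiStateMarkovModel, prepare_panel,
                        transition_count_table)

__all__ = [
    "observed_prevalence",
    "prevalence_comparison",
    "occupancy_report",
    "trajectory_plot_data",
    "write_report",
    "plot_prevalence",
    "plot_trajectories",
]


def observed_prevalence(panel: pd.DataFrame, grid) -> pd.DataFrame:
    """Observed prevalence (%) of each state over a time grid, by LOCF.

    At grid time t a child contributes its last observed state at or before
    t, and only while t does not exceed its final observation.  Grid points
    before every child's first observation are omitted.
    Returns a tidy frame (t, state, observed_pct, n_at_risk).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    df = panel.sort_values(["child_id", "time_months"], kind="mergesort")
    grid = np.asarray(grid, dtype=float)
    n_states = 3

    # per-child observation arrays
    times_by_child = df.groupby("child_id")["time_months"].apply(np.asarray)
    states_by_child = df.groupby("child_id")["state"].apply(np.asarray)
    first = times_by_child.apply(lambda a: a[0]).to_numpy()
    last = times_by_child.apply(lambda a: a[-1]).to_numpy()

    rows = []
    for t in grid:
        contributing = (first <= t) & (t <= last)
        if not contributing.any():
            continue
        counts = np.zeros(n_states)
        for times, states in zip(times_by_child[contributing],
                                 states_by_child[contributing]):
            idx = np.searchsorted(times, t, side="right") - 1
            counts[states[idx] - 1] += 1
        n = counts.sum()
        for s in range(n_states):
            rows.append({"t": t, "state": s + 1,
                         "observed_pct": 100.0 * counts[s] / n,
                         "n_at_risk": int(n)})
    return pd.DataFrame(rows)


@dataclass
class PrevalenceComparison:
    """Expected vs observed prevalence over a grid, tidy in ``table``."""

    table: pd.DataFrame

    def max_abs_gap(self) -> float:
        """Largest |expected - observed| in percentage points over the grid."""
        t = self.table.dropna(subset=["observed_pct", "expected_pct"])
        return float((t["expected_pct"] - t["observed_pct"]).abs().max())

    def to_csv(self, path) -> None:
        # fixed decimal formatting so files round-trip exactly through readers
        self.table.to_csv(path, index=False, float_format="%.6f")


def prevalence_comparison(fit: MultiStateMarkovModel, panel: pd.DataFrame,
                          grid=None, Z_eval: dict | None = None
                          ) -> PrevalenceComparison:
    """Model-expected vs observed prevalence.

    The expected curve starts from the empirical baseline (first-observation)
    state distribution and evolves under the fitted Q evaluated at ``Z_eval``
    (reference covariates by default); the observed curve is LOCF.
    """
    df = prepare_panel(panel, fit.model_.covariates, verbose=False)
    if grid is None:
        grid = np.arange(0.0, df["time_months"].max() + 1.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    baseline_states = df.groupby("child_id")["state"].first()
    initial = baseline_states.value_counts().reindex([1, 2, 3], fill_value=0)
    expected = expected_prevalence(fit.intensity_matrix(Z_eval),
                                   initial.to_numpy(float), grid)
    observed = observed_prevalence(df, grid)
    table = expected.merge(observed, on=["t", "state"], how="left")
    return PrevalenceComparison(table=table)


def occupancy_report(fit: MultiStateMarkovModel, Z_eval: dict | None = None,
                     horizons=(1.0, 36.0), window=(0.0, 36.0)) -> dict:
    """Transition probabilities at each horizon, mean sojourn times, total
    length of stay over the window, and next-state probabilities — the
    standard occupancy summary of a fitted multi-state model."""
    q = fit.intensity_matrix(Z_eval)
    labels = [f"state_{i}" for i in (1, 2, 3)]
    out = {
        "transition_probabilities": {
            f"t={h:g}": pd.DataFrame(transition_probability(q, h),
                                     index=labels, columns=labels)
            for h in horizons
        },
        "mean_sojourn": pd.Series(mean_sojourn(q), index=labels),
        "total_stay": pd.DataFrame(
            [total_length_of_stay(q, s, *window) for s in (1, 2, 3)],
            index=labels, columns=labels,
        ),
        "next_state": pd.DataFrame(next_state_distribution(q),
                                   index=labels, columns=labels),
        "window": tuple(window),
    }
    return out


def trajectory_plot_data(panel: pd.DataFrame, child_ids) -> dict:
    """Per-child (time, state) step series for spaghetti plots."""
    available = set(panel["child_id"].unique())
    missing = [c for c in child_ids if c not in available]
    if missing:
        raise KeyError(
            f"unknown child ids {missing}; {len(available)} ids available "
            f"(e.g. {sorted(available)[:5]})"
        )
    df = panel.sort_values(["child_id", "time_months"], kind="mergesort")
    return {
        cid: df[df["child_id"] == cid][["time_months", "state"]].reset_index(drop=True)
        for cid in child_ids
    }


def write_report(fit: MultiStateMarkovModel, panel: pd.DataFrame, out_dir,
                 Z_eval: dict | None = None) -> dict:
    """Write the full result surface as CSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    table = transition_count_table(panel)
    table.counts.to_csv(out / "state_table.csv")
    manifest["state_table"] = "state_table.csv"

    fit.intensity_table(Z_eval).to_csv(out / "intensities.csv", index=False)
    manifest["intensities"] = "intensities.csv"

    occ = occupancy_report(fit, Z_eval)
    occ_rows = []
    for key, p in occ["transition_probabilities"].items():
        for frm in p.index:
            for to in p.columns:
                occ_rows.append({"horizon": key, "from": frm, "to": to,
                                 "probability": round(p.loc[frm, to], 6)})
    pd.DataFrame(occ_rows).to_csv(out / "occupancy.csv", index=False)
    occ["next_state"].round(6).to_csv(out / "next_state.csv")
    manifest["occupancy"] = "occupancy.csv"
    manifest["next_state"] = "next_state.csv"

    hr = fit.hazard_ratio_table()
    if len(hr):
        hr.to_csv(out / "hazard_ratios.csv", index=False)
        manifest["hazard_ratios"] = "hazard_ratios.csv"

    comparison = prevalence_comparison(fit, panel, Z_eval=Z_eval)
    comparison.to_csv(out / "prevalence.csv")
    manifest["prevalence"] = "prevalence.csv"

    manifest["fit"] = "fit.json"
    (out / "fit.json").write_text(fit.to_json())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# optional matplotlib figures

def plot_prevalence(comparison: PrevalenceComparison, ax=None):
    """Expected (dotted) vs observed (solid) prevalence per state."""
    import matplotlib.pyplot as plt

    t = comparison.table
    if ax is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    else:
        axes = ax
    for s, a in zip((1, 2, 3), np.atleast_1d(axes)):
        sub = t[t["state"] == s]
        a.plot(sub["t"], sub["observed_pct"], "-", label="observed")
        a.plot(sub["t"], sub["expected_pct"], "r:", label="expected")
        a.set_title(f"state {s}")
        a.set_xlabel("months since baseline")
    np.atleast_1d(axes)[0].set_ylabel("prevalence (%)")
    np.atleast_1d(axes)[0].legend()
    return axes


def plot_trajectories(series: dict, ax=None):
    """Step plot of observed CIAF states for selected children."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    for cid, df in series.items():
        ax.step(df["time_months"], df["state"], where="post", label=f"child {cid}")
    ax.set_yticks([1, 2, 3])
    ax.set_yticklabels(["undernourished", "nourished", "overnourished"])
    ax.set_xlabel("months since baseline")
    ax.legend(fontsize="small")
    return ax
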