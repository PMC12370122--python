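"""Composite Index of Anthropometric Failure (CIAF) classification.

Maps WHO-standard z-scores (HAZ, WHZ, WAZ) to the four failure flags, the
nine revised-CIAF groups A-H,Y, and the collapsed three-level state used by
the multi-state model:

    1 = undernourished (groups B, C, D, E, F, Y)
    2 = nourished      (group A)
    3 = overnourished  (groups G, H)

Cut-offs are strict: stunted HAZ < -2, wasted WHZ < -2, underweight
WAZ < -2, overweight WHZ > +1; a z-score exactly at a cut-off is not a
failure.  Sixteen flag patterns are possible but only nine are CIAF groups;
the remaining seven (which include patterns a z-score triple can never
produce, e.g. wasted and overweight together) are rejected by default or,
under the ``"undernutrition-priority"`` policy, mapped to the nearest
undernutrition group by Hamming distance on the three undernutrition flags.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FailureFlags",
    "UnclassifiableRecordError",
    "IncompleteMeasurementError",
    "reconcile_measurements",
    "flags_from_zscores",
    "classify_group",
    "collapse_state",
    "classify_zscores",
    "classify_table",
    "prevalence_table",
    "CIAFClassifier",
    "STATE_NAMES",
]

STATE_NAMES = {1: "undernourished", 2: "nourished", 3: "overnourished"}

# (wasted, stunted, underweight, overweight) -> group
GROUP_PATTERNS = {
    (False, False, False, False): "A",
    (True, False, False, False): "B",
    (True, False, True, False): "C",
    (True, True, True, False): "D",
    (False, True, True, False): "E",
    (False, True, False, False): "F",
    (False, True, False, True): "G",
    (False, False, False, True): "H",
    (False, False, True, False): "Y",
}

GROUP_TO_STATE = {"A": 2, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 3, "H": 3, "Y": 1}

# undernutrition groups keyed by their (wasted, stunted, underweight) pattern
_UNDER_PATTERNS = {
    (True, False, False): "B",
    (True, False, True): "C",
    (True, True, True): "D",
    (False, True, True): "E",
    (False, True, False): "F",
    (False, False, True): "Y",
}


class UnclassifiableRecordError(ValueError):
    """Flag combination outside the nine CIAF groups under the default policy."""


class IncompleteMeasurementError(ValueError):
    """Two discordant measurements without the required third."""


@dataclass(frozen=True)
class FailureFlags:
    wasted: bool
    stunted: bool
    underweight: bool
    overweight: bool

    def __post_init__(self):
        if self.wasted and self.overweight:
            raise ValueError(
                "wasted (WHZ < -2) and overweight (WHZ > +1) cannot co-occur"
            )

    def as_tuple(self):
        return (self.wasted, self.stunted, self.underweight, self.overweight)


def reconcile_measurements(first: float, second: float, third: float | None = None,
                           tol: float = 0.01) -> float:
    """Combine repeated anthropometric measurements into one accepted value.

    Two measurements closer than ``tol`` (0.01 cm for length, 0.01 kg for
    weight) are averaged; otherwise a third is required and the median of
    the three is returned.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if abs(first - second) < tol:
        return (first + second) / 2.0
    if third is None:
        raise IncompleteMeasurementError(
            f"measurements {first} and {second} differ by >= {tol}; "
            "a third measurement is required"
        )
    return float(np.median([first, second, third]))


def flags_from_zscores(haz: float, whz: float, waz: float) -> FailureFlags:
    """Anthropometric failure flags from the three z-scores (strict cut-offs)."""
    if not all(np.isfinite([haz, whz, waz])):
        raise ValueError(f"z-scores must be finite, got haz={haz}, whz={whz}, waz={waz}")
    return FailureFlags(
        wasted=whz < -2,
        stunted=haz < -2,
        underweight=waz < -2,
        overweight=whz > 1,
    )


def classify_group(flags: FailureFlags, policy: str = "error") -> str:
    """CIAF group A-H,Y for a flag pattern.

    ``policy="error"`` raises :class:`UnclassifiableRecordError` for the seven
    flag patterns outside the nine groups; ``policy="undernutrition-priority"``
    maps any such pattern (all of which carry at least one undernutrition
    flag) to the nearest undernutrition group and logs a warning.
    """
    key = flags.as_tuple() if isinstance(flags, FailureFlags) else tuple(map(bool, flags))
    if key in GROUP_PATTERNS:
        return GROUP_PATTERNS[key]
    if policy == "error":
        raise UnclassifiableRecordError(
            f"flag pattern (wasted={key[0]}, stunted={key[1]}, "
            f"underweight={key[2]}, overweight={key[3]}) is not a CIAF group"
        )
    if policy != "undernutrition-priority":
        raise ValueError(f"unknown policy {policy!r}")
    under = key[:3]
    if not any(under):
        raise UnclassifiableRecordError(
            f"pattern {key} has no undernutrition flag to prioritise"
        )
    group = _nearest_undernutrition_group(under)
    logger.warning("flag pattern %s outside the nine CIAF groups mapped to %s", key, group)
    return group


def _nearest_undernutrition_group(under: tuple) -> str:
    # minimal Hamming distance on (wasted, stunted, underweight); ties broken
    # toward the group with more failures (the more severe classification)
    best = min(
        _UNDER_PATTERNS,
        key=lambda pat: (sum(a != b for a, b in zip(pat, under)), -sum(pat)),
    )
    return _UNDER_PATTERNS[best]


def collapse_state(group: str) -> int:
    """Collapse a CIAF group to the 3-level state (1 under / 2 nourished / 3 over)."""
    try:
        return GROUP_TO_STATE[group]
    except KeyError:
        raise ValueError(f"unknown CIAF group {group!r}") from None


def classify_zscores(haz: float, whz: float, waz: float,
                     policy: str = "error") -> tuple[str, int]:
    """(group, state) straight from the three z-scores."""
    group = classify_group(flags_from_zscores(haz, whz, waz), policy=policy)
    return group, collapse_state(group)


def classify_table(records: pd.DataFrame, policy: str = "error") -> pd.DataFrame:
    """Add ``group`` and ``state`` columns to a frame with haz/whz/waz columns."""
    for col in ("haz", "whz", "waz"):
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
        if not np.all(np.isfinite(records[col].to_numpy(float))):
            raise ValueError(f"column {col!r} contains non-finite z-scores")
    out = records.copy()
    pairs = [
        classify_zscores(h, w, a, policy=policy)
        for h, w, a in zip(out["haz"], out["whz"], out["waz"])
    ]
    out["group"] = [g for g, _ in pairs]
    out["state"] = [s for _, s in pairs]
    return out


def _round_half_up(x, decimals=1):
    factor = 10.0 ** decimals
    return np.floor(np.asarray(x, float) * factor + 0.5) / factor


def prevalence_table(classified: pd.DataFrame, by: str = "round") -> pd.DataFrame:
    """Round-wise state counts and percentages (half-up, 1 decimal).

    Input needs ``state`` and a grouping column (survey round).  Output is a
    tidy frame with columns round, state, count, pct.
    """
    rows = []
    for rnd, grp in classified.groupby(by, sort=True):
        counts = grp["state"].value_counts().reindex([1, 2, 3], fill_value=0)
        total = counts.sum()
        for state, count in counts.items():
            rows.append(
                {
                    by: rnd,
                    "state": state,
                    "count": int(count),
                    "pct": float(_round_half_up(100.0 * count / total)) if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


class CIAFClassifier:
    """Stateless transformer mapping z-score records to CIAF states.

    Plays the sklearn transformer role so the classification step can sit in
    a pipeline; ``fit`` only validates.

    Parameters
    ----------
    policy : {"error", "undernutrition-priority"}
        Handling of flag patterns outside the nine CIAF groups.
    """

    def __init__(self, policy: str = "error"):
        self.policy = policy

    def get_params(self, deep=True):
        return {"policy": self.policy}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        if self.policy not in ("error", "undernutrition-priority"):
            raise ValueError(f"unknown policy {self.policy!r}")
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        """Return the state codes for a (n, 3) array or haz/whz/waz frame."""
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        if isinstance(X, pd.DataFrame):
            Z = X[["haz", "whz", "waz"]].to_numpy(float)
        else:
            Z = np.asarray(X, dtype=float)
            if Z.ndim != 2 or Z.shape[1] != 3:
                raise ValueError("expected an (n, 3) array of (haz, whz, waz)")
        return np.array(
            [classify_zscores(h, w, a, policy=self.policy)[1] for h, w, a in Z]
        )

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
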