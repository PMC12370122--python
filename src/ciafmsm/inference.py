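"""Maximum-likelihood estimation of the multi-state model from panel data.

The process is observed only at survey times (interval censoring), so each
consecutive pair of observations on a child contributes a matrix-exponential
transition probability to the likelihood,

    L = prod_i prod_r [expm((t_{r+1} - t_r) Q(Z_{i,r}))]_{s_r, s_{r+1}},

with proportional-hazards covariate effects q_hj(Z) = exp(theta_hj +
beta_hj' Z) on the allowed transitions.  Estimation is quasi-Newton on the
unconstrained scale (theta = log q, raw beta); standard errors come from
the inverse observed information.

The fit is exposed as :class:`MultiStateMarkovModel`, a scikit-learn-style
estimator (``fit`` on a long-format panel frame, fitted attributes with a
trailing underscore, ``get_params``/``set_params``); the module-level
functions are thin wrappers kept for script use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

from .ctmc import FULL_MASK_3, IntensityMatrix, build_intensity_matrix

__all__ = [
    "TransitionModel",
    "MultiStateMarkovModel",
    "StateTable",
    "transition_count_table",
    "apply_covariates",
    "panel_loglikelihood",
    "fit_msm",
    "bootstrap_derived",
    "prepare_panel",
]

_Z975 = 1.959963984540054  # standard-normal 97.5% quantile


# ---------------------------------------------------------------------------
# model specification

@dataclass
class TransitionModel:
    """Specification (and, once populated, parameter values) of the model.

    Parameters
    ----------
    mask
        Boolean allowed-transition matrix; defaults to all six off-diagonal
        transitions of the 3-state process.
    covariates
        Names of the covariate columns entering the proportional-hazards
        term.
    covariate_map
        Optional per-transition restriction ``{(h, j): (names...)}``.  When
        given it is complete: an allowed transition absent from the map gets
        no covariates.  When omitted every transition gets ``covariates``.
    center
        Centre covariates at their sample means before fitting (the fitted
        baseline then refers to an average child rather than the reference
        one).
    theta, beta
        Log baseline intensities ``{(h, j): value}`` and coefficient dicts
        ``{(h, j): {name: value}}``.  Left empty for a model to be fitted;
        populated on a fitted specification.
    """

    mask: np.ndarray = None  # type: ignore[assignment]
    covariates: tuple = ()
    covariate_map: dict | None = None
    center: bool = False
    theta: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    covariate_means: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mask is None:
            self.mask = FULL_MASK_3.copy()
        self.mask = np.asarray(self.mask, dtype=bool)
        np.fill_diagonal(self.mask, False)
        self.covariates = tuple(self.covariates)

    @property
    def n_states(self) -> int:
        return self.mask.shape[0]

    @property
    def transitions(self) -> list:
        """Allowed transitions as 1-based (h, j) pairs in row-major order."""
        return [
            (h + 1, j + 1)
            for h in range(self.n_states)
            for j in range(self.n_states)
            if self.mask[h, j]
        ]

    def covariates_for(self, transition) -> tuple:
        if self.covariate_map is not None:
            return tuple(self.covariate_map.get(transition, ()))
        return self.covariates

    @property
    def df(self) -> int:
        """Free-parameter count: one baseline per transition plus its betas."""
        return sum(1 + len(self.covariates_for(tr)) for tr in self.transitions)


def apply_covariates(model: TransitionModel, Z: dict | None = None) -> IntensityMatrix:
    """Intensity matrix q_hj(Z) = exp(theta_hj + beta_hj' Z) for one child.

    ``Z`` defaults to the reference covariate vector (all zeros); on a
    centred model values are shifted by the stored sample means.
    """
    if not model.theta:
        raise ValueError("model has no parameter values; fit it first")
    Z = dict(Z or {})
    rates = {}
    for tr in model.transitions:
        lin = model.theta[tr]
        for name in model.covariates_for(tr):
            if name not in Z and name not in model.covariate_means:
                raise ValueError(f"missing covariate {name!r} in evaluation vector")
            z = Z.get(name, 0.0)
            if model.center:
                z -= model.covariate_means.get(name, 0.0)
            lin += model.beta.get(tr, {}).get(name, 0.0) * z
        rates[tr] = np.exp(lin)
    return build_intensity_matrix(rates, mask=model.mask)


# ---------------------------------------------------------------------------
# panel handling

REQUIRED_COLUMNS = ("child_id", "time_months", "state")


def prepare_panel(panel: pd.DataFrame, covariates=(), n_states: int = 3,
                  verbose: bool = True) -> pd.DataFrame:
    """Validate and clean a long-format panel.

    Sorts by child and time, checks states and strictly increasing times,
    and drops children with fewer than two observations (they carry no
    transition information), logging how many were dropped.
    """
    for col in (*REQUIRED_COLUMNS, *covariates):
        if col not in panel.columns:
            raise ValueError(f"panel is missing required column {col!r}")
    df = panel.sort_values(["child_id", "time_months"], kind="mergesort").copy()
    states = df["state"].to_numpy()
    if not np.isin(states, np.arange(1, n_states + 1)).all():
        bad = sorted(set(states) - set(range(1, n_states + 1)))
        raise ValueError(f"states outside 1..{n_states}: {bad}")
    sizes = df.groupby("child_id")["time_months"].agg(["count", lambda s: s.is_monotonic_increasing and s.is_unique])
    if not sizes.iloc[:, 1].all():
        bad = sizes.index[~sizes.iloc[:, 1]].tolist()[:5]
        raise ValueError(f"observation times not strictly increasing for children {bad}")
    keep = sizes.index[sizes["count"] >= 2]
    n_dropped = sizes.shape[0] - len(keep)
    if n_dropped and verbose:
        warnings.warn(f"dropped {n_dropped} children with a single observation")
    return df[df["child_id"].isin(keep)].reset_index(drop=True)


@dataclass
class StateTable:
    """Frequency-of-transition table over consecutive observation pairs."""

    counts: pd.DataFrame  # from-state rows, to-state columns plus 'total'
    pct: pd.DataFrame     # row percentages, 2 decimals
    n_pairs: int


def transition_count_table(panel: pd.DataFrame, n_states: int = 3) -> StateTable:
    """Cross-tabulate consecutive observed state pairs pooled over children."""
    labels = list(range(1, n_states + 1))
    if len(panel) == 0:
        counts = pd.DataFrame(0, index=labels, columns=labels)
    else:
        df = panel.sort_values(["child_id", "time_months"], kind="mergesort")
        same = df["child_id"].to_numpy()[1:] == df["child_id"].to_numpy()[:-1]
        frm = df["state"].to_numpy()[:-1][same]
        to = df["state"].to_numpy()[1:][same]
        counts = (
            pd.crosstab(pd.Series(frm, name="from"), pd.Series(to, name="to"))
            .reindex(index=labels, columns=labels, fill_value=0)
        )
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, np.nan), axis=0).mul(100).round(2)
    counts = counts.copy()
    counts["total"] = totals
    return StateTable(counts=counts, pct=pct, n_pairs=int(totals.sum()))


# ---------------------------------------------------------------------------
# likelihood core

class _PairData:
    """Consecutive-pair arrays extracted once from a panel."""

    def __init__(self, panel: pd.DataFrame, spec: TransitionModel):
        df = panel
        child = df["child_id"].to_numpy()
        same = child[1:] == child[:-1]
        t = df["time_months"].to_numpy(float)
        s = df["state"].to_numpy(int)
        self.dt = (t[1:] - t[:-1])[same]
        self.frm = (s[:-1] - 1)[same]
        self.to = (s[1:] - 1)[same]
        self.child = child[:-1][same]
        names = sorted({n for tr in spec.transitions for n in spec.covariates_for(tr)})
        self.cov_names = names
        if names:
            Z = df[list(names)].to_numpy(float)[:-1][same]
            if spec.center:
                means = {n: float(df[n].mean()) for n in names}
                spec.covariate_means.update(means)
                Z = Z - np.array([means[n] for n in names])
            self.z_unique, self.z_inverse = np.unique(Z, axis=0, return_inverse=True)
        else:
            self.z_unique = np.zeros((1, 0))
            self.z_inverse = np.zeros(len(self.dt), dtype=int)
        self.n_pairs = len(self.dt)

        # structural zeros: pairs whose transition is impossible under the mask
        reach = _reachability(spec.mask)
        bad = ~reach[self.frm, self.to]
        self.impossible_pairs = [
            (int(c), int(f) + 1, int(g) + 1)
            for c, f, g in zip(self.child[bad], self.frm[bad], self.to[bad])
        ]


def _reachability(mask: np.ndarray) -> np.ndarray:
    n = mask.shape[0]
    reach = mask | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    return reach


def _pack_spec(spec: TransitionModel):
    """Index bookkeeping: parameter vector = thetas then betas per transition."""
    transitions = spec.transitions
    names = []
    slices = {}
    pos = len(transitions)
    for k, tr in enumerate(transitions):
        names.append(f"theta_{tr[0]}{tr[1]}")
        covs = spec.covariates_for(tr)
        slices[tr] = (k, pos, covs)
        for c in covs:
            names.append(f"beta_{tr[0]}{tr[1]}_{c}")
        pos += len(covs)
    return transitions, slices, names, pos


def _log_q_matrix(params, spec, slices, cov_names, z_unique):
    """Per-unique-covariate-row intensity matrices, shape (m, n, n)."""
    n = spec.n_states
    m = z_unique.shape[0]
    q = np.zeros((m, n, n))
    col = {c: i for i, c in enumerate(cov_names)}
    for tr, (k, pos, covs) in slices.items():
        lin = np.full(m, params[k])
        for i, c in enumerate(covs):
            lin = lin + params[pos + i] * z_unique[:, col[c]]
        q[:, tr[0] - 1, tr[1] - 1] = np.exp(np.clip(lin, -500, 50))
    diag = -q.sum(axis=2)
    idx = np.arange(n)
    q[:, idx, idx] = diag[:, idx]
    return q


def _interval_probabilities(q: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """P(dt) = expm(dt Q) for one Q and many interval lengths.

    Eigendecomposition fast path with automatic fallback to
    scaling-and-squaring when the eigenvectors are ill-conditioned or the
    reconstruction drifts from row-stochastic.
    """
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        e = np.exp(np.multiply.outer(dts, w))
        p = np.einsum("ij,tj,jk->tik", v, e, vinv).real
        if np.abs(p.sum(axis=2) - 1.0).max() < 1e-8 and p.min() > -1e-10:
            return np.clip(p, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    return np.clip(expm(dts[:, None, None] * q), 0.0, 1.0)


def _loglik_core(params, data: _PairData, spec, slices) -> float:
    q = _log_q_matrix(params, spec, slices, data.cov_names, data.z_unique)
    p_obs = np.empty(data.n_pairs)
    for u in range(q.shape[0]):
        sel = data.z_inverse == u
        p = _interval_probabilities(q[u], data.dt[sel])
        p_obs[sel] = p[np.arange(sel.sum()), data.frm[sel], data.to[sel]]
    return float(np.log(np.maximum(p_obs, 1e-300)).sum())


def panel_loglikelihood(model: TransitionModel, panel: pd.DataFrame) -> float:
    """Log-likelihood of a parameterised model on a panel.

    Returns ``-inf`` (with a diagnostic naming an offending pair) when an
    observed transition is structurally impossible under the mask.
    """
    df = prepare_panel(panel, model.covariates, model.n_states, verbose=False)
    data = _PairData(df, model)
    if data.impossible_pairs:
        c, h, j = data.impossible_pairs[0]
        warnings.warn(
            f"observed transition {h}->{j} (child {c}) is impossible under the "
            f"mask; log-likelihood is -inf"
        )
        return -np.inf
    transitions, slices, _, n_par = _pack_spec(model)
    params = np.empty(n_par)
    for tr, (k, pos, covs) in slices.items():
        params[k] = model.theta[tr]
        for i, c in enumerate(covs):
            params[pos + i] = model.beta.get(tr, {}).get(c, 0.0)
    return _loglik_core(params, data, model, slices)


# ---------------------------------------------------------------------------
# the estimator

class MultiStateMarkovModel:
    """Continuous-time Markov multi-state model for interval-censored panels.

    Parameters
    ----------
    mask : (n, n) bool array, optional
        Allowed transitions; defaults to all six off-diagonals of the
        3-state CIAF process.
    covariates : sequence of str
        Covariate columns entering every allowed transition (unless
        restricted by ``covariate_map``).
    covariate_map : dict, optional
        ``{(h, j): (names...)}`` restriction of covariates per transition.
    center : bool
        Centre covariates at their sample means.
    max_iter, gtol, ftol
        Quasi-Newton (L-BFGS-B) stopping controls.

    Attributes (after ``fit``)
    --------------------------
    params_, param_names_ : packed estimates (thetas then betas).
    theta_, beta_ : the same keyed by transition.
    covariance_ : inverse observed information (packed order).
    loglik_, minus2ll_, aic_, df_ : fit statistics, AIC = -2LL + 2 df.
    converged_, n_iter_ : optimizer diagnostics.
    """

    def __init__(self, mask=None, covariates=(), covariate_map=None,
                 center=False, max_iter=500, gtol=1e-6, ftol=1e-10):
        self.mask = mask
        self.covariates = covariates
        self.covariate_map = covariate_map
        self.center = center
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep=True):
        return {
            "mask": self.mask,
            "covariates": self.covariates,
            "covariate_map": self.covariate_map,
            "center": self.center,
            "max_iter": self.max_iter,
            "gtol": self.gtol,
            "ftol": self.ftol,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _spec(self) -> TransitionModel:
        return TransitionModel(
            mask=None if self.mask is None else np.asarray(self.mask, bool),
            covariates=tuple(self.covariates),
            covariate_map=self.covariate_map,
            center=self.center,
        )

    # -- fitting ------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None, init_params=None):
        """Fit by maximum likelihood on a long-format panel frame.

        ``X`` needs columns child_id, time_months, state plus the covariate
        columns; ``y`` is ignored (present for sklearn compatibility).
        """
        spec = self._spec()
        df = prepare_panel(X, spec.covariates, spec.n_states)
        n_children_in = X["child_id"].nunique()
        self.n_children_ = df["child_id"].nunique()
        self.n_dropped_children_ = n_children_in - self.n_children_
        data = _PairData(df, spec)
        if data.impossible_pairs:
            c, h, j = data.impossible_pairs[0]
            raise ValueError(
                f"panel contains transition {h}->{j} (child {c}) that is "
                "impossible under the mask"
            )
        transitions, slices, names, n_par = _pack_spec(spec)
        observed = set(zip(data.frm + 1, data.to + 1))
        for tr in transitions:
            if tr not in observed:
                warnings.warn(f"allowed transition {tr[0]}->{tr[1]} never observed")

        crude = self._crude_init(data, spec, slices, n_par)
        x0 = crude if init_params is None else np.asarray(init_params, float)
        neg = lambda p: -_loglik_core(p, data, spec, slices)
        opts = {"maxiter": self.max_iter, "ftol": self.ftol, "gtol": self.gtol}
        res = minimize(neg, x0, method="L-BFGS-B", options=opts)
        if not res.success and "ABNORMAL" in str(res.message) \
                and init_params is not None:
            # noisy finite-difference line search from a warm start; restart cold
            res = minimize(neg, crude, method="L-BFGS-B", options=opts)
        if not res.success and "ABNORMAL" in str(res.message):
            raise RuntimeError(f"optimizer failed: {res.message}")

        self.params_ = res.x
        self.param_names_ = names
        self.transitions_ = transitions
        self.n_pairs_ = data.n_pairs
        self.loglik_ = -res.fun
        self.minus2ll_ = 2 * res.fun
        self.df_ = spec.df
        self.aic_ = self.minus2ll_ + 2 * self.df_
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.optimizer_message_ = str(res.message)

        self.covariance_, self.covariance_ok_ = self._covariance(neg, res.x)

        spec.theta = {tr: float(res.x[slices[tr][0]]) for tr in transitions}
        spec.beta = {
            tr: {c: float(res.x[slices[tr][1] + i]) for i, c in enumerate(slices[tr][2])}
            for tr in transitions
        }
        self.model_ = spec
        self.theta_ = spec.theta
        self.beta_ = spec.beta
        self._slices = slices
        return self

    @staticmethod
    def _crude_init(data, spec, slices, n_par):
        """Crude-rate initialisation: transitions observed / time at risk."""
        n = spec.n_states
        counts = np.zeros((n, n))
        np.add.at(counts, (data.frm, data.to), 1.0)
        time_at = np.zeros(n)
        np.add.at(time_at, data.frm, data.dt)
        x0 = np.zeros(n_par)
        for tr, (k, _, _) in slices.items():
            t_h = max(time_at[tr[0] - 1], 1e-8)
            rate = max(counts[tr[0] - 1, tr[1] - 1], 0.5) / t_h
            x0[k] = np.log(rate)
        return x0

    def _covariance(self, neg, x):
        try:
            hess = approx_hess(x, neg)
            cov = np.linalg.inv(hess)
            cov = (cov + cov.T) / 2
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            return cov, True
        except np.linalg.LinAlgError:
            warnings.warn("observed information is singular; CIs unavailable")
            return np.full((len(x), len(x)), np.nan), False

    # -- derived surfaces ---------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("model is not fitted yet; call fit first")

    def intensity_matrix(self, Z: dict | None = None) -> IntensityMatrix:
        """Fitted Q evaluated at a covariate vector (reference by default)."""
        self._check_fitted()
        return apply_covariates(self.model_, Z)

    def loglik(self, X: pd.DataFrame) -> float:
        self._check_fitted()
        return panel_loglikelihood(self.model_, X)

    def _lin_var(self, tr, Z) -> tuple[float, float]:
        """Point and variance of log q_hj(Z) by the delta method (exact: the
        log-intensity is linear in the parameters)."""
        k, pos, covs = self._slices[tr]
        grad = np.zeros(len(self.params_))
        grad[k] = 1.0
        val = self.params_[k]
        for i, c in enumerate(covs):
            z = Z.get(c, 0.0)
            if self.model_.center:
                z -= self.model_.covariate_means.get(c, 0.0)
            grad[pos + i] = z
            val += self.params_[pos + i] * z
        var = float(grad @ self.covariance_ @ grad)
        return float(val), var

    def intensity_table(self, Z: dict | None = None) -> pd.DataFrame:
        """Transition intensities at ``Z`` with 95% CIs (log-scale delta method,
        exponentiated, so the bounds are always positive)."""
        self._check_fitted()
        Z = dict(Z or {})
        rows = []
        for tr in self.transitions_:
            log_q, var = self._lin_var(tr, Z)
            se = np.sqrt(var) if self.covariance_ok_ else np.nan
            rows.append({
                "from": tr[0], "to": tr[1],
                "estimate": np.exp(log_q),
                "lower": np.exp(log_q - _Z975 * se),
                "upper": np.exp(log_q + _Z975 * se),
            })
        return pd.DataFrame(rows)

    def hazard_ratio_table(self) -> pd.DataFrame:
        """exp(beta) with 95% Wald CIs per covariate and transition."""
        self._check_fitted()
        rows = []
        for tr in self.transitions_:
            k, pos, covs = self._slices[tr]
            for i, c in enumerate(covs):
                b = self.params_[pos + i]
                se = (np.sqrt(self.covariance_[pos + i, pos + i])
                      if self.covariance_ok_ else np.nan)
                rows.append({
                    "from": tr[0], "to": tr[1], "covariate": c,
                    "hr": np.exp(b),
                    "lower": np.exp(b - _Z975 * se),
                    "upper": np.exp(b + _Z975 * se),
                })
        return pd.DataFrame(rows)

    def transition_probability(self, t: float, Z: dict | None = None) -> np.ndarray:
        from .ctmc import transition_probability
        return transition_probability(self.intensity_matrix(Z), t)

    def to_json(self) -> str:
        """Serialise the fit with stable key order for diffing."""
        self._check_fitted()
        obj = {
            "aic": self.aic_,
            "converged": self.converged_,
            "covariance": self.covariance_.tolist(),
            "df": self.df_,
            "minus2ll": self.minus2ll_,
            "n_children": int(self.n_children_),
            "n_iter": self.n_iter_,
            "n_pairs": int(self.n_pairs_),
            "param_names": list(self.param_names_),
            "params": self.params_.tolist(),
        }
        return json.dumps(obj, indent=2, sort_keys=True)


def fit_msm(panel: pd.DataFrame, model: TransitionModel | None = None,
            **options) -> MultiStateMarkovModel:
    """Functional wrapper: fit a (possibly covariate) multi-state model."""
    spec = model or TransitionModel()
    est = MultiStateMarkovModel(
        mask=spec.mask, covariates=spec.covariates,
        covariate_map=spec.covariate_map, center=spec.center, **options,
    )
    return est.fit(panel)


# ---------------------------------------------------------------------------
# bootstrap

_STATISTICS = {
    "next_state": lambda q, kw: _ns(q),
    "sojourn": lambda q, kw: _ms(q),
    "total_stay": lambda q, kw: _tls(q, kw),
    "transition_probability": lambda q, kw: _tp(q, kw),
}


def _ns(q):
    from .ctmc import next_state_distribution
    return next_state_distribution(q)


def _ms(q):
    from .ctmc import mean_sojourn
    return mean_sojourn(q)


def _tls(q, kw):
    from .ctmc import total_length_of_stay
    return total_length_of_stay(q, kw.get("start_state", 1),
                                kw.get("t1", 0.0), kw.get("t2", 36.0))


def _tp(q, kw):
    from .ctmc import transition_probability
    return transition_probability(q, kw.get("t", 36.0))


def bootstrap_derived(fit: MultiStateMarkovModel, panel: pd.DataFrame,
                      statistic, B: int = 1000, seed: int | None = None,
                      Z_eval: dict | None = None, max_fail_frac: float = 0.2,
                      **stat_kwargs) -> dict:
    """Nonparametric bootstrap CIs for derived quantities.

    Children are resampled with replacement, the model refit (initialised at
    the original estimates), and the statistic recomputed; the 2.5/97.5
    percentiles over replicates form the interval.  ``statistic`` is one of
    'next_state', 'sojourn', 'total_stay', 'transition_probability' or a
    callable mapping an intensity matrix to an array.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    stat_fn = statistic if callable(statistic) else _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    df = prepare_panel(panel, fit.model_.covariates, verbose=False)
    ids = df["child_id"].unique()
    groups = {i: g for i, g in df.groupby("child_id")}

    point = stat_fn(fit.intensity_matrix(Z_eval), stat_kwargs)
    reps, failures = [], 0
    for _ in range(B):
        draw = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for new_id, cid in enumerate(draw):
            g = groups[cid].copy()
            g["child_id"] = new_id
            frames.append(g)
        resample = pd.concat(frames, ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = MultiStateMarkovModel(**fit.get_params()).fit(
                    resample, init_params=fit.params_)
            reps.append(stat_fn(refit.intensity_matrix(Z_eval), stat_kwargs))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
        if failures > max_fail_frac * B:
            raise RuntimeError(
                f"{failures} of {B} bootstrap refits failed; aborting"
            )
    reps = np.asarray(reps)
    return {
        "point": np.asarray(point),
        "lower": np.nanpercentile(reps, 2.5, axis=0),
        "upper": np.nanpercentile(reps, 97.5, axis=0),
        "n_success": len(reps),
        "replicates": reps,
    }
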