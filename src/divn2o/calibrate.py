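"""Surrogate (Gaussian-process) Bayesian-optimization calibration.

Calibrates the six maximum oxidation/reduction rates of the process model
against flux observations by minimizing the RMSE of predicted monthly
fluxes.  The optimizer is a sequential model-based loop: a GP surrogate
(Matern 5/2 + white noise, fitted in a normalized box, K_max on a log
scale) proposes points by expected improvement, switching to posterior-mean
exploitation with a shrinking local search radius over the final
``n_average`` iterations so that the returned parameter vector — the mean
of the final ``n_average`` proposals — is a converged point estimate
rather than an exploration average.  Observations are split 70/30 into
training and validation sets; accuracy is reported as R-squared and RMSE
on the held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .micn import (
    KMAX_NAMES,
    DiversityFactor,
    MicNParams,
    SiteForcing,
    simulate_site,
)

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "OptimizationResult",
    "DEFAULT_KMAX_BOUNDS",
    "rmse_loss",
    "train_valid_split",
    "bayes_optimize",
    "calibrate_kmax",
    "calibrate_per_richness",
    "validate_model",
]

#: A-priori box for the six K_max (g N m-2 month-1): roughly an order of
#: magnitude either side of plausible forest-topsoil turnover rates.
DEFAULT_KMAX_BOUNDS = {name: (0.02, 1.5) for name in KMAX_NAMES}


@dataclass
class CalibrationSpec:
    """Budget and search-space definition for a calibration run."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_KMAX_BOUNDS)
    )
    n_iterations: int = 1000
    n_average: int = 100
    n_initial: int = 20
    seed: int = 0
    train_fraction: float = 0.70
    log_scale: bool = True
    average_best: bool = False  # average the n_average best instead of final

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"bounds for {name} not ordered: ({lo}, {hi})")
            if self.log_scale and lo <= 0:
                raise ValueError(f"log-scale bounds for {name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_average > self.n_iterations:
            raise ValueError("n_average cannot exceed n_iterations")
        if self.n_initial < 2:
            raise ValueError("n_initial must be >= 2")


@dataclass
class OptimizationResult:
    """Raw optimizer output in original parameter units."""

    x: np.ndarray  # returned estimate (averaged proposals)
    x_best: np.ndarray  # best single evaluation
    f_best: float
    objective_trace: np.ndarray  # objective value per iteration
    proposals: np.ndarray  # all evaluated points, (n_iterations, d)
    param_names: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.x))


@dataclass
class CalibrationResult:
    """Calibrated parameters plus held-out accuracy."""

    params: MicNParams
    objective_trace: np.ndarray
    validation_r2: float
    validation_rmse: float
    split_ids: dict[str, np.ndarray]
    optimization: OptimizationResult | None = None


def rmse_loss(predicted, observed) -> float:
    """Root mean squared error between equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def train_valid_split(
    observations: pd.DataFrame, spec: CalibrationSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random 70/30 (by default) partition of observation rows."""
    n = len(observations)
    if n < 4:
        raise ValueError("need >= 4 observations to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    idx = observations.index.to_numpy()
    train_ids, valid_ids = idx[perm[:n_train]], idx[perm[n_train:]]
    return observations.loc[train_ids], observations.loc[valid_ids]


def _expected_improvement(mu, sigma, y_best, xi=0.01):
    sigma = np.maximum(sigma, 1e-12)
    z = (y_best - mu - xi) / sigma
    return (y_best - mu - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayes_optimize(
    objective, spec: CalibrationSpec, residuals=None, extra_starts=None
) -> OptimizationResult:
    """Minimize ``objective`` over the spec's box with a GP surrogate.

    ``objective`` takes a dict of parameter values and returns a scalar
    loss; non-finite returns are penalized, never raised.  The loop spends
    ``n_initial`` Latin-hypercube evaluations seeding the surrogate, then
    proposes by expected improvement (GP fitted to the log-loss), and
    spends the final ``n_average`` evaluations refining the incumbent —
    damped least squares when a ``residuals`` callable (dict -> residual
    vector, RMSE consistent with ``objective``) is supplied, otherwise
    Nelder-Mead — so that the returned estimate, the mean of the final
    ``n_average`` proposals (of the ``n_average`` best with
    ``average_best``), is a converged point rather than an exploration
    average.  ``extra_starts`` (dicts of parameter values) are evaluated
    with the seeding points and tried first in the refinement phase —
    useful to warm-start from a related fit.  Deterministic given
    ``spec.seed``.
    """
    names = tuple(spec.bounds)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    d = len(names)
    rng = np.random.default_rng(spec.seed)

    if spec.log_scale:
        t_lo, t_hi = np.log(lo), np.log(hi)
        to_x = lambda u: np.exp(t_lo + u * (t_hi - t_lo))
        to_u = lambda x: (np.log(np.clip(x, lo, hi)) - t_lo) / (t_hi - t_lo)
    else:
        t_lo, t_hi = lo, hi
        to_x = lambda u: t_lo + u * (t_hi - t_lo)
        to_u = lambda x: (np.clip(x, lo, hi) - t_lo) / (t_hi - t_lo)

    def evaluate(u):
        val = objective(dict(zip(names, to_x(np.clip(u, 0.0, 1.0)))))
        return float(val)

    # Latin-hypercube seeding
    n_init = min(spec.n_initial, spec.n_iterations)
    lhs = (rng.permuted(np.tile(np.arange(n_init), (d, 1)), axis=1).T + rng.random((n_init, d))) / n_init
    us: list[np.ndarray] = []
    ys: list[float] = []

    def record(u):
        u = np.clip(np.asarray(u, float), 0.0, 1.0)
        us.append(u)
        ys.append(evaluate(u))
        return ys[-1]

    warm_us = []
    for start in extra_starts or []:
        u = to_u(np.array([start[n] for n in names], dtype=float))
        warm_us.append(u)
        record(u)
    for u in lhs:
        record(u)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-8, (1e-12, 1e-2))
    # Budget split after seeding: brief EI exploration, then local
    # refinement, with the final n_average evaluations reserved for tight
    # sampling around the converged incumbent (so their mean, the returned
    # estimate, is itself converged).
    n_tail = min(spec.n_average, max(spec.n_iterations - n_init, 0))
    n_ei = min(
        max(10, spec.n_iterations // 20),
        max(spec.n_iterations - n_init - n_tail, 0),
    )

    # surrogate-guided exploration (expected improvement on the log-loss)
    for _ in range(n_ei):
        y_arr = np.asarray(ys)
        finite = np.isfinite(y_arr)
        penalty = (y_arr[finite].max() + 1.0) if finite.any() else 1e6
        y_pen = np.where(finite, y_arr, penalty)
        y_fit = np.log(np.maximum(y_pen, 1e-300))
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-10,
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(np.vstack(us), y_fit)
        kernel = gp.kernel_  # warm-start hyperparameters
        u_best = us[int(np.argmin(y_pen))]
        cands = [rng.random((192, d))]
        for radius in (0.02, 0.05, 0.10, 0.20):
            cands.append(np.clip(u_best + rng.normal(0.0, radius, (48, d)), 0.0, 1.0))
        cands = np.vstack(cands)
        mu, sigma = gp.predict(cands, return_std=True)
        ei = _expected_improvement(mu, sigma, float(y_fit.min()))
        record(cands[int(np.argmax(ei))])

    # local refinement of the incumbent (multi-start within budget)
    n_refine = spec.n_iterations - len(us) - n_tail

    class _Budget(Exception):
        pass

    def _incumbent():
        y_arr = np.asarray(ys)
        finite = np.isfinite(y_arr)
        return int(np.argmin(np.where(finite, y_arr, np.inf)))

    if n_refine > 0:
        from scipy.optimize import least_squares as _least_squares
        from scipy.optimize import minimize as _minimize

        refine_cap = len(us) + n_refine
        n_starts = 3
        # Diversified starts: the best seeding point first (its basin is
        # chosen by the least-squares geometry, not by the surrogate's
        # exploitation), then the overall incumbent, then distant others.
        y_arr = np.where(np.isfinite(ys), ys, np.inf)
        seed_best = int(np.argmin(y_arr[: n_init + len(warm_us)]))
        starts = list(warm_us)
        if all(np.linalg.norm(us[seed_best] - s) > 0.15 for s in starts):
            starts.append(us[seed_best])
        y_sorted = np.argsort(y_arr)
        for i in y_sorted:
            if len(starts) >= n_starts:
                break
            if all(np.linalg.norm(us[i] - s) > 0.15 for s in starts):
                starts.append(us[i])

        def capped(u, cap):
            if len(us) >= cap:
                raise _Budget
            return record(u)

        def resid_capped(u, cap):
            if len(us) >= cap:
                raise _Budget
            u = np.clip(np.asarray(u, float), 0.0, 1.0)
            r = np.asarray(residuals(dict(zip(names, to_x(u)))), float)
            us.append(u)
            ys.append(float(np.sqrt(np.mean(r**2))))
            return np.where(np.isfinite(r), r, 1e6)

        for u_start in starts:
            if len(us) >= refine_cap:
                break
            # each start may use the whole remaining refinement budget; a
            # later start only runs on what an early terminator left over
            start_cap = refine_cap
            try:
                if residuals is not None:
                    _least_squares(
                        lambda u: resid_capped(u, start_cap),
                        u_start,
                        bounds=(0.0, 1.0),
                        diff_step=1e-6,
                        xtol=1e-14,
                        ftol=1e-14,
                        gtol=1e-14,
                        max_nfev=start_cap - len(us),
                    )
                else:
                    _minimize(
                        lambda u: capped(u, start_cap),
                        u_start,
                        method="Nelder-Mead",
                        bounds=[(0.0, 1.0)] * d,
                        options={
                            "maxfev": start_cap - len(us),
                            "xatol": 1e-12,
                            "fatol": 1e-15,
                            "initial_simplex": np.clip(
                                u_start
                                + 0.05 * np.vstack([np.zeros(d), np.eye(d)]),
                                0.0,
                                1.0,
                            ),
                        },
                    )
            except _Budget:
                if len(us) >= refine_cap:
                    break
                continue
            # a well-converged fit needs no further restarts
            if ys[_incumbent()] < 1e-10:
                break

    # final n_average evaluations: tight jitter around the incumbent, so
    # the averaged tail is a converged point estimate
    while len(us) < spec.n_iterations:
        record(np.clip(us[_incumbent()] + rng.normal(0.0, 0.002, d), 0.0, 1.0))

    y_arr = np.asarray(ys)
    u_arr = np.vstack(us)
    finite = np.isfinite(y_arr)
    i_best = int(np.argmin(np.where(finite, y_arr, np.inf)))
    n_avg = min(spec.n_average, len(us))
    if spec.average_best:
        order = np.argsort(np.where(finite, y_arr, np.inf))[:n_avg]
        u_mean = u_arr[order].mean(axis=0)
    else:
        u_mean = u_arr[-n_avg:].mean(axis=0)
    return OptimizationResult(
        x=to_x(u_mean),
        x_best=to_x(u_arr[i_best]),
        f_best=float(y_arr[i_best]),
        objective_trace=y_arr,
        proposals=np.vstack([to_x(u) for u in us]),
        param_names=names,
    )


def _simulate_months(params, forcing, richness, fpd, months):
    flux = simulate_site(forcing, params, richness=richness, fpd=fpd)
    return flux[np.asarray(months, dtype=int)]


def _predict_observations(params, forcing, obs, richness, fpd):
    """Predicted fluxes for observation rows, honouring a richness column.

    Multi-richness observation tables (with a known diversity factor) pin
    the pathway-specific K_max far better than any single series: the
    per-pathway richness scaling reweights the pathways between levels.
    """
    if "richness" in obs.columns:
        pred = np.empty(len(obs))
        for r, grp in obs.groupby("richness"):
            flux = simulate_site(forcing, params, richness=float(r), fpd=fpd)
            pred[obs["richness"].to_numpy() == r] = flux[
                grp["month"].to_numpy(int)
            ]
        return pred
    return _simulate_months(params, forcing, richness, fpd, obs["month"])


def calibrate_kmax(
    observations: pd.DataFrame,
    forcing: SiteForcing,
    spec: CalibrationSpec,
    base_params: MicNParams | None = None,
    richness: float = 1.0,
    fpd: DiversityFactor | None = None,
    split: bool = True,
    extra_starts=None,
) -> CalibrationResult:
    """Calibrate the six K_max against monthly flux observations.

    ``observations`` needs ``month`` (0-based forcing index) and ``flux``
    (g N m-2 month-1) columns; a ``richness`` column (with ``fpd``) fits
    all levels jointly.  The loss is the RMSE of predicted vs observed
    training fluxes; validation metrics are computed on the held-out rows
    (or on the training rows when ``split=False``).  The prior
    parameterization ``base_params`` is always tried as a refinement
    start, alongside any ``extra_starts``.
    """
    for col in ("month", "flux"):
        if col not in observations.columns:
            raise ValueError(f"observations missing column {col!r}")
    base = base_params if base_params is not None else MicNParams()
    if split:
        train, valid = train_valid_split(observations, spec)
    else:
        train = valid = observations

    y_train = train["flux"].to_numpy(float)

    def residuals(kmax: dict) -> np.ndarray:
        params = base.with_kmax(kmax)
        return _predict_observations(params, forcing, train, richness, fpd) - y_train

    def objective(kmax: dict) -> float:
        return float(np.sqrt(np.mean(residuals(kmax) ** 2)))

    starts = list(extra_starts or [])
    prior = {n: getattr(base, n) for n in spec.bounds if hasattr(base, n)}
    if len(prior) == len(spec.bounds):
        starts.append(prior)
    opt = bayes_optimize(objective, spec, residuals=residuals, extra_starts=starts)
    params = base.with_kmax(opt.as_dict())
    r2, rmse = validate_model(
        params, valid, forcing, richness=richness, fpd=fpd
    )
    return CalibrationResult(
        params=params,
        objective_trace=opt.objective_trace,
        validation_r2=r2,
        validation_rmse=rmse,
        split_ids={
            "train": train.index.to_numpy(),
            "validation": valid.index.to_numpy(),
        },
        optimization=opt,
    )


def calibrate_per_richness(
    observations: pd.DataFrame,
    forcing: SiteForcing,
    spec: CalibrationSpec,
    base_params: MicNParams | None = None,
    split: bool = False,
) -> pd.DataFrame:
    """Independent K_max calibration per richness level.

    ``observations`` needs ``richness``, ``month`` and ``flux`` columns.
    Each richness group is calibrated with the model run at richness 1 (no
    diversity factor), so the fitted K_max absorb the diversity effect;
    the resulting table feeds
    :func:`~divn2o.micn.fit_diversity_factor`.  Groups are calibrated with
    per-group seeds derived from ``spec.seed`` for reproducibility.
    """
    if "richness" not in observations.columns:
        raise ValueError("observations missing column 'richness'")
    rows = []
    previous: dict | None = None
    for k, (richness, grp) in enumerate(observations.groupby("richness")):
        if grp.empty:  # pragma: no cover - groupby yields no empty groups
            continue
        sub_spec = CalibrationSpec(
            bounds=dict(spec.bounds),
            n_iterations=spec.n_iterations,
            n_average=spec.n_average,
            n_initial=spec.n_initial,
            seed=spec.seed + 1000 * k,
            train_fraction=spec.train_fraction,
            log_scale=spec.log_scale,
            average_best=spec.average_best,
        )
        result = calibrate_kmax(
            grp.reset_index(drop=True),
            forcing,
            sub_spec,
            base_params=base_params,
            richness=1.0,
            fpd=None,
            split=split,
            # effective K_max vary smoothly with richness, so the previous
            # level's fit is an excellent refinement start
            extra_starts=[previous] if previous else None,
        )
        previous = {n: getattr(result.params, n) for n in KMAX_NAMES}
        row = {"richness": richness, "rmse": result.validation_rmse}
        row.update(previous)
        rows.append(row)
    return pd.DataFrame(rows)


def validate_model(
    params: MicNParams,
    validation: pd.DataFrame,
    forcing: SiteForcing,
    richness: float = 1.0,
    fpd: DiversityFactor | None = None,
) -> tuple[float, float]:
    """Held-out R-squared and RMSE of the model at given parameters.

    R-squared is 1 - SS_res/SS_tot over the validation observations;
    raises when the observations have zero variance (R-squared undefined).
    """
    if validation.empty:
        raise ValueError("validation set is empty")
    obs = validation["flux"].to_numpy(float)
    pred = _predict_observations(params, forcing, validation, richness, fpd)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance validation observations: R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot, rmse_loss(pred, obs)
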