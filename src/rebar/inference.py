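"""Two-stage inference of rank-one barcode processing bias.

The bias effect on the log-count of variant i in sample (assay a, time t) is
modeled as u_i * v_t^a: a per-variant susceptibility times a per-sample bias
prevalence, with the prevalence decomposed into a linear-in-time trend plus a
deviation, v_t^a = lambda^a * t + gamma_t^a.

Stage 1 alternates exact ridge-regularized updates of u (given gamma) and
gamma (given u) against the residual-projected log-counts; only the deviation
part of the prevalence is identifiable from residuals, because the projector
annihilates anything linear in time. Stage 2 pins down the trend lambda of
each assay by regressing the fitness misestimates of an equal-fitness control
set against the inferred susceptibilities (delta_f = u * lambda). The composed
prevalences give bias-adjusted log-counts logA = logC - u x v, which are refit
for corrected fitness estimates.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import FitSet, FitnessErrors, control_fitness_errors, fit_loglinear
from .io import AssayDesign, CountDataset, LogCountMatrix, normalize_depth

logger = logging.getLogger(__name__)

__all__ = [
    "RebarConfig",
    "BiasComponents",
    "Stage1Result",
    "RebarResult",
    "update_susceptibilities",
    "update_prevalence_deviations",
    "run_stage1",
    "estimate_trend",
    "compose_and_correct",
    "correct_log_counts",
    "run_rebar",
]


@dataclass(frozen=True)
class RebarConfig:
    """Tuning knobs of the alternating optimization.

    ridge
        Weight of the quadratic penalty on both u and gamma; resolves the
        scale symmetry and keeps degenerate updates finite. ``None`` means
        1e-3 x n_samples.
    tol
        Stop when the relative drop of the penalized objective over one sweep
        falls below this.
    fit_intercept_trend
        Regress control-set fitness errors on group-centered susceptibilities
        (the errors are group-centered by construction). ``False`` forces the
        regression through the origin against raw u.
    """

    ridge: float | None = None
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    init_scale: float = 0.01
    fit_intercept_trend: bool = True

    def __post_init__(self) -> None:
        if self.ridge is not None and self.ridge < 0:
            raise ValueError("ridge must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")

    def resolve_ridge(self, n_samples: int) -> float:
        return 1e-3 * n_samples if self.ridge is None else float(self.ridge)


@dataclass(frozen=True)
class BiasComponents:
    """Inferred bias decomposition: susceptibility u per variant, trend lambda
    per assay, deviation gamma and absolute prevalence v = lambda*t + gamma
    per sample. gamma is orthogonal to {1, t} within each assay; u is
    normalized to unit root-mean-square with its largest entry positive."""

    variant_ids: tuple[str, ...]
    assays: tuple[AssayDesign, ...]
    u: np.ndarray       # (n_variants,)
    gamma: np.ndarray   # (n_samples,)
    lam: np.ndarray     # (n_assays,)
    v: np.ndarray       # (n_samples,)

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return tuple(a.assay_id for a in self.assays)


@dataclass(frozen=True)
class Stage1Result:
    u: np.ndarray
    gamma: np.ndarray
    objective_trace: np.ndarray       # penalized objective after each sweep
    half_step_trace: np.ndarray       # penalized objective after each half-step
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class RebarResult:
    bias: BiasComponents
    corrected_log_counts: LogCountMatrix
    corrected_fits: FitSet
    raw_fits: FitSet
    objective_trace: np.ndarray | None = None
    half_step_trace: np.ndarray | None = None
    converged: bool = True
    lambda_se: np.ndarray | None = None
    config: RebarConfig | None = None


def _projected_blocks(logc: LogCountMatrix):
    """Per assay: (design, column index, projector, projected data block)."""
    blocks = []
    for assay, cols in logc.assay_slices():
        t = assay.times()
        X = np.column_stack([np.ones_like(t), t])
        P = np.eye(t.size) - X @ np.linalg.solve(X.T @ X, X.T)
        blocks.append((assay, cols, P, logc.values[:, cols] @ P))
    return blocks


def update_susceptibilities(logc: LogCountMatrix, v_hat: np.ndarray, ridge: float) -> np.ndarray:
    """Exact minimizer of the per-variant ridge objective given prevalences.

    u_i = sum_a <P logC_i^a, P v^a> / (sum_a ||P v^a||^2 + ridge).
    """
    v_hat = np.asarray(v_hat, dtype=float)
    if v_hat.shape != (logc.values.shape[1],):
        raise ValueError("v_hat must hold one value per sample")
    num = np.zeros(logc.values.shape[0])
    den = float(ridge)
    for assay, cols in logc.assay_slices():
        t = assay.times()
        X = np.column_stack([np.ones_like(t), t])
        P = np.eye(t.size) - X @ np.linalg.solve(X.T @ X, X.T)
        pv = P @ v_hat[cols]
        num += logc.values[:, cols] @ pv
        den += float(pv @ pv)
    if den <= 1e-10 * (1.0 + float(v_hat @ v_hat)):
        raise ValueError(
            "prevalence lies in span{1, t} in every assay; the susceptibility "
            "update is degenerate -- use ridge > 0"
        )
    return num / den


def update_prevalence_deviations(
    logc: LogCountMatrix, u_hat: np.ndarray, assay: AssayDesign | str, ridge: float
) -> np.ndarray:
    """Exact minimizer of one assay's ridge objective given susceptibilities.

    gamma^a = P [sum_i u_i logC_i^a] / (sum_i u_i^2 + ridge), constrained to
    the range of the residual projector (orthogonal to {1, t}).
    """
    u_hat = np.asarray(u_hat, dtype=float)
    assay_id = assay.assay_id if isinstance(assay, AssayDesign) else str(assay)
    for a, cols in logc.assay_slices():
        if a.assay_id == assay_id:
            break
    else:
        raise KeyError(f"no assay {assay_id!r} in dataset")
    if not np.any(u_hat):
        warnings.warn(
            "all susceptibilities are zero; prevalence deviations are "
            "unidentifiable and set to zero (regularized limit)",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(a.n_timepoints)
    t = a.times()
    X = np.column_stack([np.ones_like(t), t])
    P = np.eye(t.size) - X @ np.linalg.solve(X.T @ X, X.T)
    den = float(u_hat @ u_hat + ridge)
    return P @ (logc.values[:, cols].T @ u_hat) / den


def _normalize_components(u: np.ndarray, gamma: np.ndarray):
    """Fix the scale/sign symmetry: RMS(u)=1 and largest-|u| entry positive."""
    rms = float(np.sqrt(np.mean(u**2)))
    if rms < 1e-12:
        warnings.warn(
            "stage 1 found no bias mode (susceptibilities ~ 0)",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.zeros_like(u), np.zeros_like(gamma)
    u = u / rms
    gamma = gamma * rms
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        u = -u
        gamma = -gamma
    return u, gamma


def run_stage1(logc: LogCountMatrix, config: RebarConfig | None = None) -> Stage1Result:
    """Alternating inference of susceptibilities and prevalence deviations.

    Susceptibilities start at small random values (gamma at zero) and each
    sweep updates gamma then u with their exact conditional minimizers, so the
    penalized objective never increases. A balance rescale (equalizing the
    penalty split between u and gamma, which also never increases the
    objective) is applied each sweep; the reported components are normalized
    to RMS(u)=1 with the sign convention at the end.
    """
    config = config or RebarConfig()
    values = logc.values
    n_var, n_samp = values.shape
    rho = config.resolve_ridge(n_samp)
    blocks = _projected_blocks(logc)

    rng = np.random.default_rng(config.seed)
    u = rng.normal(0.0, config.init_scale, n_var)
    gammas = [np.zeros(assay.n_timepoints) for assay, *_ in blocks]

    def objective(u, gammas) -> float:
        rss = sum(
            float(np.sum((Yp - np.outer(u, g)) ** 2))
            for (_, _, _, Yp), g in zip(blocks, gammas)
        )
        pen = rho * (float(u @ u) + sum(float(g @ g) for g in gammas))
        return rss + pen

    half = [objective(u, gammas)]
    trace = [half[0]]
    converged = False
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        # gamma update (per assay), given u
        den_g = float(u @ u) + rho
        if den_g <= 0:
            warnings.warn(
                "susceptibilities and ridge are both zero; stopping",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        gammas = [Yp.T @ u / den_g for (_, _, _, Yp) in blocks]
        half.append(objective(u, gammas))

        # u update, given gamma
        num = np.zeros(n_var)
        den = rho
        for (_, _, _, Yp), g in zip(blocks, gammas):
            num += Yp @ g
            den += float(g @ g)
        if den <= 0:
            raise ValueError(
                "prevalence deviations vanished with ridge 0; use ridge > 0"
            )
        u = num / den
        half.append(objective(u, gammas))

        # balance rescale: never increases the penalized objective
        nu2 = float(u @ u)
        ng2 = sum(float(g @ g) for g in gammas)
        if nu2 > 0 and ng2 > 0:
            s = (nu2 / ng2) ** 0.25
            u = u / s
            gammas = [g * s for g in gammas]
            half.append(objective(u, gammas))

        obj = half[-1]
        if not np.isfinite(obj):
            raise FloatingPointError("stage-1 objective became non-finite")
        prev = trace[-1]
        trace.append(obj)
        if obj <= 1e-30 or (prev - obj) <= config.tol * max(prev, 1e-30):
            converged = True
            break

    gamma_full = np.zeros(n_samp)
    for (assay, cols, _, _), g in zip(blocks, gammas):
        gamma_full[cols] = g
    u, gamma_full = _normalize_components(u, gamma_full)
    return Stage1Result(
        u=u,
        gamma=gamma_full,
        objective_trace=np.asarray(trace),
        half_step_trace=np.asarray(half),
        converged=converged,
        n_iter=n_iter,
    )


def estimate_trend(
    errors: FitnessErrors,
    u_control: np.ndarray,
    fit_intercept: bool = True,
):
    """Per-assay bias-prevalence trend from the control-set regression.

    The model delta_f_i = u_i * lambda has no intercept, but the control-set
    delta_f are centered on the group mean, so the default regresses against
    group-centered u (the numerators coincide because sum(delta_f) = 0; only
    the denominator differs). Returns (lambda, standard_error) per assay.
    """
    u_control = np.asarray(u_control, dtype=float)
    delta = errors.delta_f
    if u_control.shape != (delta.shape[0],):
        raise ValueError("u_control must align with the control-set error rows")
    n_assays = delta.shape[1]
    lam = np.zeros(n_assays)
    se = np.full(n_assays, np.nan)
    for a in range(n_assays):
        y = delta[:, a]
        ok = np.isfinite(y) & np.isfinite(u_control)
        x = u_control[ok]
        y = y[ok]
        if x.size < 2:
            warnings.warn(
                f"assay {errors.assay_ids[a]!r}: fewer than 2 control variants "
                "with fits; trend set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        xc = x - x.mean() if fit_intercept else x
        den = float(xc @ xc)
        if den < 1e-12:
            warnings.warn(
                f"assay {errors.assay_ids[a]!r}: control susceptibilities carry "
                "no signal; bias trend unidentifiable, set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        lam[a] = float(xc @ y) / den
        dof = x.size - (2 if fit_intercept else 1)
        if dof > 0:
            fitted = lam[a] * xc + (y.mean() if fit_intercept else 0.0)
            resid = y - fitted
            se[a] = float(np.sqrt(resid @ resid / dof / den))
    return lam, se


def compose_and_correct(
    logc: LogCountMatrix,
    u_hat: np.ndarray,
    gamma_hat: np.ndarray,
    lambda_hat: np.ndarray,
) -> RebarResult:
    """Compose absolute prevalences and produce bias-adjusted counts and fits.

    v = lambda*t + gamma per sample; logA = logC - u x v. Corrected fitnesses
    come from refitting logA; because gamma is orthogonal to {1, t}, they must
    equal the analytic shortcut f_raw - u*lambda, which is verified here.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    lambda_hat = np.asarray(lambda_hat, dtype=float)
    n_var, n_samp = logc.values.shape
    slices = logc.assay_slices()
    if u_hat.shape != (n_var,) or gamma_hat.shape != (n_samp,):
        raise ValueError("component shapes do not match the dataset")
    if lambda_hat.shape != (len(slices),):
        raise ValueError("lambda must hold one value per assay")

    v = np.zeros(n_samp)
    for j, (assay, cols) in enumerate(slices):
        v[cols] = lambda_hat[j] * assay.times() + gamma_hat[cols]

    logA = logc.values - np.outer(u_hat, v)
    corrected = logc.replace_values(logA, provenance="corrected")
    corrected_fits = fit_loglinear(corrected)
    raw_fits = fit_loglinear(logc)

    shortcut = raw_fits.slope - np.outer(u_hat, lambda_hat)
    diff = np.abs(corrected_fits.slope - shortcut)
    scale = 1.0 + float(np.nanmax(np.abs(raw_fits.slope))) if raw_fits.slope.size else 1.0
    if np.nanmax(diff, initial=0.0) > 1e-8 * scale:
        raise RuntimeError(
            "internal consistency failure: refit slopes disagree with the "
            "analytic trend subtraction"
        )

    bias = BiasComponents(
        variant_ids=logc.variant_ids,
        assays=logc.assays,
        u=u_hat,
        gamma=gamma_hat,
        lam=lambda_hat,
        v=v,
    )
    return RebarResult(
        bias=bias,
        corrected_log_counts=corrected,
        corrected_fits=corrected_fits,
        raw_fits=raw_fits,
    )


def correct_log_counts(
    logc: LogCountMatrix,
    control_ids,
    config: RebarConfig | None = None,
) -> RebarResult:
    """Full two-stage correction starting from normalized log-counts."""
    config = config or RebarConfig()
    control_ids = tuple(str(v) for v in control_ids)
    if not control_ids:
        raise ValueError("control set is empty")
    missing = set(control_ids) - set(logc.variant_ids)
    if missing:
        raise KeyError(f"control variants absent from dataset: {sorted(missing)[:5]}")

    raw_fits = fit_loglinear(logc)
    stage1 = run_stage1(logc, config)
    errors = control_fitness_errors(raw_fits, control_ids)
    lookup = {v: i for i, v in enumerate(logc.variant_ids)}
    u_ctrl = stage1.u[[lookup[v] for v in control_ids]]
    lam, lam_se = estimate_trend(errors, u_ctrl, fit_intercept=config.fit_intercept_trend)
    result = compose_and_correct(logc, stage1.u, stage1.gamma, lam)
    return RebarResult(
        bias=result.bias,
        corrected_log_counts=result.corrected_log_counts,
        corrected_fits=result.corrected_fits,
        raw_fits=raw_fits,
        objective_trace=stage1.objective_trace,
        half_step_trace=stage1.half_step_trace,
        converged=stage1.converged,
        lambda_se=lam_se,
        config=config,
    )


def run_rebar(
    dataset: CountDataset,
    control_ids,
    config: RebarConfig | None = None,
) -> RebarResult:
    """Depth-normalize, infer the bias mode, and correct counts and fitnesses."""
    logc = normalize_depth(dataset)
    return correct_log_counts(logc, control_ids, config)
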