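"""Spillover-matrix estimation: robust initial fit and iterative refinement.

Model. For an event with true dye abundances x (length d) and observed
detector signals y (length c >= d), the linear mixing model is x S = y with S
the d x c row-normalized spillover matrix. On a single-color control for dye
i only x_i varies, so every spillover coefficient S_ij equals the slope of
detector j regressed on the primary detector h_i — estimated robustly
(Huber, k = 1.345) because fluorescence is heteroskedastic.

Compensating with an erroneous estimate U = S + T leaves residual slopes
(the compensation error matrix E, E_ij = slope of compensated dye j vs dye i
on control i, diagonal 0). The estimation error obeys the exact identity
T = -E U, which turns the measured E into a correction: the refinement step
S <- row-normalize(S + E S) drives the measured compensation error to zero.
Iterations run in linear scale, switch to bi-exponential scale once
max|E| < 1e-2 (so the refinement optimizes the scale on which data are
inspected), stop at max|E| < 1e-4, and damp the update to 10% when a moving
average (window 10, initial value 1) of the per-iteration decrease of sd(E)
falls below 1e-6, which signals oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .io import (
    AUTO,
    AutospillError,
    CompensationErrorMatrix,
    ControlSet,
    ConvergenceTrace,
    EventTable,
    SpilloverMatrix,
    TraceRecord,
)
from .robust import HUBER_K, fit_slope_robust
from .transforms import LinearTransform, LogicleTransform, logicle_from_data

__all__ = [
    "RefinementConfig",
    "SingularSpilloverError",
    "resolve_primary",
    "resolve_primaries",
    "initial_spillover",
    "compensate",
    "compensate_table",
    "compensation_errors",
    "refine_step",
    "refine_until_convergence",
    "traditional_spillover",
]


class SingularSpilloverError(AutospillError):
    """The spillover matrix is singular or rank-deficient."""


@dataclass(frozen=True)
class RefinementConfig:
    """Thresholds and knobs of the iterative refinement.

    All default values are the algorithm's published operating points: scale
    switch at max|E| < 1e-2, convergence at 1e-4, oscillation detection at
    1e-6 on a moving average of window 10 initialized at 1, 10% damped
    updates, Huber tuning constant 1.345.
    """

    scale_switch_threshold: float = 1e-2
    convergence_threshold: float = 1e-4
    oscillation_threshold: float = 1e-6
    oscillation_window: int = 10
    oscillation_initial: float = 1.0
    damping_fraction: float = 0.10
    max_iterations: int = 100
    huber_k: float = HUBER_K
    biexp_decades: float = 4.5

    def __post_init__(self) -> None:
        for name in (
            "scale_switch_threshold",
            "convergence_threshold",
            "oscillation_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.damping_fraction <= 1:
            raise ValueError("damping_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# primaries and initial estimate
# ---------------------------------------------------------------------------


def resolve_primary(control: EventTable, requested: str = AUTO) -> str:
    """Detector assigned to a dye: explicit name, or highest-median channel.

    With ``AUTO`` the primary is the fluorescence detector with the highest
    median signal in the (gated) control; ties resolve to the earlier
    detector in file order.
    """
    if requested != AUTO:
        if requested not in control.detector_names:
            from .io import DetectorNotFoundError

            raise DetectorNotFoundError(requested)
        return requested
    names = control.fluorescence_names()
    medians = np.median(control.fluorescence(), axis=0)
    return names[int(np.argmax(medians))]


def resolve_primaries(controls: ControlSet) -> ControlSet:
    resolved = {
        dye: resolve_primary(controls.tables[dye], controls.primaries.get(dye, AUTO))
        for dye in controls.dyes
    }
    return replace_primaries(controls, resolved)


def replace_primaries(controls: ControlSet, primaries: dict[str, str]) -> ControlSet:
    return ControlSet(
        dyes=list(controls.dyes),
        tables=dict(controls.tables),
        primaries=primaries,
        unstained=controls.unstained,
        detectors=tuple(controls.detectors),
    )


def initial_spillover(controls: ControlSet, k: float = HUBER_K) -> SpilloverMatrix:
    """First spillover estimate: one robust slope per (dye, secondary) pair.

    Row i has 1 at the dye's primary detector and the Huber slope of detector
    j vs the primary elsewhere. Controls are expected gated and primaries
    resolved.
    """
    channels = controls.fluorescence_names()
    d, c = controls.n_dyes, len(channels)
    coef = np.zeros((d, c))
    primary: dict[str, int] = {}
    for i, dye in enumerate(controls.dyes):
        table = controls.tables[dye]
        name = controls.primaries[dye]
        if name == AUTO:
            raise ValueError(f"primary for dye {dye!r} not resolved")
        h = channels.index(name)
        primary[dye] = h
        x = table.column(name)
        fl = table.fluorescence()
        for j in range(c):
            if j == h:
                coef[i, j] = 1.0
            else:
                coef[i, j] = fit_slope_robust(x, fl[:, j], k=k).slope
    return SpilloverMatrix(coef, tuple(controls.dyes), channels, primary)


# ---------------------------------------------------------------------------
# compensation
# ---------------------------------------------------------------------------


def compensate(values: np.ndarray, matrix: SpilloverMatrix) -> np.ndarray:
    """Solve x S = y for every observed event row y.

    Square systems invert S; rectangular systems (fewer dyes than detectors,
    the spectral-unmixing case) solve the per-event least-squares problem via
    the normal equations x = y S' (S S')^-1.
    """
    s = matrix.coef
    d, c = s.shape
    y = np.asarray(values, dtype=np.float64)
    try:
        if d == c:
            cond = np.linalg.cond(s)
            if not np.isfinite(cond) or cond > 1e12:
                raise SingularSpilloverError("spillover matrix is numerically singular")
            return np.linalg.solve(s.T, y.T).T
        gram = s @ s.T
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularSpilloverError("spillover matrix is rank-deficient")
        return np.linalg.solve(gram, s @ y.T).T
    except np.linalg.LinAlgError as err:  # pragma: no cover - cond check first
        raise SingularSpilloverError(str(err)) from err


def compensate_table(table: EventTable, matrix: SpilloverMatrix) -> EventTable:
    """Compensated dye-space EventTable (columns become dyes)."""
    idx = [table.detector_names.index(n) for n in matrix.detectors]
    x = compensate(table.values[:, idx], matrix)
    return EventTable(x, matrix.dyes, scatter_channels=None)


# ---------------------------------------------------------------------------
# compensation errors and refinement
# ---------------------------------------------------------------------------


def _biexp_slope(
    x: np.ndarray,
    y: np.ndarray,
    tx_transform: LogicleTransform,
    ty_transform: LogicleTransform,
    k: float,
) -> float:
    """Robust slope on the bi-exponential scale, mapped back to linear.

    The fit runs on transformed coordinates; the returned linear-scale slope
    is the chord through the two points of the fitted line at the extreme
    primary-channel values, both mapped back through the inverse transform.
    """
    tx = tx_transform.forward(x)
    ty = ty_transform.forward(y)
    fit = fit_slope_robust(tx, ty, k=k)
    t0, t1 = float(tx.min()), float(tx.max())
    if t1 == t0:
        from .robust import ZeroVarianceError

        raise ZeroVarianceError("zero variance in transformed primary channel")
    pts_t = np.array([t0, t1])
    line_t = fit.intercept + fit.slope * pts_t
    x_lin = tx_transform.inverse(pts_t)
    y_lin = ty_transform.inverse(line_t)
    return float((y_lin[1] - y_lin[0]) / (x_lin[1] - x_lin[0]))


def compensation_errors(
    compensated: dict[str, EventTable],
    dyes: tuple[str, ...],
    transforms: dict[str, LogicleTransform] | None = None,
    k: float = HUBER_K,
) -> CompensationErrorMatrix:
    """Residual robust slopes of each secondary dye vs the control's own dye.

    ``transforms`` maps dye name to its bi-exponential transform; ``None``
    means the fits run in linear scale. Bi-exponential slopes are converted
    back to linear-scale slopes (chord through the extreme-primary points of
    the regression line) so they can feed the linear update identity.
    """
    d = len(dyes)
    coef = np.zeros((d, d))
    for i, dye in enumerate(dyes):
        table = compensated.get(dye)
        if table is None:
            continue
        xi = table.column(dye)
        for j, other in enumerate(dyes):
            if i == j:
                continue
            yj = table.column(other)
            if transforms is None:
                coef[i, j] = fit_slope_robust(xi, yj, k=k).slope
            else:
                coef[i, j] = _biexp_slope(xi, yj, transforms[dye], transforms[other], k)
    return CompensationErrorMatrix(coef, dyes)


def refine_step(
    matrix: SpilloverMatrix, errors: CompensationErrorMatrix, damping: float = 1.0
) -> SpilloverMatrix:
    """One update S <- row-normalize(S + damping * E S)."""
    s = matrix.coef
    update = errors.coef @ s
    shat = s + damping * update
    coef = np.empty_like(shat)
    for i, dye in enumerate(matrix.dyes):
        h = matrix.primary[dye]
        pivot = shat[i, h]
        if pivot == 0.0:
            raise SingularSpilloverError(
                f"update zeroed the primary entry of dye {dye!r}"
            )
        coef[i] = shat[i] / pivot
        coef[i, h] = 1.0  # exact, not just within roundoff
    return replace(matrix, coef=coef)


def _moving_average(deltas: list[float], window: int, initial: float) -> float:
    padded = [initial] * max(window - len(deltas), 0) + deltas[-window:]
    return float(np.mean(padded[-window:]))


def refine_until_convergence(
    controls: ControlSet,
    initial: SpilloverMatrix,
    config: RefinementConfig | None = None,
) -> tuple[SpilloverMatrix, ConvergenceTrace, dict[str, EventTable]]:
    """Iterate compensate -> measure errors -> update until max|E| < 1e-4.

    Returns the final matrix, the per-iteration trace, and the compensated
    controls at the final matrix. Non-convergence within ``max_iterations``
    is reported through ``trace.status`` rather than raised.
    """
    cfg = config or RefinementConfig()
    matrix = initial
    trace = ConvergenceTrace()
    transforms: dict[str, LogicleTransform] | None = None
    deltas: list[float] = []
    prev_sd: float | None = None
    damping_on = False
    compensated: dict[str, EventTable] = {}

    for iteration in range(cfg.max_iterations):
        compensated = {
            dye: compensate_table(controls.tables[dye], matrix) for dye in controls.dyes
        }
        errors = compensation_errors(
            compensated, matrix.dyes, transforms=transforms, k=cfg.huber_k
        )
        sd = errors.sd()
        max_abs = errors.max_abs()
        if prev_sd is not None:
            deltas.append(prev_sd - sd)
        prev_sd = sd
        ma = _moving_average(deltas, cfg.oscillation_window, cfg.oscillation_initial)
        if not damping_on and ma < cfg.oscillation_threshold:
            damping_on = True
        alpha = cfg.damping_fraction if damping_on else 1.0
        scale = "biexp" if transforms is not None else "linear"
        trace.append(
            TraceRecord(
                iteration=iteration,
                scale=scale,
                sd_error=sd,
                max_abs_error=max_abs,
                moving_average=ma,
                damping=alpha,
            )
        )
        trace.final_errors = errors
        trace.transforms = transforms
        if max_abs < cfg.convergence_threshold:
            trace.status = "converged"
            return matrix, trace, compensated
        if transforms is None and max_abs < cfg.scale_switch_threshold:
            transforms = {
                dye: logicle_from_data(
                    np.concatenate(
                        [compensated[d2].column(dye) for d2 in controls.dyes]
                    ),
                    m=cfg.biexp_decades,
                )
                for dye in matrix.dyes
            }
        matrix = refine_step(matrix, errors, damping=alpha)

    trace.status = "not_converged"
    return matrix, trace, compensated


# ---------------------------------------------------------------------------
# traditional positive/negative-population estimate (comparison oracle)
# ---------------------------------------------------------------------------


def _split_positive_negative(values: np.ndarray) -> np.ndarray:
    """Boolean mask of the positive population by 1-d 2-means.

    Clustering runs on a signed-square-root scale: on the raw scale the
    variance of a log-normal positive population dwarfs the
    negative/positive separation and k-means would split the positives
    instead of the populations.
    """
    t = np.sign(values) * (np.sqrt(np.abs(values) + 1.0) - 1.0)
    v = t.reshape(-1, 1)
    init = np.array([[float(t.min())], [float(t.max())]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=100)
    labels = km.fit_predict(v)
    centers = km.cluster_centers_.ravel()
    return labels == int(np.argmax(centers))


def _populations_distinct(
    primary_values: np.ndarray,
    pos: np.ndarray,
    min_events: int,
    min_separation_sds: float,
) -> bool:
    if pos.sum() < min_events or (~pos).sum() < min_events:
        return False
    med_pos = float(np.median(primary_values[pos]))
    med_neg = float(np.median(primary_values[~pos]))
    if med_pos <= med_neg:
        return False
    neg = primary_values[~pos]
    neg_sd = float(np.percentile(neg, 84) - np.median(neg))
    return (med_pos - med_neg) >= min_separation_sds * neg_sd


def traditional_spillover(
    controls: ControlSet, min_events: int = 10, min_separation_sds: float = 5.0
) -> tuple[SpilloverMatrix, np.ndarray]:
    """Classic positive/negative-population spillover estimate.

    Each control is split into positive and negative populations on the
    primary channel (1-d 2-means); the coefficient is the ratio of the
    median differences. Returns the matrix and a boolean flag matrix marking
    rows whose populations were indistinguishable (separated by fewer than
    ``min_separation_sds`` robust SDs of the negative population, or with a
    non-positive primary separation). Flagged coefficients are still reported
    when computable, zero otherwise.
    """
    channels = controls.fluorescence_names()
    d, c = controls.n_dyes, len(channels)
    coef = np.zeros((d, c))
    flagged = np.zeros((d, c), dtype=bool)
    primary: dict[str, int] = {}
    for i, dye in enumerate(controls.dyes):
        table = controls.tables[dye]
        name = controls.primaries[dye]
        h = channels.index(name)
        primary[dye] = h
        values = table.column(name)
        pos = _split_positive_negative(values)
        fl = table.fluorescence()
        if not _populations_distinct(values, pos, min_events, min_separation_sds):
            flagged[i, :] = True
        med_pos = np.median(fl[pos], axis=0) if pos.any() else np.zeros(c)
        med_neg = np.median(fl[~pos], axis=0) if (~pos).any() else np.zeros(c)
        denom = med_pos[h] - med_neg[h]
        if denom > 0:
            coef[i] = (med_pos - med_neg) / denom
        coef[i, h] = 1.0
    return SpilloverMatrix(coef, tuple(controls.dyes), channels, primary), flagged
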