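"""Spillover spreading matrix (SSM) by quantile partitioning and regression.

Compensation re-centers secondary channels at zero but spreads their noise:
photon-counting variance grows linearly with fluorescence, so the robust
standard deviation sigma of a compensated secondary channel C obeys

    sigma^2 = (SS_C^P)^2 * F + sigma_0^2

as a function of the primary fluorescence F, where SS_C^P is the spillover
spreading coefficient and sigma_0 the machine noise floor at F = 0. Instead
of the classic two-population estimate
SS = sqrt(sigma_pos^2 - sigma_neg^2) / sqrt(F_pos - F_neg), the events of the
single-color control for P are partitioned into up to 256 quantile bins of
the primary value; each bin contributes (median F, sigma = P84 - median of
C). Two regressions follow: first sigma ~ f_sqrt(F) with intercept to
estimate sigma_0, then the no-intercept fit of the adjusted
sigma' = f_sqrt(sigma^2 - sigma_0^2) on f_sqrt(F), whose slope is SS_C^P.
F may be negative or near zero after compensation, so the signed transform
f_sqrt(x) = sign(x) (sqrt(|x|+1) - 1) replaces the plain square root.
Non-significant (F-test) and negative coefficients are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import AutospillError, ControlSet, SpilloverMatrix
from .spillover import _populations_distinct, _split_positive_negative, compensate_table

__all__ = [
    "QuantileBins",
    "SpreadingMatrix",
    "f_sqrt",
    "partition_quantiles",
    "estimate_sigma0",
    "spreading_coefficient",
    "build_ssm",
    "traditional_ssm",
    "MIN_BIN_EVENTS",
    "BIN_LADDER",
]

#: Power-of-two ladder of allowed bin counts and the per-bin event minimum.
BIN_LADDER = (256, 128, 64, 32, 16, 8)
MIN_BIN_EVENTS = 32

_P84 = 84.0


class TooFewEventsError(AutospillError):
    pass


def f_sqrt(x):
    """Signed square-root-like transform sign(x) * (sqrt(|x|+1) - 1)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * (np.sqrt(np.abs(x) + 1.0) - 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class QuantileBins:
    """Per-bin summaries of one control: median primary F, robust SD of each
    secondary (sigma = P84 - median), and event counts."""

    F: np.ndarray  # (n_bins,) median primary fluorescence, ascending
    sigma: np.ndarray  # (n_bins, n_secondaries)
    counts: np.ndarray  # (n_bins,)
    secondaries: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.F)
        if not 8 <= n <= 256:
            raise ValueError("bin count must lie in [8, 256]")
        if np.any(self.counts <= 0):
            raise ValueError("every bin must be non-empty")
        if np.any(np.diff(self.F) < 0):
            raise ValueError("bins must be ordered by F")


@dataclass(frozen=True)
class SpreadingMatrix:
    """d x d nonnegative spillover spreading matrix with zero diagonal.

    ``reasons`` records why an entry was zeroed ("nonsignificant" or
    "negative"); ``sigma0`` holds the per-(P, C) noise-floor estimates.
    """

    coef: np.ndarray
    dyes: tuple[str, ...]
    sigma0: np.ndarray
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=np.float64)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "dyes", tuple(self.dyes))
        d = len(self.dyes)
        if coef.shape != (d, d):
            raise ValueError("spreading matrix must be d x d")
        if np.any(np.diag(coef) != 0):
            raise ValueError("spreading matrix diagonal must be zero")
        if np.any(coef < 0):
            raise ValueError("retained spreading coefficients must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef, index=list(self.dyes), columns=list(self.dyes))


def partition_quantiles(
    primary: np.ndarray,
    secondaries: np.ndarray,
    secondary_names: tuple[str, ...],
    min_bin_events: int = MIN_BIN_EVENTS,
) -> QuantileBins:
    """Quantile-partition a control by primary value.

    The bin count is the largest value of the {256, ..., 8} ladder giving at
    least ``min_bin_events`` events per bin.
    """
    primary = np.asarray(primary, dtype=np.float64)
    secondaries = np.asarray(secondaries, dtype=np.float64)
    n = primary.size
    n_bins = next((b for b in BIN_LADDER if n // b >= min_bin_events), None)
    if n_bins is None:
        raise TooFewEventsError(
            f"{n} events cannot fill {BIN_LADDER[-1]} bins of {min_bin_events}"
        )
    order = np.argsort(primary, kind="stable")
    chunks = np.array_split(order, n_bins)
    F = np.array([np.median(primary[c]) for c in chunks])
    sigma = np.empty((n_bins, secondaries.shape[1]))
    for b, c in enumerate(chunks):
        vals = secondaries[c]
        sigma[b] = np.percentile(vals, _P84, axis=0) - np.median(vals, axis=0)
    counts = np.array([len(c) for c in chunks])
    return QuantileBins(F=F, sigma=sigma, counts=counts, secondaries=secondary_names)


def estimate_sigma0(F: np.ndarray, sigma: np.ndarray) -> tuple[float, float]:
    """OLS of sigma on f_sqrt(F) with intercept; returns (sigma_0, beta).

    sigma_0 is the intercept floored at zero (a standard deviation cannot be
    negative).
    """
    x = f_sqrt(F)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all primary medians equal")
    exog = sm.add_constant(np.asarray(x))
    fit = sm.OLS(np.asarray(sigma, dtype=np.float64), exog).fit()
    intercept, beta = float(fit.params[0]), float(fit.params[1])
    return max(intercept, 0.0), beta


def spreading_coefficient(
    F: np.ndarray, sigma: np.ndarray, sigma0: float, alpha: float = 0.05
) -> tuple[float, str | None]:
    """No-intercept fit of sigma' = f_sqrt(sigma^2 - sigma0^2) on f_sqrt(F).

    Returns (coefficient, zero_reason); reason is None when the coefficient
    is kept, else "nonsignificant" or "negative". Noisy bins can make
    sigma^2 - sigma0^2 negative — the signed transform absorbs them, no bin
    is dropped.
    """
    sigma_adj = f_sqrt(np.asarray(sigma, dtype=np.float64) ** 2 - sigma0**2)
    x = np.asarray(f_sqrt(F))
    if np.all(x == 0) or np.ptp(sigma_adj) == 0 and np.all(sigma_adj == 0):
        return 0.0, "nonsignificant"
    fit = sm.OLS(sigma_adj, x.reshape(-1, 1)).fit()
    coef = float(fit.params[0])
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    if coef <= 0:
        return 0.0, "negative"
    if p >= alpha:
        return 0.0, "nonsignificant"
    return coef, None


def build_ssm(
    controls: ControlSet,
    spillover: SpilloverMatrix,
    alpha: float = 0.05,
    drop_dyes: tuple[str, ...] = (),
) -> SpreadingMatrix:
    """Spillover spreading matrix over all (P, C) dye pairs.

    Controls must be gated; they are compensated here with the converged
    spillover matrix (the SSM is compensation-matrix-dependent). ``drop_dyes``
    removes rows (spread *from* those dyes) from the result, e.g. the
    autofluorescence pseudo-dye.
    """
    dyes = tuple(d for d in spillover.dyes if d not in drop_dyes)
    all_dyes = spillover.dyes
    d = len(all_dyes)
    coef = np.zeros((d, d))
    sigma0_mat = np.zeros((d, d))
    reasons: dict[tuple[str, str], str] = {}
    for i, dye in enumerate(all_dyes):
        if dye in drop_dyes or dye not in controls.tables:
            continue
        comp = compensate_table(controls.tables[dye], spillover)
        primary = comp.column(dye)
        sec_names = tuple(n for n in all_dyes if n != dye)
        sec_idx = [all_dyes.index(n) for n in sec_names]
        bins = partition_quantiles(primary, comp.values[:, sec_idx], sec_names)
        for col, (name, j) in enumerate(zip(sec_names, sec_idx)):
            sigma = bins.sigma[:, col]
            sigma0, _ = estimate_sigma0(bins.F, sigma)
            ss, reason = spreading_coefficient(bins.F, sigma, sigma0, alpha)
            coef[i, j] = ss
            sigma0_mat[i, j] = sigma0
            if reason is not None:
                reasons[(dye, name)] = reason
    keep = [all_dyes.index(dye) for dye in dyes]
    return SpreadingMatrix(
        coef=coef[np.ix_(keep, keep)],
        dyes=dyes,
        sigma0=sigma0_mat[np.ix_(keep, keep)],
        reasons={k: v for k, v in reasons.items() if k[0] in dyes and k[1] in dyes},
    )


def traditional_ssm(
    controls: ControlSet,
    spillover: SpilloverMatrix,
    min_events: int = 10,
    min_separation_sds: float = 5.0,
) -> tuple[SpreadingMatrix, dict[tuple[str, str], str]]:
    """Two-population SSM estimate (comparison oracle).

    SS = sqrt(sigma_pos^2 - sigma_neg^2) / sqrt(F_pos - F_neg) with medians
    for F and robust SDs (P84 - median) for sigma in the 2-means positive and
    negative populations. Entries whose numerator would be imaginary
    (sigma_pos < sigma_neg) are zeroed and flagged; inseparable populations
    flag the whole row.
    """
    all_dyes = spillover.dyes
    d = len(all_dyes)
    coef = np.zeros((d, d))
    flags: dict[tuple[str, str], str] = {}
    for i, dye in enumerate(all_dyes):
        if dye not in controls.tables:
            continue
        comp = compensate_table(controls.tables[dye], spillover)
        primary = comp.column(dye)
        pos = _split_positive_negative(primary)
        if not _populations_distinct(primary, pos, min_events, min_separation_sds):
            for other in all_dyes:
                if other != dye:
                    flags[(dye, other)] = "inseparable"
            continue
        f_pos = float(np.median(primary[pos]))
        f_neg = float(np.median(primary[~pos]))
        for j, other in enumerate(all_dyes):
            if other == dye:
                continue
            v = comp.column(other)
            s_pos = np.percentile(v[pos], _P84) - np.median(v[pos])
            s_neg = np.percentile(v[~pos], _P84) - np.median(v[~pos])
            if s_pos < s_neg:
                flags[(dye, other)] = "imaginary"
                continue
            coef[i, j] = np.sqrt(s_pos**2 - s_neg**2) / np.sqrt(f_pos - f_neg)
    return (
        SpreadingMatrix(coef=coef, dyes=all_dyes, sigma0=np.zeros((d, d))),
        flags,
    )
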