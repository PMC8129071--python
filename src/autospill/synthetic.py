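"""Synthetic single-color control panels with known ground truth.

The generator emulates the statistical structure of real compensation
controls that the estimation pipeline assumes:

* row-normalized Gaussian-bump emission spectra over detector index, each
  with a unique primary detector;
* fluorescence intensity distributions per dye — ``bimodal`` (a negative
  population at zero plus a log-normal positive), ``smear`` (a single
  log-normal tail with no distinct positive population) and ``dim`` (low
  intensity) — covering the population shapes a robust-regression estimator
  must handle and a two-population estimator cannot always;
* heteroskedastic, photon-counting-like detector noise with per-detector
  variance a*|mean| + b (shot-noise gain a, electronic floor b), Gaussian,
  so negative observed values occur near zero as in real area parameters;
* cellular autofluorescence: one fixed spectrum scaled per event by a
  log-normal brightness factor, recorded like any other signal — the main
  real-data artifact that biases per-row initial spillover estimates and
  gives the iterative refinement real work to do (the brightest
  autofluorescence channel is left free of dyes so the unstained control can
  be folded in as an extra dye);
* forward/side scatter with a compact main cell/bead cluster and a debris
  cluster near the origin. Clusters are elliptical generalized-Gaussian
  clouds (radial density ~ exp(-r^p), p = 2.5 by default): unimodal with one
  clear density peak like real cell/bead scatter blobs, but with shorter
  shoulders than a Gaussian. The exponent stays moderate so the density
  surface keeps a genuine gradient everywhere — a flat-topped cluster has no
  stable unique maximum under kernel-density sampling noise.

Everything is reproducible bit-for-bit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _fcs
from .io import ControlSet, EventTable, SpilloverMatrix

__all__ = [
    "SyntheticPanelSpec",
    "PanelTruth",
    "ControlTruth",
    "generate_control",
    "generate_panel",
    "generate_spread_pair",
    "write_fixture_fcs",
    "analytic_spreading",
]

UNSTAINED = "unstained"


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of a synthetic control panel.

    Defaults describe the standard test condition: an 8-detector panel of 7
    exogenous dyes plus autofluorescence on the free eighth channel, 20,000
    events per control, shot-noise gain 0.05 with an electronic floor, a
    moderately autofluorescent cell type, and 20% debris.
    """

    n_dyes: int = 7
    n_detectors: int = 8
    spillover_amplitude: float = 0.3
    spillover_width: float = 1.1
    intensity_models: tuple[str, ...] | None = None
    positive_median: float = 20_000.0
    positive_log_sigma: float = 0.5
    smear_median: float = 3_000.0
    smear_log_sigma: float = 1.2
    dim_median: float = 800.0
    dim_log_sigma: float = 0.6
    negative_fraction: float = 0.5  # of events in a bimodal control
    shot_noise: float = 0.05  # a: detector variance gain per unit signal
    noise_floor: float = 400.0  # b: electronic variance at zero signal
    autofluorescence: bool = True
    af_peak: float = 3_000.0
    af_profile_base: float = 0.2
    af_profile_decay: float = 4.0
    af_log_sigma: float = 0.7
    cell_center: tuple[float, float] = (60_000.0, 35_000.0)
    cell_axes: tuple[float, float] = (15_000.0, 10_000.0)
    debris_center: tuple[float, float] = (2_500.0, 1_800.0)
    debris_axes: tuple[float, float] = (2_000.0, 1_400.0)
    scatter_shape: float = 2.5  # generalized-Gaussian exponent p of the clusters
    debris_fraction: float = 0.2
    n_events: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyes < 1 or self.n_dyes > self.n_detectors:
            raise ValueError("need 1 <= n_dyes <= n_detectors")
        if self.autofluorescence and self.n_dyes >= self.n_detectors:
            raise ValueError("autofluorescence needs one free detector")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris fraction must lie in [0, 1)")
        if self.shot_noise < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be nonnegative")
        models = self.intensity_models
        if models is None:
            cycle = ("bimodal", "bimodal", "smear", "bimodal", "dim")
            models = tuple(cycle[i % len(cycle)] for i in range(self.n_dyes))
            object.__setattr__(self, "intensity_models", models)
        if len(models) != self.n_dyes or not set(models) <= {"bimodal", "smear", "dim"}:
            raise ValueError("one intensity model per dye, from bimodal/smear/dim")

    # -- derived ground truth ------------------------------------------------

    @property
    def detector_names(self) -> tuple[str, ...]:
        fl = tuple(f"FL{i + 1}-A" for i in range(self.n_detectors))
        return fl + ("FSC-A", "SSC-A")

    @property
    def af_channel(self) -> int:
        return self.n_detectors - 1

    def spectra(self) -> np.ndarray:
        """(d, c) true dye spectra, row-normalized with S[i, i] = 1."""
        d, c = self.n_dyes, self.n_detectors
        j = np.arange(c)
        rows = []
        for i in range(d):
            row = self.spillover_amplitude * np.exp(
                -((j - i) ** 2) / (2.0 * self.spillover_width**2)
            )
            row[i] = 1.0
            rows.append(row)
        return np.array(rows)

    def af_vector(self) -> np.ndarray:
        """(c,) mean autofluorescence signal per detector (peak on the free
        channel, decaying but non-vanishing across the rest)."""
        c = self.n_detectors
        dist = np.abs(np.arange(c) - self.af_channel)
        profile = self.af_profile_base + (1 - self.af_profile_base) * np.exp(
            -dist / self.af_profile_decay
        )
        return self.af_peak * profile

    def true_spillover(self) -> SpilloverMatrix:
        """Ground-truth spillover matrix (with the AF row when enabled)."""
        channels = tuple(f"FL{i + 1}-A" for i in range(self.n_detectors))
        coef = self.spectra()
        dyes = [f"dye{i + 1}" for i in range(self.n_dyes)]
        primary = {dye: i for i, dye in enumerate(dyes)}
        if self.autofluorescence:
            af = self.af_vector()
            coef = np.vstack([coef, af / af[self.af_channel]])
            dyes.append("AF")
            primary["AF"] = self.af_channel
        return SpilloverMatrix(coef, tuple(dyes), channels, primary)


@dataclass(frozen=True)
class ControlTruth:
    """Ground truth for one generated control."""

    x: np.ndarray  # true dye abundance per event (0 for unstained)
    af_scale: np.ndarray  # per-event autofluorescence brightness factor
    debris: np.ndarray  # boolean: event belongs to the debris cluster


@dataclass(frozen=True)
class PanelTruth:
    spec: SyntheticPanelSpec
    controls: ControlSet
    spillover: SpilloverMatrix  # includes the AF row when AF is enabled
    spreading: np.ndarray  # analytic SS ground truth, rows/cols as spillover.dyes
    truths: dict[str, ControlTruth] = field(default_factory=dict)


def _scatter_cloud(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    axes: tuple[float, float],
    shape: float,
) -> np.ndarray:
    # elliptical super-Gaussian: radial density ~ exp(-r^p); radius drawn as
    # Gamma(2/p)^(1/p), direction uniform
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    radius = rng.gamma(2.0 / shape, 1.0, n) ** (1.0 / shape)
    return np.column_stack(
        [
            center[0] + axes[0] * radius * np.cos(theta),
            center[1] + axes[1] * radius * np.sin(theta),
        ]
    )


def _draw_intensity(
    rng: np.random.Generator, spec: SyntheticPanelSpec, model: str, n: int
) -> np.ndarray:
    if model == "bimodal":
        x = np.exp(rng.normal(np.log(spec.positive_median), spec.positive_log_sigma, n))
        x[rng.uniform(size=n) < spec.negative_fraction] = 0.0
        return x
    if model == "smear":
        return np.exp(rng.normal(np.log(spec.smear_median), spec.smear_log_sigma, n))
    if model == "dim":
        return np.exp(rng.normal(np.log(spec.dim_median), spec.dim_log_sigma, n))
    raise ValueError(f"unknown intensity model {model!r}")


def generate_control(
    spec: SyntheticPanelSpec, dye: int | str
) -> tuple[EventTable, ControlTruth]:
    """One synthetic control: dye index 0..d-1 or ``"unstained"``.

    Observed fluorescence is x * S_true + af_scale * af + noise; debris
    events carry no dye, reduced autofluorescence, and near-origin scatter.
    Deterministic for a fixed spec (the per-control random stream derives
    from (seed, control)).
    """
    if dye == UNSTAINED:
        stream = spec.n_dyes
    else:
        stream = int(dye)
        if not 0 <= stream < spec.n_dyes:
            raise ValueError(f"dye index out of range: {dye}")
    rng = np.random.default_rng([spec.seed, stream])
    n = spec.n_events
    c = spec.n_detectors

    debris = rng.uniform(size=n) < spec.debris_fraction
    n_debris = int(debris.sum())

    x = np.zeros(n)
    if dye != UNSTAINED:
        x[~debris] = _draw_intensity(
            rng, spec, spec.intensity_models[int(dye)], n - n_debris
        )

    af_scale = np.zeros(n)
    if spec.autofluorescence:
        sigma = spec.af_log_sigma
        af_scale = np.exp(rng.normal(-0.5 * sigma**2, sigma, n))
        af_scale[debris] *= 0.3  # debris autofluoresces weakly

    spectra = spec.spectra()
    row = spectra[int(dye)] if dye != UNSTAINED else np.zeros(c)
    mean = np.outer(x, row)
    if spec.autofluorescence:
        mean += np.outer(af_scale, spec.af_vector())
    sd = np.sqrt(spec.shot_noise * np.abs(mean) + spec.noise_floor)
    fluor = mean + rng.standard_normal((n, c)) * sd

    scatter = np.empty((n, 2))
    scatter[~debris] = _scatter_cloud(
        rng, n - n_debris, spec.cell_center, spec.cell_axes, spec.scatter_shape
    )
    scatter[debris] = _scatter_cloud(
        rng, n_debris, spec.debris_center, spec.debris_axes, spec.scatter_shape
    )

    table = EventTable(
        np.hstack([fluor, scatter]),
        spec.detector_names,
        scatter_channels=("FSC-A", "SSC-A"),
    )
    return table, ControlTruth(x=x, af_scale=af_scale, debris=debris)


def analytic_spreading(
    spillover: np.ndarray, shot_noise: float
) -> np.ndarray:
    """Ground-truth spreading coefficients implied by the noise model.

    Compensation solves x S = y; with per-detector noise variance
    a * mean_k + b and mean_k = F * S[P, k] at primary level F, the
    compensated secondary C has conditional variance
    sum_k (a F S[P,k] + b) W[k,C]^2 with W the (pseudo)inverse of S, i.e.
    sigma^2 = SS^2 F + sigma_0^2 with SS_C^P = sqrt(a sum_k S[P,k] W[k,C]^2).
    """
    s = np.asarray(spillover, dtype=np.float64)
    w = np.linalg.pinv(s)
    d = s.shape[0]
    ss = np.zeros((d, d))
    for p in range(d):
        for ch in range(d):
            if ch == p:
                continue
            ss[p, ch] = np.sqrt(shot_noise * np.dot(s[p], w[:, ch] ** 2))
    return ss


def generate_panel(spec: SyntheticPanelSpec) -> PanelTruth:
    """Full panel: one control per dye, an unstained control, and all truth."""
    dyes = [f"dye{i + 1}" for i in range(spec.n_dyes)]
    tables: dict[str, EventTable] = {}
    truths: dict[str, ControlTruth] = {}
    for i, dye in enumerate(dyes):
        tables[dye], truths[dye] = generate_control(spec, i)
    unstained, truths[UNSTAINED] = generate_control(spec, UNSTAINED)
    primaries = {dye: f"FL{i + 1}-A" for i, dye in enumerate(dyes)}
    controls = ControlSet(
        dyes=dyes,
        tables=tables,
        primaries=primaries,
        unstained=unstained,
        detectors=spec.detector_names,
    )
    spill = spec.true_spillover()
    spreading = analytic_spreading(spill.coef, spec.shot_noise)
    return PanelTruth(
        spec=spec, controls=controls, spillover=spill, spreading=spreading, truths=truths
    )


def generate_spread_pair(
    ss_true: float,
    sigma0: float,
    n_events: int = 50_000,
    seed: int = 0,
    spill: float = 0.5,
) -> tuple[ControlSet, SpilloverMatrix]:
    """Two-channel calibration fixture with exact spreading ground truth.

    Channel P spills ``spill`` into channel C; the shot-noise gain and floor
    are solved from the requested SS and sigma_0 (see
    :func:`analytic_spreading`): a = SS^2 / (spill (1 + spill)) and
    b = sigma_0^2 / (1 + spill^2). The primary intensity is bimodal with half
    the events negative at zero — the near-zero population that pins the
    noise-floor regression.
    """
    if not 0 < spill < 1:
        raise ValueError("spill must lie in (0, 1)")
    a = ss_true**2 / (spill * (1.0 + spill))
    b = sigma0**2 / (1.0 + spill**2)
    s_true = np.array([[1.0, spill], [0.0, 1.0]])
    rng = np.random.default_rng([seed, 977])
    names = ("P-A", "C-A")
    tables = {}
    for row, dye in enumerate(("P", "C")):
        x = np.exp(rng.normal(np.log(20_000.0), 0.5, n_events))
        x[rng.uniform(size=n_events) < 0.5] = 0.0
        mean = np.outer(x, s_true[row])
        sd = np.sqrt(a * np.abs(mean) + b)
        tables[dye] = EventTable(
            mean + rng.standard_normal((n_events, 2)) * sd, names
        )
    matrix = SpilloverMatrix(s_true, ("P", "C"), names, {"P": 0, "C": 1})
    controls = ControlSet(
        dyes=["P", "C"],
        tables=tables,
        primaries={"P": "P-A", "C": "C-A"},
        detectors=names,
    )
    return controls, matrix


def write_fixture_fcs(table: EventTable, path: str | Path) -> None:
    """Write a fixture control as a minimal FCS 3.1 file."""
    if table.n_events < 1:
        raise ValueError("cannot write an empty event table")
    _fcs.write_fcs(path, table.values, list(table.detector_names))
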