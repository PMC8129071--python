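"""Model/Results interface tying the pipeline together.

:class:`SpilloverModel` holds a set of single-color controls plus the
configuration; ``fit()`` gates the controls, optionally folds in the
unstained control as an autofluorescence dye, computes the robust initial
spillover estimate and refines it to convergence, returning a
:class:`SpilloverResults` with the matrix, the convergence trace, the final
compensation errors and the compensated controls. :class:`SpreadingModel`
does the same for the spillover spreading matrix given a fitted (or
externally supplied) spillover matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating as _gating
from .autofluorescence import AF_DYE_NAME, augment_with_af
from .io import (
    AUTO,
    CompensationErrorMatrix,
    ControlSet,
    ConvergenceTrace,
    EventTable,
    SpilloverMatrix,
    write_spillover_csv,
    write_trace,
)
from .spillover import (
    RefinementConfig,
    compensation_errors,
    initial_spillover,
    refine_until_convergence,
    resolve_primaries,
)
from .spread import SpreadingMatrix, build_ssm

__all__ = ["SpilloverModel", "SpilloverResults", "SpreadingModel", "SpreadingResults"]


class SpilloverModel:
    """Spillover estimation from a set of single-color controls.

    Parameters
    ----------
    controls
        Raw or pre-gated controls (one per dye, optional unstained).
    config
        Refinement thresholds; defaults are the published operating points.
    gate
        Run the automated scatter gate on every control first. Disable for
        pre-gated or scatter-free data.
    autofluorescence
        Fold the unstained control in as an extra "AF" dye on ``af_channel``
        (default: the free detector with the highest unstained signal).
    """

    def __init__(
        self,
        controls: ControlSet,
        config: RefinementConfig | None = None,
        gate: bool = True,
        gating_config: "_gating.GatingConfig | None" = None,
        autofluorescence: bool = False,
        af_channel: str = AUTO,
    ) -> None:
        self.controls = controls
        self.config = config or RefinementConfig()
        self.gate = gate
        self.gating_config = gating_config or _gating.GatingConfig()
        self.autofluorescence = autofluorescence
        self.af_channel = af_channel
        if autofluorescence and controls.unstained is None:
            raise ValueError(
                "autofluorescence removal requested but the control set has "
                "no unstained control"
            )

    def fit(self) -> "SpilloverResults":
        controls = self.controls
        gates: dict[str, _gating.GateResult] = {}
        if self.gate:
            def _gate(table: EventTable) -> EventTable:
                return _gating.compute_gate(table, self.gating_config).gated

            gated_tables = {}
            for dye in controls.dyes:
                result = _gating.compute_gate(controls.tables[dye], self.gating_config)
                gates[dye] = result
                gated_tables[dye] = result.gated
            unstained = controls.unstained
            if unstained is not None:
                result = _gating.compute_gate(unstained, self.gating_config)
                gates["unstained"] = result
                unstained = result.gated
            controls = ControlSet(
                dyes=list(controls.dyes),
                tables=gated_tables,
                primaries=dict(controls.primaries),
                unstained=unstained,
                detectors=tuple(controls.detectors),
            )
        controls = resolve_primaries(controls)
        if self.autofluorescence:
            controls = augment_with_af(controls, channel=self.af_channel)
        initial = initial_spillover(controls, k=self.config.huber_k)
        final, trace, compensated = refine_until_convergence(
            controls, initial, self.config
        )
        errors = trace.final_errors
        if errors is None:  # pragma: no cover - loop always records at least once
            errors = compensation_errors(compensated, final.dyes, k=self.config.huber_k)
        return SpilloverResults(
            model=self,
            gated_controls=controls,
            spillover=final,
            initial_spillover=initial,
            trace=trace,
            errors=errors,
            compensated=compensated,
            transforms=trace.transforms,
            gates=gates,
        )


@dataclass
class SpilloverResults:
    """Converged spillover matrix with diagnostics."""

    model: SpilloverModel
    gated_controls: ControlSet
    spillover: SpilloverMatrix
    initial_spillover: SpilloverMatrix
    trace: ConvergenceTrace
    errors: CompensationErrorMatrix
    compensated: dict[str, EventTable]
    transforms: dict | None = None  # per-dye biexp transforms at the final iteration
    gates: dict[str, "_gating.GateResult"] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.trace.status == "converged"

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    def summary(self) -> str:
        rows = []
        for dye in self.gated_controls.dyes:
            rows.append(
                {
                    "dye": dye,
                    "primary": self.gated_controls.primaries[dye],
                    "events": self.gated_controls.tables[dye].n_events,
                }
            )
        frame = pd.DataFrame(rows)
        last = self.trace.records[-1]
        lines = [
            "Spillover estimation results",
            "=" * 60,
            frame.to_string(index=False),
            "-" * 60,
            f"status:            {self.trace.status}",
            f"iterations:        {self.n_iterations}",
            f"final scale:       {last.scale}",
            f"final max |error|: {last.max_abs_error:.3e}",
            f"final sd(error):   {last.sd_error:.3e}",
        ]
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Write spillover CSV and convergence trace TSV into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_spillover_csv(self.spillover, directory / "spillover.csv")
        write_trace(self.trace, directory / "convergence.tsv")


class SpreadingModel:
    """Spillover spreading matrix from compensated single-color controls.

    Needs the gated controls and a converged spillover matrix (the SSM is
    compensation-matrix-dependent); spread *from* the autofluorescence
    pseudo-dye is dropped by default.
    """

    def __init__(
        self,
        controls: ControlSet,
        spillover: SpilloverMatrix,
        alpha: float = 0.05,
        drop_af_row: bool = True,
    ) -> None:
        missing = [d for d in controls.dyes if d not in spillover.dyes]
        if missing:
            raise ValueError(f"controls without a spillover row: {missing}")
        self.controls = controls
        self.spillover = spillover
        self.alpha = alpha
        self.drop_af_row = drop_af_row

    @classmethod
    def from_results(
        cls, results: SpilloverResults, alpha: float = 0.05, drop_af_row: bool = True
    ) -> "SpreadingModel":
        return cls(
            results.gated_controls, results.spillover, alpha=alpha, drop_af_row=drop_af_row
        )

    def fit(self) -> "SpreadingResults":
        drop = (AF_DYE_NAME,) if self.drop_af_row else ()
        ssm = build_ssm(self.controls, self.spillover, alpha=self.alpha, drop_dyes=drop)
        return SpreadingResults(model=self, ssm=ssm)


@dataclass
class SpreadingResults:
    model: SpreadingModel
    ssm: SpreadingMatrix

    def summary(self) -> str:
        zeroed = ", ".join(
            f"{p}->{c} ({reason})" for (p, c), reason in sorted(self.ssm.reasons.items())
        )
        lines = [
            "Spillover spreading matrix",
            "=" * 60,
            self.ssm.to_frame().round(4).to_string(),
            "-" * 60,
            f"zeroed entries: {zeroed or 'none'}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        frame = self.ssm.to_frame()
        frame.index.name = "dye"
        frame.to_csv(path)
        sidecar = Path(path).with_suffix(".reasons.tsv")
        with open(sidecar, "w") as fh:
            fh.write("primary\tsecondary\treason\n")
            for (p, c), reason in sorted(self.ssm.reasons.items()):
                fh.write(f"{p}\t{c}\t{reason}\n")
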