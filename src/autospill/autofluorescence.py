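"""Autofluorescence removal by treating it as an endogenous dye.

Cells fluoresce on their own; in an unstained control this endogenous signal
behaves exactly like spillover from a dye without distinct positive and
negative populations. The unstained control is therefore folded into the
control set as one extra dye ("AF") whose primary is a free detector — one
not assigned to any real dye, preferably the channel with the highest
unstained signal (the most autofluorescent channel is sacrificed to clean up
all the others). Downstream spillover estimation and refinement need no
changes; compensating with the augmented matrix assigns the autofluorescence
component of every event to the AF dye column, which is then discarded.

This models a single autofluorescence spectrum with per-cell brightness
variation. Samples mixing cell types with *qualitatively* different spectra
are outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AUTO, AutospillError, ControlSet, EventTable

__all__ = ["AF_DYE_NAME", "AutofluorescenceSpec", "NoFreeDetectorError",
           "select_af_channel", "augment_with_af"]

#: Name under which the autofluorescence pseudo-dye is appended.
AF_DYE_NAME = "AF"


class NoFreeDetectorError(AutospillError):
    """Every fluorescence detector is already a dye primary."""


@dataclass(frozen=True)
class AutofluorescenceSpec:
    unstained_control_id: str = ""
    dummy_detector: str = AUTO


def select_af_channel(
    unstained: EventTable, used_primaries: set[str], requested: str = AUTO
) -> str:
    """Free detector carrying the autofluorescence pseudo-dye.

    ``AUTO`` picks the unassigned fluorescence detector with the highest
    median signal in the unstained control; an explicit name is honored after
    checking it exists and is not a real dye's primary.
    """
    names = unstained.fluorescence_names()
    if requested != AUTO:
        if requested not in names:
            from .io import DetectorNotFoundError

            raise DetectorNotFoundError(requested)
        if requested in used_primaries:
            raise ValueError(
                f"detector {requested!r} is already the primary of a dye"
            )
        return requested
    free = [n for n in names if n not in used_primaries]
    if not free:
        raise NoFreeDetectorError("no fluorescence detector left for autofluorescence")
    medians = {n: float(np.median(unstained.column(n))) for n in free}
    return max(free, key=lambda n: (medians[n], -names.index(n)))


def augment_with_af(
    controls: ControlSet, channel: str = AUTO, dye_name: str = AF_DYE_NAME
) -> ControlSet:
    """Control set with the unstained control appended as the AF dye."""
    if controls.unstained is None:
        raise ValueError("autofluorescence removal requires an unstained control")
    if dye_name in controls.dyes:
        raise ValueError(f"dye name {dye_name!r} already present")
    used = {
        controls.primaries[dye]
        for dye in controls.dyes
        if controls.primaries[dye] != AUTO
    }
    af_channel = select_af_channel(controls.unstained, used, channel)
    dyes = list(controls.dyes) + [dye_name]
    tables = dict(controls.tables)
    tables[dye_name] = controls.unstained
    primaries = dict(controls.primaries)
    primaries[dye_name] = af_channel
    return ControlSet(
        dyes=dyes,
        tables=tables,
        primaries=primaries,
        unstained=controls.unstained,
        detectors=tuple(controls.detectors),
    )
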