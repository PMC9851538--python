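"""Mito-stress-test parameter extraction and RT-QuIC seeding calls.

Seahorse traces measure the oxygen consumption rate (OCR) at baseline and
after sequential injection of oligomycin (ATP-synthase inhibitor), FCCP
(uncoupler) and rotenone/antimycin A (complex I/III inhibitors). The
standard parameters are:

* non-mitochondrial respiration — mean OCR after rotenone/antimycin A;
* basal respiration — last baseline reading minus non-mito;
* maximal respiration — highest post-FCCP reading minus non-mito;
* ATP-linked respiration — last baseline reading minus the lowest
  post-oligomycin reading.

RT-QuIC plates record thioflavin-T fluorescence of replicate wells over
time (reads every 45 min). A sample is called positive for seeding
activity when strictly more than 25% of its replicate wells exceed 10% of
the maximum value on the plate before the assay horizon (40 h by
default; the tau assay preset runs to 50 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import DataQualityError, ParameterError

CANONICAL_INJECTIONS = ("oligomycin", "fccp", "rotenone_antimycin")

#: Per-assay horizon presets (hours).
ASSAY_HORIZONS_H = {"prion": 40.0, "alpha_synuclein": 40.0, "tau": 50.0}


@dataclass
class OCRTrace:
    """An injection-annotated oxygen-consumption time series for one well."""

    times: np.ndarray  # minutes, strictly increasing
    ocr: np.ndarray  # pmol O2 / min
    injections: Sequence[tuple[float, str]]
    protein: float | None = None  # micrograms, optional
    well: str = "well"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.times.shape != self.ocr.shape:
            raise ParameterError("times and ocr must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        labels = [lab for _, lab in self.injections]
        if labels != [l for l in CANONICAL_INJECTIONS if l in labels]:
            raise ParameterError(
                f"injections must follow the canonical order {CANONICAL_INJECTIONS}, "
                f"got {labels}"
            )
        inj_times = [t for t, _ in self.injections]
        if any(b <= a for a, b in zip(inj_times, inj_times[1:])):
            raise ParameterError("injection times must be increasing")


@dataclass
class MitoStressParams:
    """Extracted mito-stress-test parameters (pmol O2/min per well).

    Negative derived rates are reported as-is and flagged, never clipped.
    When normalized to protein the units become pmol/min/ug.
    """

    non_mito: float
    basal: float
    maximal: float
    atp_linked: float
    normalized: bool = False
    units: str = "pmol/min"
    flags: list[str] = field(default_factory=list)


def _phase_slices(trace: OCRTrace) -> dict[str, np.ndarray]:
    t = trace.times
    inj = {lab: when for when, lab in trace.injections}
    for lab in CANONICAL_INJECTIONS:
        if lab not in inj:
            raise ParameterError(f"missing injection {lab!r}")
    phases = {
        "baseline": (t < inj["oligomycin"]),
        "oligomycin": (t >= inj["oligomycin"]) & (t < inj["fccp"]),
        "fccp": (t >= inj["fccp"]) & (t < inj["rotenone_antimycin"]),
        "rotenone_antimycin": t >= inj["rotenone_antimycin"],
    }
    for name, mask in phases.items():
        if not mask.any():
            raise DataQualityError(f"no OCR readings in the {name} phase")
    return phases


def mito_stress_params(trace: OCRTrace) -> MitoStressParams:
    """Extract non-mito, basal, maximal and ATP-linked respiration.

    Basal uses the last baseline reading (the convention the assay
    schematic depicts), maximal the highest post-FCCP reading, ATP-linked
    the drop from the last baseline reading to the lowest
    post-oligomycin reading; all but ATP-linked are corrected for
    non-mitochondrial respiration (mean after rotenone/antimycin A).
    """
    phases = _phase_slices(trace)
    ocr = trace.ocr
    non_mito = float(ocr[phases["rotenone_antimycin"]].mean())
    last_baseline = float(ocr[phases["baseline"]][-1])
    basal = last_baseline - non_mito
    maximal = float(ocr[phases["fccp"]].max()) - non_mito
    atp_linked = last_baseline - float(ocr[phases["oligomycin"]].min())

    flags = [
        f"negative {name}"
        for name, v in (
            ("basal", basal),
            ("maximal", maximal),
            ("atp_linked", atp_linked),
        )
        if v < 0
    ]
    if maximal < basal:
        flags.append("no spare capacity (maximal < basal)")
    return MitoStressParams(
        non_mito=non_mito,
        basal=basal,
        maximal=maximal,
        atp_linked=atp_linked,
        flags=flags,
    )


def normalize_to_protein(params: MitoStressParams, protein: float) -> MitoStressParams:
    """Divide every rate by the well's total protein (ug)."""
    if params.normalized:
        raise ParameterError("parameters are already protein-normalized")
    if protein <= 0:
        raise ParameterError(f"protein must be > 0 ug, got {protein}")
    return replace(
        params,
        non_mito=params.non_mito / protein,
        basal=params.basal / protein,
        maximal=params.maximal / protein,
        atp_linked=params.atp_linked / protein,
        normalized=True,
        units="pmol/min/ug",
    )


# --------------------------------------------------------------------------
# RT-QuIC
# --------------------------------------------------------------------------


@dataclass
class QuICPlate:
    """Replicate ThT fluorescence curves for one plate.

    ``fluorescence``: wells x timepoints (arbitrary units); ``times_h``:
    hours, uniform at ``cadence_min``; ``replicate_map``: sample (or
    sample/dilution) id -> row indices of its replicate wells.
    """

    fluorescence: np.ndarray
    times_h: np.ndarray
    replicate_map: Mapping[str, Sequence[int]]
    cadence_min: float = 45.0

    def __post_init__(self) -> None:
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.fluorescence.shape[1] != self.times_h.size:
            raise ParameterError("fluorescence columns must match times_h")
        if len(self.replicate_map) < 1:
            raise ParameterError("replicate_map must define at least one group")
        steps = np.diff(self.times_h)
        if steps.size and not np.allclose(steps, self.cadence_min / 60.0, rtol=1e-6):
            raise ParameterError(
                f"timepoints are not uniform at {self.cadence_min} min cadence"
            )


@dataclass(frozen=True)
class SeedingCall:
    """Positivity call for one sample/dilution."""

    sample_id: str
    n_replicates: int
    n_positive_wells: int
    positive: bool
    threshold_value: float


def call_seeding(
    plate: QuICPlate,
    frac_of_max: float = 0.10,
    well_frac: float = 0.25,
    horizon_h: float = 40.0,
    baseline_subtract: bool = True,
) -> list[SeedingCall]:
    """Call seeding activity per replicate group.

    The threshold is ``frac_of_max`` x the maximum fluorescence anywhere
    on the plate before ``horizon_h``; a well is positive when any
    reading before the horizon strictly exceeds it, and a sample is
    positive when the positive fraction of its replicates strictly
    exceeds ``well_frac``. By default each well's initial reading is
    subtracted first so the rule responds to fluorescence increase above
    background rather than to the background itself; set
    ``baseline_subtract=False`` to apply the rule to raw signal.
    """
    if plate.fluorescence.size == 0:
        raise ParameterError("empty plate")
    if horizon_h > plate.times_h[-1] + plate.cadence_min / 60.0:
        raise ParameterError(
            f"horizon {horizon_h} h exceeds the recorded span "
            f"{plate.times_h[-1]:g} h"
        )
    window = plate.times_h < horizon_h
    fluor = plate.fluorescence
    if baseline_subtract:
        fluor = fluor - fluor[:, :1]
    in_window = fluor[:, window]
    threshold = frac_of_max * float(in_window.max())
    well_positive = (in_window > threshold).any(axis=1)

    calls = []
    for sample_id, wells in plate.replicate_map.items():
        wells = list(wells)
        n_pos = int(well_positive[wells].sum())
        calls.append(
            SeedingCall(
                sample_id=sample_id,
                n_replicates=len(wells),
                n_positive_wells=n_pos,
                positive=n_pos / len(wells) > well_frac,
                threshold_value=threshold,
            )
        )
    return calls
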