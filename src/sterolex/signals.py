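"""Fluorescence signal conversion and initial-velocity extraction.

The assays monitor either FRET from a fluorescent sterol (DHE) to a dansyl
lipid in the donor liposome, or quenching of an NBD-labelled
phosphoinositide sensor.  Every conversion is anchored by two calibration
signals: a floor ``F0`` (ligand-free or fully-bound control) and a
reference ``Fref`` (the pre-injection maximum ``F_max``, or the
full-equilibration control ``F_eq`` for the phosphoinositide transport
assay).  All conversions work elementwise on scalars or arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AssayKind",
    "FluorescenceCalibration",
    "FluorescenceTrace",
    "VelocityEstimate",
    "normalized_ratio",
    "binding_percent",
    "dhe_transport_amount",
    "pip_transport_amount",
    "initial_velocity",
    "background_subtract",
    "fold_stimulation",
    "default_window",
]

ASSAY_KINDS = ("dhe_binding", "pip_binding", "dhe_transport", "pip_transport")
AssayKind = str


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Signal anchors converting raw fluorescence to fractions/concentrations.

    Parameters
    ----------
    f0:
        Signal floor (a.u.): the methyl-β-cyclodextrin control for sterol
        binding, the sensor-off-liposome control for PIP binding, the
        cargo-free donor for transport.
    fref:
        Reference signal (a.u.): ``F_max`` recorded before protein injection,
        or ``F_eq`` (sensor signal with ligand fully equilibrated between
        liposome populations) for the PIP transport assay.
    accessible_ligand:
        Accessible ligand concentration in the assay, μM.
    assay_kind:
        One of ``dhe_binding | pip_binding | dhe_transport | pip_transport``.
    """

    f0: float
    fref: float
    accessible_ligand: float
    assay_kind: AssayKind

    def __post_init__(self) -> None:
        if self.fref == self.f0:
            raise ValueError("degenerate calibration: fref == f0")
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(
                f"unknown assay_kind {self.assay_kind!r}; expected one of {ASSAY_KINDS}"
            )
        if self.accessible_ligand < 0:
            raise ValueError("accessible_ligand must be >= 0")


@dataclass(frozen=True)
class FluorescenceTrace:
    """A timestamped fluorescence (or concentration) progress curve."""

    times: np.ndarray  # seconds, strictly increasing
    signal: np.ndarray  # a.u. (or μM once converted)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("trace needs >= 2 samples")
        if signal.shape != times.shape:
            raise ValueError("times and signal must have the same length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_signal(self, signal: np.ndarray, **meta) -> "FluorescenceTrace":
        return FluorescenceTrace(self.times, signal, {**self.metadata, **meta})


def normalized_ratio(f, cal: FluorescenceCalibration, clip: bool = False):
    """``(F − F0) / (Fref − F0)``, the normalized signal.

    Not clipped by default — noisy input may leave [0, 1] and clipping would
    bias velocity estimates near t = 0; pass ``clip=True`` to clamp.
    """
    ratio = (np.asarray(f, dtype=float) - cal.f0) / (cal.fref - cal.f0)
    if clip:
        ratio = np.clip(ratio, 0.0, 1.0)
    return ratio if np.ndim(f) else float(ratio)


def binding_percent(f, cal: FluorescenceCalibration, clip: bool = False):
    """Percent of accessible ligand bound: ``100 × (1 − (F − F0)/(Fmax − F0))``.

    F0 is the complete-binding control (e.g. cyclodextrin-extracted sterol),
    so F = F0 means 100% bound and F = Fmax means none.
    """
    if cal.assay_kind not in ("dhe_binding", "pip_binding"):
        raise ValueError(
            f"binding_percent applies to binding assays, not {cal.assay_kind!r}"
        )
    out = 100.0 * (1.0 - normalized_ratio(f, cal, clip=clip))
    return out if np.ndim(f) else float(out)


def dhe_transport_amount(
    f, cal: FluorescenceCalibration, as_printed: bool = False, clip: bool = False
):
    """μM of sterol that left the FRET donor liposome.

    The FRET ratio ``(F − F0)/(Fmax − F0)`` measures the fraction of sterol
    still on the donor, so the amount transferred is by default
    ``accessible × (1 − ratio)`` — consistent with the binding-assay formula
    and the convention that the FRET *decrease* reports transfer.
    ``as_printed=True`` instead returns ``accessible × ratio``, the literal
    bench-protocol expression (both conventions circulate; the flag makes
    the choice explicit rather than guessing intent).
    """
    if cal.assay_kind != "dhe_transport":
        raise ValueError(
            f"dhe_transport_amount applies to dhe_transport, not {cal.assay_kind!r}"
        )
    ratio = normalized_ratio(f, cal, clip=clip)
    amount = cal.accessible_ligand * (ratio if as_printed else 1.0 - ratio)
    return amount if np.ndim(f) else float(amount)


def pip_transport_amount(f, cal: FluorescenceCalibration, clip: bool = False):
    """μM of phosphoinositide moved to the acceptor liposomes.

    The sensor signal is normalized against the full-equilibration control
    ``F_eq`` (calibration ``fref``); at equilibrium the ligand is split
    evenly, so the transported fraction is ``0.5 × (F − F0)/(F_eq − F0)``
    and the amount is ``accessible × 0.5 × ratio``.
    """
    if cal.assay_kind != "pip_transport":
        raise ValueError(
            f"pip_transport_amount applies to pip_transport, not {cal.assay_kind!r}"
        )
    out = cal.accessible_ligand * 0.5 * normalized_ratio(f, cal, clip=clip)
    return out if np.ndim(f) else float(out)


@dataclass(frozen=True)
class VelocityEstimate:
    """An initial velocity from the linear phase of a progress curve."""

    slope: float  # μM s⁻¹
    intercept: float  # μM
    r_squared: float
    n_points: int
    window: tuple  # (t_start, t_end) seconds


def default_window(times: np.ndarray) -> np.ndarray:
    """Boolean mask for the default early window of a progress curve.

    Earliest 10% of the trace duration, or the first 10 points, whichever
    selects more samples.
    """
    times = np.asarray(times, dtype=float)
    cutoff = times[0] + 0.10 * (times[-1] - times[0])
    mask = times <= cutoff
    if mask.sum() < min(10, times.size):
        mask = np.zeros_like(mask)
        mask[: min(10, times.size)] = True
    return mask


def initial_velocity(
    trace: FluorescenceTrace,
    window: Optional[np.ndarray] = None,
    r2_warn: float = 0.98,
) -> VelocityEstimate:
    """Initial rate (μM s⁻¹) as the least-squares slope of the early window.

    The trace must already be in concentration units.  ``window`` is a
    boolean mask (or index array) over samples; by default the earliest 10%
    of the duration or the first 10 points, whichever is larger.  Emits a
    warning when the linear fit has R² below ``r2_warn`` — the window then
    extends past the linear phase.
    """
    if window is None:
        mask = default_window(trace.times)
    else:
        mask = np.zeros(trace.times.size, dtype=bool)
        mask[np.asarray(window)] = True
    t = trace.times[mask]
    y = trace.signal[mask]
    if t.size < 3:
        raise ValueError(f"initial-velocity window must hold >= 3 points, got {t.size}")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 < r2_warn:
        warnings.warn(
            f"initial-velocity window is not linear (R² = {r2:.4f} < {r2_warn}); "
            "consider a shorter window",
            stacklevel=2,
        )
    return VelocityEstimate(float(slope), float(intercept), r2, int(t.size),
                            (float(t[0]), float(t[-1])))


def background_subtract(v_protein: float, v_blank: float) -> float:
    """Protein-dependent velocity: observed minus the no-protein blank."""
    return v_protein - v_blank


def fold_stimulation(v_condition: float, v_basal: float) -> float:
    """Velocity fold change of a condition over basal (v_basal must be > 0)."""
    if v_basal <= 0:
        raise ValueError(f"basal velocity must be > 0, got {v_basal}")
    return v_condition / v_basal
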