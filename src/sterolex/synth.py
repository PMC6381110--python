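"""Synthetic fluorescence traces and velocity datasets.

The generators emulate the bench assay conditions — 200 μM total lipid
donor liposomes doped with 2.5% DNS-PE and 5% DHE (10 μM accessible
sterol), with or without 4% of a doped phosphoinositide, protein titrated
at 15 °C — so that every analysis stage can be exercised without any
external data.  Noise is multiplicative Gaussian by default
(cv = 0.05, matching the scale of triplicate s.e.m. bars on such assays)
with an optional additive term; every generator is a deterministic
function of (configuration, seed).

Default true parameters for two-condition scenarios: K1 = 0.8 μM,
k+2 = 0.05 s⁻¹ basal and K1* = 0.4 μM, k+2* = 0.1 s⁻¹ stimulated.  These
are synthetic stand-ins embodying the qualitative allosteric effect
(membrane binding tightens, extraction accelerates, second-order
efficiency rises 4-fold) — not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .composition import (
    LipidSpecies,
    LiposomeComposition,
    OUTER_LEAFLET_FRACTION,
    accessible_concentration,
)
from .kinetics import (
    KineticScheme,
    SchemeState,
    Trajectory,
    VelocityModelParams,
    cargo_on_protein,
    quasi_equilibrium_scheme,
    simulate_scheme,
    v0_quadratic,
)
from .signals import FluorescenceCalibration, FluorescenceTrace

__all__ = [
    "NoiseModel",
    "ScenarioConfig",
    "DEFAULT_BASAL",
    "DEFAULT_STIMULATED",
    "donor_liposomes",
    "generate_extraction_trace",
    "generate_velocity_dataset",
    "generate_transport_trace",
]

#: Synthetic two-condition truth: basal and phosphoinositide-stimulated.
#: L0 = 2 μM (a diluted titration, 40 μM total lipid × 5% DHE) keeps the
#: cargo-site pool comparable to K1 so that K1 stays identifiable from the
#: curvature of v0(O0); at the full 10 μM pool binding is near-stoichiometric
#: over the protein grid and K1 is essentially unconstrained by the data.
DEFAULT_BASAL = VelocityModelParams(K1=0.8, k_plus2=0.05, L0=2.0, condition="basal")
DEFAULT_STIMULATED = VelocityModelParams(
    K1=0.4, k_plus2=0.1, L0=2.0, condition="plus_PIP"
)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: y ← y·(1 + ε) + η, ε ~ N(0, cv²), η ~ N(0, sd²)."""

    multiplicative_cv: float = 0.05
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, y: np.ndarray, rng: Optional[np.random.Generator] = None):
        rng = self.rng() if rng is None else rng
        y = np.asarray(y, dtype=float)
        out = y.copy()
        if self.multiplicative_cv > 0:
            out = out * (1.0 + rng.normal(0.0, self.multiplicative_cv, size=y.shape))
        if self.additive_sd > 0:
            out = out + rng.normal(0.0, self.additive_sd, size=y.shape)
        return out


def donor_liposomes(
    total_lipid_uM: float = 200.0,
    dhe_percent: float = 5.0,
    dns_pe_percent: float = 2.5,
    pip_percent: float = 0.0,
    pip_name: str = "PI34P2",
) -> LiposomeComposition:
    """The standard extraction-assay donor recipe.

    DOPC/DOPE (2:1) liposomes doped with a dansyl-PE FRET probe and DHE,
    optionally plus an outer-leaflet phosphoinositide.
    """
    doped = [
        (LipidSpecies("DNS-PE", OUTER_LEAFLET_FRACTION, "fret_probe"), dns_pe_percent),
        (LipidSpecies("DHE", 1.0, "cargo"), dhe_percent),
    ]
    if pip_percent > 0:
        doped.append(
            (LipidSpecies(pip_name, OUTER_LEAFLET_FRACTION, "doped_pip"), pip_percent)
        )
    return LiposomeComposition.from_doping(total_lipid_uM, doped)


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete synthetic assay scenario.

    Defaults reproduce the standard setup: 200 μM total lipid with 5% DHE
    (10 μM accessible cargo sites), protein titrated over a grid bracketing
    K1, traces sampled at 1 Hz over 600 s at 15 °C.
    """

    composition: LiposomeComposition = field(default_factory=donor_liposomes)
    protein_grid: tuple = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)  # μM
    basal: VelocityModelParams = DEFAULT_BASAL
    stimulated: VelocityModelParams = DEFAULT_STIMULATED
    duration_s: float = 600.0
    sampling_hz: float = 1.0
    temperature: float = 15.0  # °C
    f0: float = 100.0  # a.u., cargo-free donor signal
    fmax: float = 1000.0  # a.u., pre-injection FRET signal

    def __post_init__(self) -> None:
        if not self.protein_grid:
            raise ValueError("protein grid must be non-empty")
        if self.duration_s <= 0 or self.sampling_hz <= 0:
            raise ValueError("duration and sampling rate must be > 0")

    def params(self, condition: str) -> VelocityModelParams:
        if condition == self.basal.condition:
            return self.basal
        if condition == self.stimulated.condition:
            return self.stimulated
        raise KeyError(f"unknown condition {condition!r}")

    @property
    def accessible_cargo(self) -> float:
        return accessible_concentration(self.composition, "DHE")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sampling_hz)) + 1
        return np.linspace(0.0, self.duration_s, n)


def generate_extraction_trace(
    scenario: ScenarioConfig,
    condition: str,
    noise: NoiseModel,
    o_total: float = 1.5,
    k_on: float = 1e3,
) -> tuple[FluorescenceTrace, FluorescenceCalibration]:
    """Simulate one extraction progress curve and its FRET read-out.

    The mass-action scheme (in its quasi-equilibrium parameterisation for
    the condition's K1 and k+2) is integrated from [O]₀ = ``o_total`` and
    [L(C)]₀ = accessible DHE; the extracted fraction x(t) maps to the donor
    signal ``F(t) = F_max − (F_max − F0)·x(t)`` before noise.  The matching
    calibration is returned so conversion round-trips exactly at zero
    noise.
    """
    p = scenario.params(condition)
    accessible = scenario.accessible_cargo
    scheme = quasi_equilibrium_scheme(p.K1, p.k_plus2, k_on=k_on, condition=condition)
    t = scenario.time_grid()
    traj = simulate_scheme(scheme, SchemeState(O=o_total, LC=accessible), t)
    extracted_fraction = cargo_on_protein(traj) / accessible
    f = scenario.fmax - (scenario.fmax - scenario.f0) * extracted_fraction
    f = noise.apply(f)
    cal = FluorescenceCalibration(
        f0=scenario.f0,
        fref=scenario.fmax,
        accessible_ligand=accessible,
        assay_kind="dhe_transport",
    )
    trace = FluorescenceTrace(
        t,
        f,
        {
            "condition": condition,
            "o_total_uM": o_total,
            "seed": noise.seed,
            "temperature_C": scenario.temperature,
        },
    )
    return trace, cal


def generate_velocity_dataset(
    params: VelocityModelParams,
    o_grid=None,
    replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
):
    """Seeded (protein, v₀) dataset on the tight-binding velocity manifold.

    ``v0 = v0_quadratic(params, o) × (1 + ε)`` with ε ~ N(0, cv²).  With
    cv = 0 the points lie exactly on the model curve.
    """
    from .fitting import VelocityDataset  # local import avoids a cycle

    if o_grid is None:
        o_grid = ScenarioConfig().protein_grid
    o_grid = np.asarray(o_grid, dtype=float)
    if o_grid.size == 0:
        raise ValueError("o_grid must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    o = np.tile(o_grid, replicates)
    rep = np.repeat(np.arange(replicates), o_grid.size)
    v_true = v0_quadratic(params, o)
    v = noise.apply(v_true)
    return VelocityDataset(
        o_total=o,
        v0=v,
        replicate=rep,
        L0=params.L0,
        condition=params.condition,
    )


def generate_transport_trace(
    fold_target: float,
    accessible: float,
    rate: float,
    noise: NoiseModel,
    stimulated: bool = False,
    duration_s: float = 600.0,
    sampling_hz: float = 1.0,
    amplitude: Optional[float] = None,
    f0: float = 100.0,
    fmax: float = 1000.0,
) -> FluorescenceTrace:
    """Phenomenological inter-liposome transport trace.

    Transferred(t) = A·(1 − e^{−r·t}) with r = ``rate`` (basal) or
    ``rate × fold_target`` (stimulated): the stimulated condition starts
    ``fold_target`` times faster but approaches the same plateau A
    (default: the full accessible pool), mirroring an allosteric effect on
    rate but not extent.  The amount maps to the donor FRET signal the way
    the extraction trace does.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if fold_target <= 0:
        raise ValueError("fold_target must be > 0")
    A = accessible if amplitude is None else amplitude
    r = rate * fold_target if stimulated else rate
    n = int(round(duration_s * sampling_hz)) + 1
    t = np.linspace(0.0, duration_s, n)
    transferred = A * (1.0 - np.exp(-r * t))
    f = fmax - (fmax - f0) * transferred / accessible
    f = noise.apply(f)
    return FluorescenceTrace(
        t,
        f,
        {
            "condition": "plus_PIP" if stimulated else "basal",
            "rate_per_s": r,
            "amplitude_uM": A,
            "seed": noise.seed,
        },
    )
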