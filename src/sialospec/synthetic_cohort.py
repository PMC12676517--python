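"""Synthetic saliva-like ATR-FTIR cohort generator.

Emulates the statistical structure the downstream analysis assumes: a donor
hierarchy (several replicate spectra per donor with donor-level random band
amplitudes), Gaussian absorption bands at the canonical saliva positions,
polynomial baseline drift and multiplicative scatter (the distortions EMSC
removes), class-dependent additive intensity shifts in the discriminative
fingerprint zones, and a tunable per-spectrum "ambiguity" mechanism: a
diseased donor's spectrum drawn from the control distribution with
probability rho, mimicking stain locations that carry no biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre

from .spectral_data import DonorRecord, SpectrumSet, WavenumberGrid


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (cm^-1), sigma (cm^-1), amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


#: Saliva absorption bands: Amide I/II, CH3 bending, COO- stretch, PO2-
#: stretch, Amide III / carbohydrate region, plus the broad OH/Amide A
#: envelope at high wavenumber.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1636.0, 25.0, 1.00),   # Amide I (protein C=O)
    BandSpec(1549.0, 22.0, 0.60),   # Amide II
    BandSpec(1447.0, 18.0, 0.30),   # CH3 asymmetric bending
    BandSpec(1398.0, 16.0, 0.25),   # COO- symmetric stretch
    BandSpec(1342.0, 16.0, 0.20),   # PO2- asymmetric stretch
    BandSpec(1072.0, 30.0, 0.35),   # Amide III / C-O carbohydrate envelope
    BandSpec(880.0, 40.0, 0.15),    # low-wavenumber carbohydrate/nucleic acid
    BandSpec(3290.0, 120.0, 0.80),  # broad OH / Amide A
)

#: Default class effect: disease raises absorbance in the carbohydrate /
#: Amide III zone (956-1210 cm^-1) and lowers it across the Amide I flank
#: (1579-1800 cm^-1) -- the discriminative zones the attribution stage is
#: expected to recover.
DEFAULT_DISEASE_DELTA: dict[tuple[float, float], float] = {
    (956.0, 1210.0): +0.02,
    (1579.0, 1800.0): -0.015,
}


def default_grid(step: float = 2.0) -> WavenumberGrid:
    return WavenumberGrid.from_range(650.0, 3700.0, step)


@dataclass
class CohortConfig:
    """Generator settings.

    Defaults mirror the cohort shape the analysis targets: 23 control and 24
    disease donors, 5 spectra per donor, with 40% of disease spectra
    ambiguous (drawn from the control distribution).
    """

    n_control_donors: int = 23
    n_disease_donors: int = 24
    spectra_per_donor: int = 5
    grid: WavenumberGrid = field(default_factory=default_grid)
    base_bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    disease_delta: dict[tuple[float, float], float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_DELTA)
    )
    ambiguity_fraction: float = 0.4
    baseline_degree: int = 6
    baseline_scale: float = 0.05
    scatter_sd: float = 0.05
    noise_sd: float = 0.005
    donor_sd: float = 0.08
    taper: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_donors < 1 or self.n_disease_donors < 1:
            raise ValueError("need at least one donor per class")
        if self.spectra_per_donor < 1:
            raise ValueError("spectra_per_donor must be >= 1")
        if not 0.0 <= self.ambiguity_fraction <= 1.0:
            raise ValueError("ambiguity_fraction must be in [0, 1]")
        for name in ("scatter_sd", "noise_sd", "donor_sd", "baseline_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")
        lo, hi = self.grid.values[0], self.grid.values[-1]
        for (zlo, zhi) in self.disease_delta:
            if zlo >= zhi or zhi < lo or zlo > hi:
                raise ValueError(f"disease zone ({zlo}, {zhi}) outside grid range")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    ambiguous_ids: set[str]
    donor_band_effects: dict[str, np.ndarray]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def class_shift_profile(config: CohortConfig) -> np.ndarray:
    """Additive disease-vs-control profile over the grid.

    Equal to the configured delta inside each zone, smoothly tapered to zero
    over ``config.taper`` cm^-1 outside the zone edges.
    """
    config.validate()
    v = config.grid.values
    profile = np.zeros_like(v)
    w = max(config.taper, 1e-9)
    for (lo, hi), delta in config.disease_delta.items():
        rise = _smoothstep((v - (lo - w)) / w)
        fall = _smoothstep(((hi + w) - v) / w)
        profile += delta * rise * fall
    return profile


def _band_matrix(grid: WavenumberGrid, bands: tuple[BandSpec, ...]) -> np.ndarray:
    """(n_bands, n_points) matrix of unit-amplitude Gaussian band shapes."""
    v = grid.values[None, :]
    c = np.array([b.center for b in bands])[:, None]
    s = np.array([b.width for b in bands])[:, None]
    return np.exp(-0.5 * ((v - c) / s) ** 2)


def _legendre_basis(grid: WavenumberGrid, degree: int) -> np.ndarray:
    v = grid.values
    x = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
    return legendre.legvander(x, degree)  # (n_points, degree+1)


def generate_cohort(config: CohortConfig) -> tuple[SpectrumSet, CohortTruth]:
    """Draw a full cohort; bit-reproducible from ``config.seed``.

    Each spectrum is built as::

        scatter * (sum_i amp_i * (1 + donor_effect_i) * gaussian_i
                   + class_shift  [disease, non-ambiguous only])
        + random Legendre baseline + white noise

    For each disease donor every spectrum is independently ambiguous with
    probability ``ambiguity_fraction``: the class shift is omitted so the
    spectrum is drawn exactly from the control distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    bands = _band_matrix(grid, config.base_bands)
    amps = np.array([b.amplitude for b in config.base_bands])
    shift = class_shift_profile(config)
    basis = _legendre_basis(grid, config.baseline_degree)

    donors: list[DonorRecord] = []
    ids: list[str] = []
    donor_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    ambiguous: set[str] = set()
    effects: dict[str, np.ndarray] = {}

    def emit_donor(donor_id: str, label: str) -> None:
        age = f"{int(rng.integers(45, 75)) // 5 * 5}s"
        donors.append(DonorRecord(donor_id=donor_id, label=label, sex="female", age_bin=age))
        eff = rng.normal(0.0, config.donor_sd, size=amps.size)
        effects[donor_id] = eff
        donor_amps = amps * (1.0 + eff)
        clean = donor_amps @ bands
        for k in range(config.spectra_per_donor):
            sid = f"{donor_id}_s{k}"
            ids.append(sid)
            donor_of[sid] = donor_id
            is_amb = label == "disease" and rng.random() < config.ambiguity_fraction
            if is_amb:
                ambiguous.add(sid)
            signal = clean + (shift if (label == "disease" and not is_amb) else 0.0)
            scatter = max(1.0 + rng.normal(0.0, config.scatter_sd), 0.1)
            baseline_coef = rng.normal(0.0, config.baseline_scale, size=basis.shape[1])
            spectrum = (
                scatter * signal
                + basis @ baseline_coef
                + rng.normal(0.0, config.noise_sd, size=len(grid))
            )
            rows.append(spectrum)

    for i in range(config.n_control_donors):
        emit_donor(f"C{i:03d}", "control")
    for i in range(config.n_disease_donors):
        emit_donor(f"D{i:03d}", "disease")

    data = SpectrumSet(
        grid=grid,
        intensities=np.vstack(rows),
        spectrum_ids=ids,
        donor_of=donor_of,
        donors=donors,
    )
    return data, CohortTruth(ambiguous_ids=ambiguous, donor_band_effects=effects)
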