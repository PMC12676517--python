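"""Model-based Extended Multiplicative Signal Correction (EMSC).

Each raw spectrum is decomposed by least squares as

    raw ~= b * reference + sum_k p_k * P_k(x)

where P_k are Legendre polynomials on the wavenumber axis affinely mapped to
[-1, 1] (orthogonal basis: keeps the degree-6 design well conditioned over a
~3000 cm^-1 span).  The corrected spectrum is (raw - baseline) / b, removing
additive polynomial drift and multiplicative scatter in one step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .spectral_data import SpectrumSet, WavenumberGrid

logger = logging.getLogger(__name__)

#: |b| below this is treated as a degenerate fit (correction undefined).
B_TOLERANCE = 1e-6


@dataclass
class EMSCModel:
    reference: np.ndarray
    degree: int
    grid: WavenumberGrid
    basis: np.ndarray      # (n_points, degree+1) Legendre columns
    design: np.ndarray     # (n_points, degree+2): [reference | basis]
    _pinv: np.ndarray      # cached pseudoinverse of design


@dataclass
class EMSCFit:
    b: float
    baseline_coef: np.ndarray
    residual_norm: float
    degenerate: bool = False


def polynomial_basis(grid: WavenumberGrid, degree: int) -> np.ndarray:
    """Legendre columns on the grid mapped affinely to [-1, 1]."""
    v = grid.values
    x = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
    return legendre.legvander(x, degree)


def build_model(reference: np.ndarray, degree: int, grid: WavenumberGrid) -> EMSCModel:
    """Assemble the EMSC design matrix [reference | P_0 ... P_degree]."""
    reference = np.asarray(reference, dtype=float)
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if reference.shape != (len(grid),):
        raise ValueError("reference length does not match grid")
    if not np.all(np.isfinite(reference)):
        raise ValueError("reference must be finite")
    if np.allclose(reference, 0.0):
        raise ValueError("reference must not be identically zero")
    basis = polynomial_basis(grid, degree)
    design = np.column_stack([reference, basis])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient EMSC design (rank {rank} < {design.shape[1]}): "
            "reference is collinear with the polynomial basis"
        )
    return EMSCModel(
        reference=reference,
        degree=degree,
        grid=grid,
        basis=basis,
        design=design,
        _pinv=np.linalg.pinv(design),
    )


def fit_spectrum(model: EMSCModel, raw: np.ndarray) -> EMSCFit:
    """Least-squares EMSC coefficients for one spectrum."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (len(model.grid),):
        raise ValueError("spectrum length does not match model grid")
    coef = model._pinv @ raw
    resid = raw - model.design @ coef
    b = float(coef[0])
    return EMSCFit(
        b=b,
        baseline_coef=coef[1:],
        residual_norm=float(np.linalg.norm(resid)),
        degenerate=abs(b) < B_TOLERANCE,
    )


def apply_fit(model: EMSCModel, raw: np.ndarray, fit: EMSCFit) -> np.ndarray:
    if fit.degenerate:
        raise ValueError("degenerate EMSC fit: |b| below tolerance, correction undefined")
    return (np.asarray(raw, dtype=float) - model.basis @ fit.baseline_coef) / fit.b


def correct_set(data: SpectrumSet, model: EMSCModel) -> tuple[SpectrumSet, list[EMSCFit]]:
    """Correct every spectrum in the set; order and metadata preserved.

    Degenerate fits (|b| < 1e-6) raise with the offending spectrum_id; callers
    that want to skip such spectra should filter beforehand.
    """
    if len(data.grid) != len(model.grid) or not np.allclose(
        data.grid.values, model.grid.values
    ):
        raise ValueError("SpectrumSet grid does not match EMSC model grid")
    coefs = data.intensities @ model._pinv.T          # (n_spectra, degree+2)
    resid = data.intensities - coefs @ model.design.T
    fits: list[EMSCFit] = []
    corrected = np.empty_like(data.intensities)
    for i, sid in enumerate(data.spectrum_ids):
        b = float(coefs[i, 0])
        fit = EMSCFit(
            b=b,
            baseline_coef=coefs[i, 1:],
            residual_norm=float(np.linalg.norm(resid[i])),
            degenerate=abs(b) < B_TOLERANCE,
        )
        if fit.degenerate:
            raise ValueError(
                f"degenerate EMSC fit for spectrum {sid!r}: |b|={abs(b):.2e} < {B_TOLERANCE}"
            )
        fits.append(fit)
        corrected[i] = (data.intensities[i] - model.basis @ fit.baseline_coef) / b
    return data.with_intensities(corrected), fits


def train_mean_reference(train: SpectrumSet) -> np.ndarray:
    """Reference spectrum: mean of the training-fold spectra (leakage-free)."""
    return train.intensities.mean(axis=0)
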