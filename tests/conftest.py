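import numpy as np
import pytest

from sialospec import (
    CohortConfig,
    DonorRecord,
    SpectrumSet,
    WavenumberGrid,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """8-donor cohort on the default grid; shared read-only fixture."""
    cfg = CohortConfig(n_control_donors=4, n_disease_donors=4, seed=11)
    data, truth = generate_cohort(cfg)
    return data, truth, cfg


@pytest.fixture
def toy_set():
    """Hand-built 3-spectrum set on a 5-point grid."""
    grid = WavenumberGrid(np.array([650.0, 700.0, 750.0, 800.0, 850.0]))
    donors = [
        DonorRecord("c1", "control"),
        DonorRecord("d1", "disease", age_bin="60s"),
    ]
    return SpectrumSet(
        grid=grid,
        intensities=np.arange(15.0).reshape(3, 5),
        spectrum_ids=["s1", "s2", "s3"],
        donor_of={"s1": "c1", "s2": "d1", "s3": "d1"},
        donors=donors,
    )


def make_set(intensities, labels, spectra_per_donor=1, grid=None):
    """Build a SpectrumSet from a matrix and per-donor labels (test helper)."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    if grid is None:
        grid = WavenumberGrid(650.0 + 2.0 * np.arange(intensities.shape[1]))
    assert n == len(labels) * spectra_per_donor
    donors, ids, donor_of = [], [], {}
    for j, lab in enumerate(labels):
        donor = f"{'C' if lab == 0 else 'D'}{j:03d}"
        donors.append(DonorRecord(donor, "control" if lab == 0 else "disease"))
        for k in range(spectra_per_donor):
            sid = f"{donor}_s{k}"
            ids.append(sid)
            donor_of[sid] = donor
    return SpectrumSet(grid=grid, intensities=intensities, spectrum_ids=ids,
                       donor_of=donor_of, donors=donors)
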