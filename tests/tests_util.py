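"""Shared helpers for building minimal SpectrumSets in tests."""

import numpy as np

from sialospec import DonorRecord, SpectrumSet


def build_plain_set(intensities, grid, label="control"):
    """One donor per spectrum, all with the same class label."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    donors = [DonorRecord(f"d{i}", label) for i in range(n)]
    return SpectrumSet(
        grid=grid,
        intensities=intensities,
        spectrum_ids=[f"s{i}" for i in range(n)],
        donor_of={f"s{i}": f"d{i}" for i in range(n)},
        donors=donors,
    )


def build_labeled_set(intensities, labels, grid, spectra_per_donor=1):
    """Per-donor labels (0 control / 1 disease), several spectra per donor."""
    intensities = np.asarray(intensities, dtype=float)
    donors, ids, donor_of = [], [], {}
    for j, lab in enumerate(labels):
        donor = f"{'C' if lab == 0 else 'D'}{j:03d}"
        donors.append(DonorRecord(donor, "control" if lab == 0 else "disease"))
        for k in range(spectra_per_donor):
            sid = f"{donor}_s{k}"
            ids.append(sid)
            donor_of[sid] = donor
    assert len(ids) == intensities.shape[0]
    return SpectrumSet(grid=grid, intensities=intensities, spectrum_ids=ids,
                       donor_of=donor_of, donors=donors)
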