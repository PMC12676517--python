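"""Core data model and I/O for ATR-FTIR spectral matrices with donor metadata.

A cohort is represented as a :class:`SpectrumSet`: a shared wavenumber grid,
an ``n_spectra x n_wavenumbers`` absorbance matrix, and per-spectrum links to
:class:`DonorRecord` entries (the donor is the unit of cross-validation and
of majority voting).  Grids are stored ascending internally; instrument files
written high-to-low (4000 -> 650 cm^-1) are canonicalized on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LABELS = ("control", "disease")
VALID_SEXES = ("female", "male")


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending, finite, positive wavenumber axis in cm^-1."""

    values: np.ndarray
    step: float = field(default=0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("wavenumbers must be finite and positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("grid must be strictly ascending with no duplicates")
        object.__setattr__(self, "values", values)
        if self.step == 0.0 and values.size > 1:
            object.__setattr__(self, "step", float(np.median(np.diff(values))))

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def from_range(cls, low: float, high: float, step: float) -> "WavenumberGrid":
        n = int(round((high - low) / step)) + 1
        return cls(low + step * np.arange(n), step=step)


@dataclass(frozen=True)
class DonorRecord:
    donor_id: str
    label: str
    sex: str = "female"
    age_bin: str | None = None

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label {self.label!r} for donor {self.donor_id!r} not in {VALID_LABELS}"
            )
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"sex {self.sex!r} for donor {self.donor_id!r} not in {VALID_SEXES}"
            )


@dataclass
class SpectrumSet:
    """Wavenumber grid + intensity matrix + donor metadata.

    ``intensities`` has one row per spectrum, one column per grid point.
    Every spectrum id maps to exactly one donor present in ``donors``.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    spectrum_ids: list[str]
    donor_of: dict[str, str]
    donors: list[DonorRecord]

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (n_spectra x n_wavenumbers)")
        n, m = self.intensities.shape
        if m != len(self.grid):
            raise ValueError(
                f"intensity columns ({m}) do not match grid length ({len(self.grid)})"
            )
        if len(self.spectrum_ids) != n:
            raise ValueError("spectrum_ids length does not match intensity rows")
        if len(set(self.spectrum_ids)) != n:
            raise ValueError("duplicate spectrum_id")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity values")
        donor_ids = [d.donor_id for d in self.donors]
        if len(set(donor_ids)) != len(donor_ids):
            raise ValueError("duplicate donor_id in donors")
        known = set(donor_ids)
        for sid in self.spectrum_ids:
            if sid not in self.donor_of:
                raise ValueError(f"spectrum {sid!r} has no donor assignment")
            if self.donor_of[sid] not in known:
                raise ValueError(
                    f"spectrum {sid!r} maps to unknown donor {self.donor_of[sid]!r}"
                )

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def donor_record(self, donor_id: str) -> DonorRecord:
        for d in self.donors:
            if d.donor_id == donor_id:
                return d
        raise KeyError(donor_id)

    def labels(self) -> np.ndarray:
        """Per-spectrum label as 0 (control) / 1 (disease)."""
        by_id = {d.donor_id: d.label for d in self.donors}
        return np.array(
            [1 if by_id[self.donor_of[s]] == "disease" else 0 for s in self.spectrum_ids]
        )

    def spectra_of(self, donor_id: str) -> list[str]:
        return [s for s in self.spectrum_ids if self.donor_of[s] == donor_id]

    def subset_spectra(self, ids: list[str]) -> "SpectrumSet":
        """Row subset (given spectrum ids, original order kept); donors restricted."""
        wanted = set(ids)
        idx = [i for i, s in enumerate(self.spectrum_ids) if s in wanted]
        missing = wanted - {self.spectrum_ids[i] for i in idx}
        if missing:
            raise KeyError(f"unknown spectrum ids: {sorted(missing)}")
        kept_ids = [self.spectrum_ids[i] for i in idx]
        kept_donors = {self.donor_of[s] for s in kept_ids}
        return SpectrumSet(
            grid=self.grid,
            intensities=self.intensities[idx],
            spectrum_ids=kept_ids,
            donor_of={s: self.donor_of[s] for s in kept_ids},
            donors=[d for d in self.donors if d.donor_id in kept_donors],
        )

    def subset_donors(self, donor_ids: list[str]) -> "SpectrumSet":
        wanted = set(donor_ids)
        ids = [s for s in self.spectrum_ids if self.donor_of[s] in wanted]
        return self.subset_spectra(ids)

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(
            grid=self.grid,
            intensities=intensities,
            spectrum_ids=list(self.spectrum_ids),
            donor_of=dict(self.donor_of),
            donors=list(self.donors),
        )


def read_spectra(matrix_path, metadata_path) -> SpectrumSet:
    """Read a spectral matrix CSV and a metadata CSV into a validated SpectrumSet.

    Matrix dialect: header ``wavenumber,<id1>,<id2>,...``, one row per grid
    point; descending instrument grids are flipped ascending.  Metadata
    columns: ``spectrum_id,donor_id,label,sex,age_bin``.  A spectrum with no
    metadata row is an error, never silently dropped.
    """
    mat = pd.read_csv(matrix_path, dtype={0: float})
    if mat.columns[0] != "wavenumber":
        raise ValueError(f"first matrix column must be 'wavenumber', got {mat.columns[0]!r}")
    spectrum_ids = [str(c) for c in mat.columns[1:]]
    if len(set(spectrum_ids)) != len(spectrum_ids):
        raise ValueError("duplicate spectrum_id column in matrix")
    wn = mat["wavenumber"].to_numpy(dtype=float)
    inten = mat.iloc[:, 1:].to_numpy(dtype=float).T  # (n_spectra, n_points)
    if wn.size > 1 and wn[0] > wn[-1]:  # instrument convention 4000 -> 650
        wn = wn[::-1]
        inten = inten[:, ::-1]

    meta = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    required = {"spectrum_id", "donor_id", "label", "sex", "age_bin"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata missing columns: {sorted(required - set(meta.columns))}")
    meta_ids = list(meta["spectrum_id"])
    if len(set(meta_ids)) != len(meta_ids):
        raise ValueError("duplicate spectrum_id in metadata")
    orphans = [s for s in spectrum_ids if s not in set(meta_ids)]
    if orphans:
        raise ValueError(f"spectra missing from metadata: {orphans}")

    rows = {r.spectrum_id: r for r in meta.itertuples(index=False)}
    donor_of = {s: rows[s].donor_id for s in spectrum_ids}
    donors: dict[str, DonorRecord] = {}
    for s in spectrum_ids:
        r = rows[s]
        rec = DonorRecord(
            donor_id=r.donor_id,
            label=r.label,
            sex=r.sex,
            age_bin=r.age_bin or None,
        )
        prev = donors.get(r.donor_id)
        if prev is not None and prev != rec:
            raise ValueError(f"inconsistent metadata for donor {r.donor_id!r}")
        donors[r.donor_id] = rec

    return SpectrumSet(
        grid=WavenumberGrid(wn),
        intensities=inten,
        spectrum_ids=spectrum_ids,
        donor_of=donor_of,
        donors=list(donors.values()),
    )


def write_spectra(data: SpectrumSet, matrix_path, metadata_path) -> None:
    """Write the two-CSV dialect accepted by :func:`read_spectra`."""
    if not data.donors or data.n_spectra == 0:
        raise ValueError("nothing to write: empty SpectrumSet")
    mat = pd.DataFrame(data.intensities.T, columns=data.spectrum_ids)
    mat.insert(0, "wavenumber", data.grid.values)
    mat.to_csv(matrix_path, index=False, float_format="%.12g")

    by_id = {d.donor_id: d for d in data.donors}
    meta = pd.DataFrame(
        {
            "spectrum_id": data.spectrum_ids,
            "donor_id": [data.donor_of[s] for s in data.spectrum_ids],
            "label": [by_id[data.donor_of[s]].label for s in data.spectrum_ids],
            "sex": [by_id[data.donor_of[s]].sex for s in data.spectrum_ids],
            "age_bin": [by_id[data.donor_of[s]].age_bin or "" for s in data.spectrum_ids],
        }
    )
    meta.to_csv(metadata_path, index=False)


def crop_region(data: SpectrumSet, low: float, high: float) -> SpectrumSet:
    """Restrict to grid values v with low <= v <= high (closed interval).

    Spectrum order, donor links and retained intensities are untouched.
    """
    if low >= high:
        raise ValueError(f"invalid region: low={low} >= high={high}")
    mask = (data.grid.values >= low) & (data.grid.values <= high)
    if not mask.any():
        raise ValueError(f"region [{low}, {high}] does not intersect the grid")
    return SpectrumSet(
        grid=WavenumberGrid(data.grid.values[mask], step=data.grid.step),
        intensities=data.intensities[:, mask],
        spectrum_ids=list(data.spectrum_ids),
        donor_of=dict(data.donor_of),
        donors=list(data.donors),
    )
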