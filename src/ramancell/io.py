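"""Core containers and plain-text I/O for single-cell Raman spectra.

A :class:`Spectrum` couples one ascending wavenumber grid (cm⁻¹) with one
intensity vector; a :class:`SpectraSet` stacks many cells' spectra on a shared
grid together with per-cell metadata (patient, response group).  All files are
tab-separated UTF-8 text so that every pipeline stage is inspectable and
diff-able.

Matrix file layout::

    <w1>\t<w2>\t...\t<wp>          # header: wavenumbers in cm⁻¹
    cell_001\t<x11>\t...\t<x1p>    # one row per cell: sample_id + intensities
    ...

Metadata manifest: TSV with columns ``sample_id``, ``patient_id``, ``group``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ExtrapolationError, FormatError, GridError

logger = logging.getLogger(__name__)

GROUPS = ("CR", "NR", "UNKNOWN")


def _validate_grid(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise GridError("wavenumber grid must be a 1-D vector of length >= 2")
    if not np.all(np.diff(w) > 0):
        raise GridError("wavenumber grid must be strictly increasing (ascending cm^-1)")
    return w


@dataclass(frozen=True)
class Spectrum:
    """One wavenumber grid plus one intensity vector for a single measurement."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = _validate_grid(self.wavenumbers)
        x = np.asarray(self.intensities, dtype=float)
        if x.shape != w.shape:
            raise FormatError(
                f"intensities length {x.size} does not match grid length {w.size}"
            )
        if not np.all(np.isfinite(x)):
            raise FormatError("intensities must be finite")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one measured cell: sample id, donor patient, response group."""

    sample_id: str
    patient_id: str
    group: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )


@dataclass
class SpectraSet:
    """An aligned cells × channels intensity matrix with per-row metadata.

    This is the universal currency between pipeline stages.  Rows all share
    the one grid; alignment onto a common grid is an explicit operation
    (:func:`align_to_grid`), never implicit.
    """

    wavenumbers: np.ndarray
    matrix: np.ndarray
    meta: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_grid(self.wavenumbers)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(0, self.wavenumbers.size)
        if self.matrix.shape[1] != self.wavenumbers.size:
            raise FormatError(
                f"matrix has {self.matrix.shape[1]} channels but grid has "
                f"{self.wavenumbers.size}"
            )
        if len(self.meta) != self.matrix.shape[0]:
            raise FormatError(
                f"{self.matrix.shape[0]} rows but {len(self.meta)} metadata entries"
            )
        ids = [m.sample_id for m in self.meta]
        if len(set(ids)) != len(ids):
            raise FormatError("sample_id values must be unique within a SpectraSet")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    @property
    def groups(self) -> np.ndarray:
        return np.array([m.group for m in self.meta])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([m.patient_id for m in self.meta])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.matrix[i])

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows)
        return SpectraSet(
            self.wavenumbers.copy(),
            self.matrix[rows].copy(),
            [self.meta[int(i)] for i in rows],
        )


def read_spectra_table(path_matrix, path_meta) -> SpectraSet:
    """Read a spectra matrix plus its metadata manifest.

    Rows missing from the manifest are kept with group ``UNKNOWN`` and a
    logged warning.  A row whose value count disagrees with the header grid
    raises :class:`FormatError` naming the offending row; a non-ascending
    header raises :class:`GridError`.
    """
    path_matrix = Path(path_matrix)
    with open(path_matrix, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path_matrix}: empty file") from None
        try:
            grid = np.array([float(v) for v in header])
        except ValueError as exc:
            raise FormatError(f"{path_matrix}: non-numeric header: {exc}") from None
        grid = _validate_grid(grid)
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != grid.size + 1:
                raise FormatError(
                    f"{path_matrix}: row {lineno - 1} has {len(row) - 1} values, "
                    f"expected {grid.size}"
                )
            ids.append(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise FormatError(
                    f"{path_matrix}: row {lineno - 1}: {exc}"
                ) from None
    matrix = np.array(rows, dtype=float).reshape(len(rows), grid.size)

    manifest = pd.read_csv(path_meta, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "group"}
    if not required.issubset(manifest.columns):
        raise FormatError(
            f"{path_meta}: manifest must have columns {sorted(required)}"
        )
    lookup = {
        r.sample_id: SampleMeta(r.sample_id, r.patient_id, r.group)
        for r in manifest.itertuples()
    }
    meta = []
    for sid in ids:
        if sid in lookup:
            meta.append(lookup[sid])
        else:
            logger.warning("sample %s missing from manifest; group set to UNKNOWN", sid)
            meta.append(SampleMeta(sid, "NA", "UNKNOWN"))
    return SpectraSet(grid, matrix, meta)


def write_spectra_table(dataset: SpectraSet, path_matrix, path_meta) -> None:
    """Write a SpectraSet so that :func:`read_spectra_table` round-trips it.

    Floats are printed with ``repr`` (shortest round-trip representation), so
    read(write(x)) reproduces the matrix bitwise.
    """
    with open(path_matrix, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(repr(float(w)) for w in dataset.wavenumbers) + "\n")
        for sid, row in zip(dataset.sample_ids, dataset.matrix):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    manifest = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "patient_id": [m.patient_id for m in dataset.meta],
            "group": [m.group for m in dataset.meta],
        }
    )
    manifest.to_csv(path_meta, sep="\t", index=False)


def align_to_grid(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid inside its span."""
    grid = _validate_grid(np.asarray(list(grid), dtype=float))
    w = spectrum.wavenumbers
    if grid[0] < w[0] or grid[-1] > w[-1]:
        raise ExtrapolationError(
            f"target grid [{grid[0]}, {grid[-1]}] extends outside the measured "
            f"span [{w[0]}, {w[-1]}]"
        )
    return Spectrum(grid, np.interp(grid, w, spectrum.intensities))


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "spectra") -> None:
    if a.shape != b.shape or not np.allclose(a, b):
        raise AlignmentError(f"{what} are not on the same wavenumber grid")
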