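"""SQLite reference spectra libraries.

Schema (table ``spectra``): record_id INTEGER PRIMARY KEY, compound_name,
formula, inchikey, precursor_mz REAL, adduct, polarity, collision_energy,
instrument_type, peaks_mz, peaks_intensity, fragment_formulas — peak arrays
stored as semicolon-joined decimal strings.  A companion ``meta`` table holds
``schema_version``.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .spectrum import Spectrum

SCHEMA_VERSION = "1"

_CREATE_SPECTRA = """
CREATE TABLE spectra (
    record_id INTEGER PRIMARY KEY,
    compound_name TEXT,
    formula TEXT,
    inchikey TEXT,
    precursor_mz REAL,
    adduct TEXT,
    polarity TEXT,
    collision_energy TEXT,
    instrument_type TEXT,
    peaks_mz TEXT,
    peaks_intensity TEXT,
    fragment_formulas TEXT
)
"""


@dataclass
class LibraryRecord:
    """One reference spectrum with compound annotations."""

    record_id: int
    compound_name: str
    formula: str
    inchikey: str
    precursor_mz: float
    adduct: str
    polarity: str
    collision_energy: str
    instrument_type: str
    spectrum: Spectrum
    fragment_formulas: list[str] | None = None

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if len(self.spectrum) == 0:
            raise ValueError("library record spectrum must be non-empty")


def _join(values: Sequence[float]) -> str:
    return ";".join(f"{v:.6f}" for v in values)


def _split(text: str) -> np.ndarray:
    return np.array([float(t) for t in text.split(";")]) if text else np.array([])


class SpectralLibrary:
    """Handle over an open SQLite reference library."""

    def __init__(self, conn: sqlite3.Connection, path: str = ""):
        self.conn = conn
        self.path = path

    # -- construction -------------------------------------------------

    @classmethod
    def create(cls, path: str | Path, records: Iterable[LibraryRecord] = ()) -> "SpectralLibrary":
        path = Path(path)
        if path.exists():
            path.unlink()
        conn = sqlite3.connect(str(path))
        conn.execute(_CREATE_SPECTRA)
        conn.execute("CREATE TABLE meta (key TEXT, value TEXT)")
        conn.execute("INSERT INTO meta VALUES ('schema_version', ?)", (SCHEMA_VERSION,))
        conn.execute("CREATE INDEX idx_precursor ON spectra (precursor_mz)")
        conn.execute("CREATE INDEX idx_formula ON spectra (formula)")
        lib = cls(conn, str(path))
        lib.add_records(records)
        conn.commit()
        return lib

    def add_records(self, records: Iterable[LibraryRecord]) -> None:
        rows = []
        for r in records:
            frag_forms = ";".join(r.fragment_formulas) if r.fragment_formulas else ""
            rows.append((
                r.record_id, r.compound_name, r.formula, r.inchikey, r.precursor_mz,
                r.adduct, r.polarity, r.collision_energy, r.instrument_type,
                _join(r.spectrum.mz), _join(r.spectrum.intensity), frag_forms,
            ))
        self.conn.executemany(
            "INSERT INTO spectra VALUES (?,?,?,?,?,?,?,?,?,?,?,?)", rows
        )
        self.conn.commit()

    # -- queries ------------------------------------------------------

    def _row_to_record(self, row) -> LibraryRecord:
        (rid, name, formula, inchikey, pmz, adduct, pol, ce, inst, pmzs, pints, ff) = row
        spec = Spectrum(
            mz=_split(pmzs), intensity=_split(pints),
            precursor_mz=pmz, polarity=pol or "positive", source_id=f"lib:{rid}",
        )
        return LibraryRecord(
            record_id=rid, compound_name=name or "", formula=formula or "",
            inchikey=inchikey or "", precursor_mz=pmz, adduct=adduct or "",
            polarity=pol or "positive", collision_energy=ce or "",
            instrument_type=inst or "", spectrum=spec,
            fragment_formulas=ff.split(";") if ff else None,
        )

    def query_by_precursor(
        self, mz: float, tol_ppm: float, polarity: str | None = None
    ) -> list[LibraryRecord]:
        """All records with |Δppm| ≤ tol_ppm (ppm relative to the record) and
        matching polarity, ordered by record_id."""
        half = mz * tol_ppm * 1e-6 * 1.001  # tiny cushion; exact ppm re-checked below
        rows = self.conn.execute(
            "SELECT * FROM spectra WHERE precursor_mz BETWEEN ? AND ? ORDER BY record_id",
            (mz - half, mz + half),
        ).fetchall()
        out = []
        for row in rows:
            rec = self._row_to_record(row)
            if polarity and rec.polarity != polarity:
                continue
            if abs(1e6 * (mz - rec.precursor_mz) / rec.precursor_mz) <= tol_ppm:
                out.append(rec)
        return out

    def query_by_formula(self, formula: str) -> list[LibraryRecord]:
        rows = self.conn.execute(
            "SELECT * FROM spectra WHERE formula = ? ORDER BY record_id", (formula,)
        ).fetchall()
        return [self._row_to_record(r) for r in rows]

    def get(self, record_id: int) -> LibraryRecord | None:
        row = self.conn.execute(
            "SELECT * FROM spectra WHERE record_id = ?", (record_id,)
        ).fetchone()
        return self._row_to_record(row) if row else None

    def all_records(self) -> list[LibraryRecord]:
        rows = self.conn.execute("SELECT * FROM spectra ORDER BY record_id").fetchall()
        return [self._row_to_record(r) for r in rows]

    def __len__(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM spectra").fetchone()[0]

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_library(path: str | Path) -> SpectralLibrary:
    """Open an existing SQLite reference library, validating its schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    conn = sqlite3.connect(str(path))
    try:
        cols = [r[1] for r in conn.execute("PRAGMA table_info(spectra)")]
        version = conn.execute(
            "SELECT value FROM meta WHERE key = 'schema_version'"
        ).fetchone()
    except sqlite3.Error as exc:
        conn.close()
        raise ValueError(f"{path.name}: not a reference library (missing tables)") from exc
    expected = [
        "record_id", "compound_name", "formula", "inchikey", "precursor_mz",
        "adduct", "polarity", "collision_energy", "instrument_type",
        "peaks_mz", "peaks_intensity", "fragment_formulas",
    ]
    if cols != expected or version is None or version[0] != SCHEMA_VERSION:
        conn.close()
        raise ValueError(
            f"{path.name}: library schema mismatch "
            f"(version {version[0] if version else 'absent'}, expected {SCHEMA_VERSION})"
        )
    return SpectralLibrary(conn, str(path))


def derive_neutral_loss_library(library: SpectralLibrary, path: str | Path) -> SpectralLibrary:
    """Pre-compute the neutral-loss companion of a reference library.

    Each fragment m/z is replaced by (precursor m/z − fragment m/z) with the
    intensity mirrored; non-positive neutral losses are dropped.
    """
    from .search import neutral_loss_spectrum

    records = []
    for r in library.all_records():
        nl = neutral_loss_spectrum(r.spectrum)
        if len(nl) == 0:
            continue
        records.append(LibraryRecord(
            record_id=r.record_id, compound_name=r.compound_name, formula=r.formula,
            inchikey=r.inchikey, precursor_mz=r.precursor_mz, adduct=r.adduct,
            polarity=r.polarity, collision_energy=r.collision_energy,
            instrument_type=r.instrument_type, spectrum=nl,
        ))
    return SpectralLibrary.create(path, records)
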