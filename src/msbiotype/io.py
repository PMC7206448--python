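"""Domain containers and file I/O for biotyping spectra and score tables.

The on-disk formats are deliberately plain: two-column text (m/z, intensity)
for profile spectra, mzML (read-only, MS1 profile arrays) for interchange,
and CSV for peak lists and score matrices.  Everything else in the package
consumes the containers defined here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MASS_RANGE",
    "Spectrum",
    "Peak",
    "PeakList",
    "ScoreMatrix",
    "read_spectrum",
    "write_spectrum",
    "read_score_table",
    "write_score_table",
    "read_peaklist",
    "write_peaklist",
    "load_table1",
]

#: Acquisition mass window in Da; points outside are discarded on read.
MASS_RANGE = (2000.0, 20000.0)


class MalformedInputError(ValueError):
    """Raised when a file parses but violates the format contract."""


@dataclass
class Spectrum:
    """A profile trace: paired m/z and intensity arrays plus sample metadata.

    Invariants: ``mz`` strictly increasing, intensities non-negative, equal
    lengths.  Enforced at construction.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    population: str | None = None
    method_tag: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    def replace(self, **kw) -> "Spectrum":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z in Da, intensity (arbitrary units), SNR."""

    mz: float
    intensity: float
    snr: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("peak intensity must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class PeakList:
    """Centroided peaks of one sample, ordered by m/z; the unit of comparison."""

    peaks: list[Peak]
    sample_id: str = ""
    population: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must be strictly increasing in mz")
        if self.normalized and self.peaks:
            if not np.isclose(max(p.intensity for p in self.peaks), 1.0):
                raise ValueError("normalized PeakList must have max intensity 1")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def snr(self) -> np.ndarray:
        return np.array([p.snr for p in self.peaks], dtype=float)


@dataclass
class ScoreMatrix:
    """Dense test-sample x reference composite-score matrix.

    ``ref_ids`` may be individual reference replicates or, after averaging,
    population names; ``ref_population_of`` maps each column to its
    population.  All scores must lie in the composite-score range [0, 3].
    """

    test_ids: list[str]
    ref_ids: list[str]
    scores: np.ndarray
    ref_population_of: dict[str, str]
    true_population_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.test_ids), len(self.ref_ids)):
            raise ValueError("scores shape must be (n_test, n_ref)")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 3):
            raise ValueError("composite scores must lie in [0, 3]")
        missing = [r for r in self.ref_ids if r not in self.ref_population_of]
        if missing:
            raise ValueError(f"ref columns without population label: {missing}")

    @property
    def populations(self) -> list[str]:
        """Distinct reference populations in column order."""
        seen: dict[str, None] = {}
        for r in self.ref_ids:
            seen.setdefault(self.ref_population_of[r], None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.test_ids, columns=self.ref_ids)


# ---------------------------------------------------------------------------
# spectra

# PSI-MS controlled-vocabulary accessions used by the minimal mzML reader
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MS_LEVEL = "MS:1000511"


def _read_mzml_ms1(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal mzML reader: m/z and intensity arrays of the first MS1
    spectrum.

    Supports 32/64-bit float binary arrays, uncompressed or zlib; indexed
    and plain mzML.  Deliberately small in scope — MS1 profile data only.
    """
    import base64 as _b64
    import zlib as _zlib

    from lxml import etree

    def local(el):  # tag name without namespace
        return etree.QName(el).localname

    def decode(bda, n_expected):
        dtype, compressed, blob = np.float64, False, None
        for child in bda.iter():
            if local(child) == "cvParam":
                acc = child.get("accession", "")
                if acc == _CV_F32:
                    dtype = np.float32
                elif acc == _CV_ZLIB:
                    compressed = True
            elif local(child) == "binary":
                blob = child.text or ""
        raw = _b64.b64decode(blob)
        if compressed:
            raw = _zlib.decompress(raw)
        arr = np.frombuffer(raw, dtype=dtype).astype(float)
        if n_expected is not None and len(arr) != n_expected:
            raise MalformedInputError(
                f"binary array length {len(arr)} != declared {n_expected}")
        return arr

    tree = etree.parse(str(path))
    for spec in tree.iter():
        if local(spec) != "spectrum":
            continue
        level = 1
        arrays: dict[str, np.ndarray] = {}
        n = spec.get("defaultArrayLength")
        n = int(n) if n is not None else None
        for child in spec.iter():
            if local(child) == "cvParam" and \
                    child.get("accession") == _CV_MS_LEVEL:
                level = int(child.get("value", "1"))
            if local(child) == "binaryDataArray":
                accs = {c.get("accession") for c in child.iter()
                        if local(c) == "cvParam"}
                if _CV_MZ_ARRAY in accs:
                    arrays["mz"] = decode(child, n)
                elif _CV_INT_ARRAY in accs:
                    arrays["intensity"] = decode(child, n)
        if level == 1 and "mz" in arrays and "intensity" in arrays:
            return arrays["mz"], arrays["intensity"]
    raise MalformedInputError(f"{path}: no MS1 spectrum with m/z and "
                              "intensity arrays found")


def _restrict_and_sort(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    keep = (mz >= MASS_RANGE[0]) & (mz <= MASS_RANGE[1])
    mz, inten = mz[keep], inten[keep]
    # collapse duplicate m/z values (keep the max intensity) so the
    # strictly-increasing invariant holds
    if len(mz) >= 2:
        uniq, inverse = np.unique(mz, return_inverse=True)
        if len(uniq) != len(mz):
            agg = np.zeros(len(uniq))
            np.maximum.at(agg, inverse, inten)
            mz, inten = uniq, agg
    return mz, inten


def read_spectrum(path: str | Path, format: str = "two_column_text", *,
                  sample_id: str | None = None) -> Spectrum:
    """Read a profile spectrum from two-column text or mzML.

    Points outside the 2-20 kDa acquisition window are dropped; out-of-order
    input is sorted.  Fewer than 2 surviving points is a malformed-input
    error.
    """
    path = Path(path)
    if format == "two_column_text":
        rows: list[tuple[float, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    raise MalformedInputError(f"{path}: bad line {line!r}")
                rows.append((float(parts[0]), float(parts[1])))
        if not rows:
            raise MalformedInputError(f"{path}: no data points")
        mz = np.array([r[0] for r in rows])
        inten = np.array([r[1] for r in rows])
    elif format == "mzml":
        mz, inten = _read_mzml_ms1(path)
    else:
        raise ValueError(f"unknown spectrum format: {format!r}")

    if len(mz) < 2:
        raise MalformedInputError(f"{path}: fewer than 2 data points")
    mz, inten = _restrict_and_sort(mz, np.maximum(inten, 0.0))
    if len(mz) == 0:
        raise MalformedInputError(
            f"{path}: no points inside the {MASS_RANGE} Da window")
    return Spectrum(mz, inten, sample_id=sample_id or path.stem)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with >=6 significant digits."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {s.sample_id}\n")
        for m, i in zip(s.mz, s.intensity):
            fh.write(f"{m:.6f} {i:.8g}\n")


# ---------------------------------------------------------------------------
# peak lists


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write a PeakList as CSV (mz, intensity, snr); exact read-back."""
    df = pd.DataFrame({
        "mz": [repr(p.mz) for p in pl.peaks],
        "intensity": [repr(p.intensity) for p in pl.peaks],
        "snr": [repr(p.snr) for p in pl.peaks],
    })
    header = (f"# sample_id={pl.sample_id} population={pl.population or ''} "
              f"normalized={int(pl.normalized)}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_peaklist(path: str | Path) -> PeakList:
    meta = {"sample_id": "", "population": None, "normalized": False}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "sample_id":
                        meta["sample_id"] = v
                    elif k == "population":
                        meta["population"] = v or None
                    elif k == "normalized":
                        meta["normalized"] = bool(int(v))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    peaks = [Peak(float(r.mz), float(r.intensity), float(r.snr))
             for r in df.itertuples()]
    return PeakList(peaks, **meta)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# score tables


def read_score_table(path: str | Path) -> ScoreMatrix:
    """Read a population-averaged score table from CSV.

    Expected columns: ``test_id``, one column per reference population, and
    optionally ``true_population``.  Scores outside [0, 3] are a validation
    error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise MalformedInputError(f"{path}: empty score table") from e
    if "test_id" not in df.columns:
        raise MalformedInputError(f"{path}: missing test_id column")
    meta_cols = {"test_id", "true_population", "call", "correct"}
    ref_cols = [c for c in df.columns if c not in meta_cols]
    if not ref_cols:
        raise MalformedInputError(f"{path}: no reference score columns")
    scores = df[ref_cols].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise MalformedInputError(f"{path}: ragged or non-numeric score cells")
    test_ids = [str(t) for t in df["test_id"]]
    truth = None
    if "true_population" in df.columns:
        truth = dict(zip(test_ids, df["true_population"].astype(str)))
    return ScoreMatrix(
        test_ids=test_ids,
        ref_ids=list(ref_cols),
        scores=scores,
        ref_population_of={c: c for c in ref_cols},
        true_population_of=truth,
    )


def write_score_table(sm: ScoreMatrix, path: str | Path) -> None:
    df = sm.to_dataframe().reset_index(names="test_id")
    if sm.true_population_of is not None:
        df["true_population"] = [sm.true_population_of[t] for t in sm.test_ids]
    df.to_csv(path, index=False)


def load_table1() -> ScoreMatrix:
    """The published 24-sample x 4-population average-score benchmark table.

    Blind-test composite scores for 24 wasp samples (6 per population:
    Dali, Hasuike, Tokyo, Ximing) against quadruplicate reference panels,
    averaged per reference population.  The ``true_population`` column holds
    the unblinded sample origin.
    """
    with resources.as_file(resources.files("msbiotype.data") / "table1.csv") as p:
        return read_score_table(p)
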