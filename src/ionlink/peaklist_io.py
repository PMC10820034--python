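"""Reading and writing the tool's external formats.

Deconvoluted peak lists arrive as delimited text (any pipeline's export works,
given a column mapping onto the canonical ``feature_id,mz,rt,intensity,group_id``
schema).  Raw runs are mzML/mzXML read through :mod:`pyteomics`; profile spectra
are reduced to centroids by local-maximum picking.  Results leave as a flat CSV,
one row per (EI pseudospectrum, rank).

Retention times are minutes everywhere in this package.
"""

from __future__ import annotations

import bisect
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .formula_engine import Formula

log = logging.getLogger(__name__)

#: isotope_flag values on features
FLAG_NONE = "none"
FLAG_M1 = "M+1"
FLAG_M2 = "M+2"

CANONICAL_COLUMNS = ("feature_id", "mz", "rt", "intensity", "group_id")
REQUIRED_COLUMNS = ("mz", "rt", "intensity", "group_id")

RUN_FRAGMENT = "fragment_run"
RUN_MOLION = "molion_run"


@dataclass
class FeatureTable:
    """Deconvoluted features of one run, one row per ion.

    ``df`` columns: feature_id (str), mz, rt, intensity (float), group_id (str),
    isotope_flag (str, one of none/M+1/M+2).  A ``rt_raw`` column appears after
    retention-time correction and preserves the run's native time axis.
    """

    df: pd.DataFrame
    run_label: str
    n_rejected: int = 0

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        if "isotope_flag" not in self.df.columns:
            self.df["isotope_flag"] = FLAG_NONE

    def groups(self) -> Iterator[Tuple[str, pd.DataFrame]]:
        """Iterate pseudospectra in sorted group_id order (deterministic)."""
        for gid in sorted(self.df["group_id"].unique()):
            yield gid, self.df[self.df["group_id"] == gid]

    def n_groups(self) -> int:
        return self.df["group_id"].nunique()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), self.run_label, self.n_rejected)


@dataclass(frozen=True)
class RtStandardTable:
    """Matched retention times of alignment standards on both time axes (minutes)."""

    rt_fragment: np.ndarray  # strictly increasing
    rt_molion: np.ndarray  # strictly increasing, same length


@dataclass
class Scan:
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.mz, kind="stable")
        self.mz = np.asarray(self.mz, dtype=float)[order]
        self.intensity = np.asarray(self.intensity, dtype=float)[order]


@dataclass
class RawRun:
    """Centroided MS1 scans of one run, sorted by retention time."""

    scans: List[Scan] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scans = sorted(self.scans, key=lambda s: s.rt)
        self._rts = [s.rt for s in self.scans]

    def find_peak(
        self,
        rt_center: float,
        rt_window: float,
        target_mz: float,
        ppm: float,
        noise_floor: float = 0.0,
    ) -> Tuple[bool, float]:
        """Search scans with \\|rt − rt_center\\| ≤ rt_window for a centroid within ppm.

        Returns (found, max intensity of matching centroids).  A centroid counts
        when its intensity exceeds ``noise_floor`` (default 0: any recorded
        signal counts — adduct satellites can be extremely weak).
        """
        lo = bisect.bisect_left(self._rts, rt_center - rt_window - 1e-12)
        hi = bisect.bisect_right(self._rts, rt_center + rt_window + 1e-12)
        tol = abs(target_mz) * ppm * 1e-6
        best = 0.0
        found = False
        for scan in self.scans[lo:hi]:
            i0 = np.searchsorted(scan.mz, target_mz - tol)
            i1 = np.searchsorted(scan.mz, target_mz + tol, side="right")
            if i1 > i0:
                m = float(scan.intensity[i0:i1].max())
                if m > noise_floor:
                    found = True
                    best = max(best, m)
        return found, best


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_peaklist(
    path: str,
    run_label: str,
    column_map: Optional[Mapping[str, str]] = None,
) -> FeatureTable:
    """Read a deconvoluted peak list from delimited text.

    ``column_map`` maps canonical names (mz, rt, intensity, group_id, and
    optionally feature_id) to the file's header names; by default the canonical
    names themselves are expected.  Rows with non-numeric or non-positive
    mz/intensity (or negative rt) are dropped with a logged count.
    """
    if not os.path.exists(path):
        raise InputError(f"peak list not found: {path}")
    try:
        raw = pd.read_csv(path, sep=_delimiter_for(path))
    except Exception as exc:
        raise InputError(f"cannot parse peak list {path}: {exc}") from exc
    if raw.empty:
        raise InputError(f"peak list {path} contains no rows")

    cmap = dict(column_map or {})
    cols: Dict[str, str] = {}
    for canon in REQUIRED_COLUMNS:
        name = cmap.get(canon, canon)
        if name not in raw.columns:
            raise ConfigurationError(
                f"peak list {path} lacks required column {name!r} (for {canon!r})"
            )
        cols[canon] = name

    df = pd.DataFrame(
        {
            "mz": pd.to_numeric(raw[cols["mz"]], errors="coerce"),
            "rt": pd.to_numeric(raw[cols["rt"]], errors="coerce"),
            "intensity": pd.to_numeric(raw[cols["intensity"]], errors="coerce"),
            "group_id": raw[cols["group_id"]].astype(str),
        }
    )
    id_col = cmap.get("feature_id", "feature_id")
    if id_col in raw.columns:
        df["feature_id"] = raw[id_col].astype(str)
    else:
        df["feature_id"] = [f"{run_label}:{i}" for i in range(len(raw))]

    ok = (
        df["mz"].notna()
        & df["rt"].notna()
        & df["intensity"].notna()
        & (df["mz"] > 0)
        & (df["intensity"] > 0)
        & (df["rt"] >= 0)
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("peak list %s: dropped %d malformed row(s)", path, n_rejected)
    df = df[ok].reset_index(drop=True)
    df["isotope_flag"] = FLAG_NONE
    return FeatureTable(
        df[["feature_id", "mz", "rt", "intensity", "group_id", "isotope_flag"]],
        run_label,
        n_rejected,
    )


def write_peaklist(table: FeatureTable, path: str) -> None:
    """Write a FeatureTable back to canonical delimited text (full float precision)."""
    cols = [c for c in ("feature_id", "mz", "rt", "intensity", "group_id") if c in table.df.columns]
    table.df[cols].to_csv(path, sep=_delimiter_for(path), index=False)


def read_rt_standards(path: str) -> RtStandardTable:
    """Read a two-column CSV of matched standard retention times.

    Column 1: fragment-run RT; column 2: molecular-ion-run RT (minutes).
    Pairs are sorted by fragment-run RT; both columns must then be strictly
    increasing (crossing standards are physically impossible).
    """
    try:
        raw = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse RT standards {path}: {exc}") from exc
    if raw.shape[1] < 2 or raw.empty:
        raise InputError(f"RT standards {path}: need two numeric columns with ≥1 row")
    a = pd.to_numeric(raw.iloc[:, 0], errors="coerce")
    b = pd.to_numeric(raw.iloc[:, 1], errors="coerce")
    if a.isna().any() or b.isna().any():
        raise InputError(f"RT standards {path}: non-numeric entries")
    order = np.argsort(a.to_numpy(), kind="stable")
    a = a.to_numpy()[order]
    b = b.to_numpy()[order]
    if len(a) > 1 and (np.diff(a).min() <= 0 or np.diff(b).min() <= 0):
        raise InputError(
            f"RT standards {path}: retention times must be strictly increasing in both runs "
            "(crossing standards)"
        )
    return RtStandardTable(rt_fragment=a, rt_molion=b)


def _centroid_local_maxima(mz: np.ndarray, intensity: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Reduce a profile trace to centroids at strict local intensity maxima."""
    if len(mz) < 3:
        return mz[intensity > 0], intensity[intensity > 0]
    i = intensity
    is_max = np.zeros(len(i), dtype=bool)
    is_max[1:-1] = (i[1:-1] > i[:-2]) & (i[1:-1] > i[2:]) & (i[1:-1] > 0)
    return mz[is_max], intensity[is_max]


def _rt_minutes(value) -> float:
    """Normalize a pyteomics scan-start-time value to minutes via its unit info."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit and "second" in str(unit):
        return v / 60.0
    return v


def _iter_mzml_spectra(path: str):
    """Yield (rt_minutes, mz, intensity, is_profile) from an mzML file.

    A compact namespace-agnostic reader covering the encodings in common use
    (32/64-bit floats, zlib or no compression); MS2+ spectra are skipped.
    """
    import xml.etree.ElementTree as ET
    import base64
    import zlib

    def localname(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    for _event, elem in ET.iterparse(path, events=("end",)):
        if localname(elem.tag) != "spectrum":
            continue
        params = {}  # accession -> (value, unitName)
        for cv in elem.iter():
            if localname(cv.tag) == "cvParam":
                params[cv.get("accession")] = (cv.get("value"), cv.get("unitName"))
        if params.get("MS:1000511", ("1", None))[0] not in (None, "", "1"):
            elem.clear()
            continue
        rt_val, rt_unit = params.get("MS:1000016", ("0", "minute"))
        rt = float(rt_val)
        if rt_unit and "second" in rt_unit:
            rt /= 60.0
        arrays = {}
        for bda in elem.iter():
            if localname(bda.tag) != "binaryDataArray":
                continue
            acc = {cv.get("accession") for cv in bda.iter() if localname(cv.tag) == "cvParam"}
            fmt = "f" if "MS:1000521" in acc else "d"
            text = ""
            for b in bda.iter():
                if localname(b.tag) == "binary":
                    text = b.text or ""
            data = base64.b64decode(text)
            if "MS:1000574" in acc:  # zlib
                data = zlib.decompress(data)
            values = np.frombuffer(data, dtype=np.dtype(f"<{fmt}")).astype(float)
            if "MS:1000514" in acc:
                arrays["mz"] = values
            elif "MS:1000515" in acc:
                arrays["intensity"] = values
        yield rt, arrays.get("mz", np.empty(0)), arrays.get(
            "intensity", np.empty(0)
        ), "MS:1000128" in params
        elem.clear()


def read_raw_run(path: str) -> RawRun:
    """Read an mzML or mzXML file into a centroided, rt-sorted :class:`RawRun`.

    mzXML goes through :mod:`pyteomics`; mzML through a built-in minimal reader
    (see :func:`_iter_mzml_spectra`).  Profile spectra are reduced to centroids
    at local intensity maxima.
    """
    lower = str(path).lower()
    scans: List[Scan] = []
    try:
        if lower.endswith(".mzml"):
            for rt, mzs, ints, is_profile in _iter_mzml_spectra(path):
                if is_profile:
                    mzs, ints = _centroid_local_maxima(mzs, ints)
                scans.append(Scan(rt=rt, mz=mzs, intensity=ints))
        elif lower.endswith(".mzxml"):
            from pyteomics import mzxml

            with mzxml.read(path) as reader:
                for spec in reader:
                    if int(spec.get("msLevel", 1)) != 1:
                        continue
                    rt = _rt_minutes(spec["retentionTime"])
                    mzs = np.asarray(spec["m/z array"], dtype=float)
                    ints = np.asarray(spec["intensity array"], dtype=float)
                    if not spec.get("centroided", True):
                        mzs, ints = _centroid_local_maxima(mzs, ints)
                    scans.append(Scan(rt=rt, mz=mzs, intensity=ints))
        else:
            raise InputError(f"unsupported raw format for {path}: expected .mzML or .mzXML")
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"cannot read raw file {path} ({type(exc).__name__}: {exc})") from exc
    return RawRun(scans=scans)


@dataclass
class ResultRow:
    """One ranked molecular-ion candidate for one EI pseudospectrum."""

    ei_group_id: str
    rank: int
    candidate_mz: float
    candidate_rt: float
    assigned_formula: Optional[Formula]
    probability_score: float  # percent, 0–100
    n_supporting_fragments: int
    adduct_evidence: Sequence[float]


RESULT_COLUMNS = [
    "ei_group_id",
    "rank",
    "candidate_mz",
    "candidate_rt",
    "assigned_formula",
    "probability_score",
    "n_supporting_fragments",
    "adduct_evidence",
]


def write_results(rows: Sequence[ResultRow], path: str) -> None:
    """Write ranked assignments as CSV, sorted by EI pseudospectrum then rank.

    Formulas are serialized in Hill order; adduct evidence as ';'-joined signed
    m/z differences at 5 decimals (matching the input convention).
    """
    records = []
    for r in sorted(rows, key=lambda r: (r.ei_group_id, r.rank)):
        records.append(
            {
                "ei_group_id": r.ei_group_id,
                "rank": r.rank,
                "candidate_mz": f"{r.candidate_mz:.5f}",
                "candidate_rt": f"{r.candidate_rt:.4f}",
                "assigned_formula": r.assigned_formula.hill() if r.assigned_formula else "",
                "probability_score": f"{r.probability_score:.2f}",
                "n_supporting_fragments": r.n_supporting_fragments,
                "adduct_evidence": ";".join(f"{d:+.5f}" for d in r.adduct_evidence),
            }
        )
    pd.DataFrame.from_records(records, columns=RESULT_COLUMNS).to_csv(path, index=False)
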