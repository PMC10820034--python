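"""Molecular-ion candidate detection via adduct / neutral-loss m/z differences.

Soft ionization leaves the (quasi-)molecular ion accompanied by a reagent-gas
signature: with methane CI, [M+H]+ carries [M+C2H5]+ (+28.03130) and [M+C3H5]+
(+40.03130) satellites and often an [M+H−CH4]+ loss (−16.03130).  An ion in a
molecular-ion pseudospectrum becomes a candidate when enough of these expected
differences are observed — in the deconvoluted features first, and optionally
in the raw data, where satellites too weak for deconvolution still show up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .peaklist_io import FLAG_NONE, RawRun

EVIDENCE_DECONVOLUTED = "deconvoluted"
EVIDENCE_RAW = "raw"

#: methane-CI defaults: ethyl/allyl adduct spacings and methane loss (Da)
DEFAULT_DELTAS = (28.03130, 40.03130, -16.03130)


@dataclass(frozen=True)
class AdductRule:
    """The m/z-difference pattern a molecular ion is expected to display."""

    deltas: Tuple[float, ...] = DEFAULT_DELTAS
    min_found: int = 2
    ppm: float = 3.0

    def __post_init__(self):
        if not self.deltas:
            raise ValueError("AdductRule needs at least one m/z difference")
        if not (1 <= self.min_found <= len(self.deltas)):
            raise ValueError("min_found must be between 1 and the number of deltas")
        if self.ppm <= 0:
            raise ValueError("ppm must be positive")


@dataclass
class CandidateIon:
    """A putative molecular-ion species with its adduct evidence."""

    mz: float
    rt: float  # corrected (fragment-run axis)
    rt_raw: float  # native molecular-ion-run axis, for raw-data lookups
    intensity: float
    source_group_id: str
    adduct_evidence: Tuple[float, ...]
    evidence_source: str  # 'deconvoluted' or 'raw' (raw if any delta needed raw data)
    feature_id: str = ""


def search_raw_peak(
    raw: RawRun,
    rt_center: float,
    rt_window: float,
    target_mz: float,
    ppm: float,
    noise_floor: float = 0.0,
) -> Tuple[bool, float]:
    """True (plus max intensity) iff a centroid within ppm of ``target_mz`` exists
    in any scan with \\|rt − rt_center\\| ≤ rt_window and intensity above the floor."""
    return raw.find_peak(rt_center, rt_window, target_mz, ppm, noise_floor=noise_floor)


def find_candidates(
    group: pd.DataFrame,
    rule: AdductRule,
    raw: Optional[RawRun] = None,
    rt_window: float = 0.05,
    group_rt_raw: Optional[float] = None,
    noise_floor: float = 0.0,
) -> List[CandidateIon]:
    """Scan one molecular-ion pseudospectrum for ions matching the adduct rule.

    Only unflagged features can be candidates (isotopologues are never the
    molecular ion), but satellites may be matched against any feature of the
    group.  For each delta d the ion at ``candidate.mz + d`` is sought first in
    the group within ppm; when absent and ``raw`` is given, in raw scans within
    ``rt_window`` of ``group_rt_raw`` (the group's RT on the raw file's axis).
    """
    all_mz = np.sort(group["mz"].to_numpy())
    base = group[group["isotope_flag"] == FLAG_NONE]
    if group_rt_raw is None and raw is not None:
        rt_col = "rt_raw" if "rt_raw" in group.columns else "rt"
        w = base["intensity"].to_numpy()
        group_rt_raw = float(np.average(base[rt_col].to_numpy(), weights=w))

    out: List[CandidateIon] = []
    for row in base.itertuples(index=False):
        evidence: List[float] = []
        used_raw = False
        for d in rule.deltas:
            target = row.mz + d
            if target <= 0:
                continue
            tol = abs(target) * rule.ppm * 1e-6
            i0 = np.searchsorted(all_mz, target - tol)
            i1 = np.searchsorted(all_mz, target + tol, side="right")
            hit = i1 > i0
            if not hit and raw is not None:
                hit, _ = raw.find_peak(group_rt_raw, rt_window, target, rule.ppm, noise_floor)
                used_raw = used_raw or hit
            if hit:
                evidence.append(d)
        if len(evidence) >= rule.min_found:
            out.append(
                CandidateIon(
                    mz=float(row.mz),
                    rt=float(row.rt),
                    rt_raw=float(getattr(row, "rt_raw", row.rt)),
                    intensity=float(row.intensity),
                    source_group_id=str(row.group_id),
                    adduct_evidence=tuple(evidence),
                    evidence_source=EVIDENCE_RAW if used_raw else EVIDENCE_DECONVOLUTED,
                    feature_id=str(row.feature_id),
                )
            )
    return out


def filter_top_candidates(
    candidates: Sequence[CandidateIon],
    top_x: int,
    mode: str = "by_mz",
) -> List[CandidateIon]:
    """Keep the top-x candidates by descending m/z (or intensity, for APCI data).

    Molecular ions sit at the top of the mass range of a spectrum, so low-m/z
    candidates are the least plausible.  Ties at the cutoff value are all
    retained.  ``mode='off'`` disables the filter.
    """
    if top_x < 1:
        raise ValueError("top_x must be >= 1")
    if mode == "off" or len(candidates) <= top_x:
        return sorted(candidates, key=_sort_key(mode), reverse=False)
    if mode == "by_mz":
        key = lambda c: c.mz
    elif mode == "by_intensity":
        key = lambda c: c.intensity
    else:
        raise ValueError(f"unknown top-x mode {mode!r}")
    ranked = sorted(candidates, key=key, reverse=True)
    cutoff = key(ranked[top_x - 1])
    return [c for c in ranked if key(c) >= cutoff]


def _sort_key(mode: str):
    if mode == "by_intensity":
        return lambda c: -c.intensity
    return lambda c: -c.mz
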