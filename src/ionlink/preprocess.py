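"""Peak-list preprocessing: size filtering, isotope flagging, RT correction, pairing.

The two runs (fragment-rich EI and soft-ionization CI/APCI) are connected only
through chromatography, so the pipeline first cleans each peak list, maps the
molecular-ion run's time axis onto the fragment run's axis using co-injected
retention-time standards, and then pairs pseudospectra that co-elute within a
tolerance window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .peaklist_io import FLAG_M1, FLAG_M2, FLAG_NONE, FeatureTable, RtStandardTable

# Da windows below a feature within which a more intense parent marks it as an
# isotopologue: wide enough for 13C, 15N, 18O, 34S and 37Cl spacings.
M1_WINDOW = (0.9970, 1.0100)
M2_WINDOW = (1.9940, 2.0100)


@dataclass
class SpectrumPair:
    """One EI pseudospectrum with its co-eluting molecular-ion pseudospectra."""

    ei_group_id: str
    ci_group_ids: List[str]
    rt_ei: float
    rt_ci_corrected: List[float]


def filter_pseudospectra(table: FeatureTable, min_features: int) -> FeatureTable:
    """Remove pseudospectra holding fewer than ``min_features`` features.

    Counting happens on the raw feature rows (before any isotope flagging);
    surviving pseudospectra are passed through untouched.  Idempotent.
    """
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    sizes = table.df["group_id"].value_counts()
    keep = sizes[sizes >= min_features].index
    df = table.df[table.df["group_id"].isin(keep)].reset_index(drop=True)
    return FeatureTable(df, table.run_label, table.n_rejected)


def flag_isotope_peaks(
    group: pd.DataFrame,
    m1_window: Tuple[float, float] = M1_WINDOW,
    m2_window: Tuple[float, float] = M2_WINDOW,
) -> pd.DataFrame:
    """Flag M+1 / M+2 isotopologues within one pseudospectrum.

    A feature is flagged when a strictly more intense feature of the same group
    sits below it at a Δm/z inside the M+1 (preferred) or M+2 window.  Flagged
    features are excluded from sum-formula work downstream but kept as evidence
    for isotope-pattern checks.  The result is independent of row order.
    """
    df = group.copy()
    mz = df["mz"].to_numpy()
    inten = df["intensity"].to_numpy()
    flags = np.array([FLAG_NONE] * len(df), dtype=object)
    for i in range(len(df)):
        delta = mz[i] - mz  # positive where mz[i] is above a potential parent
        stronger = inten > inten[i]
        if np.any(stronger & (delta >= m1_window[0]) & (delta <= m1_window[1])):
            flags[i] = FLAG_M1
        elif np.any(stronger & (delta >= m2_window[0]) & (delta <= m2_window[1])):
            flags[i] = FLAG_M2
    df["isotope_flag"] = flags
    return df


def flag_isotopes(table: FeatureTable) -> FeatureTable:
    """Apply :func:`flag_isotope_peaks` to every pseudospectrum of a table."""
    parts = [flag_isotope_peaks(g) for _, g in table.groups()]
    df = pd.concat(parts, ignore_index=True) if parts else table.df.copy()
    return FeatureTable(df, table.run_label, table.n_rejected)


def map_rt_to_fragment_axis(rt_molion, standards: RtStandardTable):
    """Map molecular-ion-run retention times onto the fragment-run axis.

    The shift between runs is modelled as piecewise linear between standard
    pairs; outside the outermost standards the boundary shift is held constant.
    Within the spanned interval this is exactly the piecewise-linear
    interpolation through (rt_molion, rt_fragment) pairs, which is the exact
    inverse of a piecewise-linear shift defined on the fragment axis.
    """
    v = np.atleast_1d(np.asarray(rt_molion, dtype=float))
    x = standards.rt_molion
    y = standards.rt_fragment
    if len(x) == 1:
        out = v - (x[0] - y[0])
    else:
        out = np.interp(v, x, y)
        below = v < x[0]
        above = v > x[-1]
        out[below] = v[below] - (x[0] - y[0])
        out[above] = v[above] - (x[-1] - y[-1])
    if np.isscalar(rt_molion) or np.ndim(rt_molion) == 0:
        return float(out[0])
    return out


def correct_rt(table: FeatureTable, standards: Optional[RtStandardTable]) -> FeatureTable:
    """Rewrite a molecular-ion-run table's RTs onto the fragment-run axis.

    The native time axis is preserved in an ``rt_raw`` column so later searches
    against the run's own raw data stay on the correct axis.  With ``standards``
    None the mapping is the identity (rt_raw still recorded).
    """
    df = table.df.copy()
    df["rt_raw"] = df["rt"].to_numpy()
    if standards is not None:
        df["rt"] = map_rt_to_fragment_axis(df["rt"].to_numpy(), standards)
    return FeatureTable(df, table.run_label, table.n_rejected)


def pseudospectrum_rt(group: pd.DataFrame, column: str = "rt") -> float:
    """Intensity-weighted mean RT of a pseudospectrum's unflagged features.

    Weighting by intensity keeps weak noise features from dragging the group's
    apex estimate; if everything is flagged, all features are used.
    """
    sub = group[group["isotope_flag"] == FLAG_NONE]
    if sub.empty:
        sub = group
    w = sub["intensity"].to_numpy()
    return float(np.average(sub[column].to_numpy(), weights=w))


def match_spectra(
    ei_table: FeatureTable,
    ci_table: FeatureTable,
    rt_tolerance: float,
) -> List[SpectrumPair]:
    """Attach to every EI pseudospectrum all CI pseudospectra within ±rt_tolerance.

    CI RTs must already be on the fragment-run axis (see :func:`correct_rt`).
    Boundaries are inclusive.  EI pseudospectra with no partner yield a pair
    with an empty CI list — reported, not silently dropped.
    """
    ci_rts = [(gid, pseudospectrum_rt(g)) for gid, g in ci_table.groups()]
    pairs: List[SpectrumPair] = []
    for ei_gid, ei_group in ei_table.groups():
        rt_ei = pseudospectrum_rt(ei_group)
        matched = [
            (gid, rt) for gid, rt in ci_rts if abs(rt - rt_ei) <= rt_tolerance + 1e-12
        ]
        pairs.append(
            SpectrumPair(
                ei_group_id=ei_gid,
                ci_group_ids=[gid for gid, _ in matched],
                rt_ei=rt_ei,
                rt_ci_corrected=[rt for _, rt in matched],
            )
        )
    return pairs
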