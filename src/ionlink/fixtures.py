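"""Synthetic paired EI/CI datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes: each
"compound" is a neutral formula eluting at one retention time; its EI
pseudospectrum holds fragment cations (all strict subformulas of the [M+H]+
composition, as produced by successive neutral losses), their 13C isotopologue
peaks, A+2 companions for S/Cl-bearing fragments, and Poisson-placed noise; its
CI pseudospectrum holds [M+H]+ with the configured adduct/neutral-loss
satellites, isotopologue peaks, residual fragment ions and noise.  CI retention
times are distorted by a constant or affine shift, and matching retention-time
standards plus raw runs (Gaussian-free centroid scans consistent with the peak
lists) are emitted alongside a truth table.

Difficulty knobs: ``noise_rate`` (noise features per signal feature),
``ambiguity_rate`` (fraction of compounds given one fragment whose mass admits
several formulas at the working tolerance, exercising the chain resolver),
``satellite_omission_rate`` (fraction of compounds whose molecular ion shows no
adduct pattern at all — the unassignable failure class), and co-elution
injection of a heavier compound inside the matching window.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .candidate_search import DEFAULT_DELTAS
from .errors import InputError
from .formula_engine import (
    A2_DELTA,
    ElementConstraints,
    Formula,
    IonType,
    enumerate_formulas,
    formula_mass,
    golden_rules_filter,
    rdbe,
)
from .peaklist_io import FLAG_NONE, FeatureTable, RawRun, RtStandardTable, Scan

C13_DELTA = 1.0033548378

# Common neutral losses used to derive fragment chains (NH3 only when N present).
_LOSSES = [
    Formula({"H": 2, "O": 1}),
    Formula({"C": 1, "O": 1}),
    Formula({"C": 2, "H": 4}),
    Formula({"C": 1, "H": 2, "O": 1}),
    Formula({"C": 2, "H": 2}),
    Formula({"C": 1, "O": 2}),
    Formula({"C": 1, "H": 3}),
    Formula({"N": 1, "H": 3}),
    Formula({"C": 3, "H": 6}),
]


@dataclass
class TrueCompound:
    """Ground-truth description of one synthetic analyte."""

    name: str
    neutral: Formula
    rt_true: float  # fragment-run axis, minutes
    fragments: List[Tuple[Formula, float]]  # (cation composition ⊂ [M+H]+, rel intensity)
    satellites: Tuple[float, ...]  # subset of the configured deltas this ion displays
    scale: float = 1e6
    has_ambiguous_fragment: bool = False

    @property
    def mplush_mz(self) -> float:
        return formula_mass(self.neutral, IonType.PROTONATED_MOLECULE)


def _try_subtract(f: Formula, loss: Formula) -> Optional[Formula]:
    counts = {el: f[el] - loss[el] for el in set(f) | set(loss)}
    if any(v < 0 for v in counts.values()):
        return None
    return Formula(counts)


def _random_neutral(rng: np.random.Generator) -> Formula:
    """A plausible CHNO(S) metabolite-like neutral molecule passing ratio filters."""
    while True:
        c = int(rng.integers(8, 23))
        o = int(rng.integers(1, 7))
        n = int(rng.integers(0, 3))
        s = 1 if rng.random() < 0.15 else 0
        rings = int(rng.integers(1, 7))
        h = 2 * c + n + 2 - 2 * rings
        if h < 6 or h > 50:
            continue
        f = Formula({"C": c, "H": h, "N": n, "O": o, "S": s})
        if golden_rules_filter([f]) and rdbe(f) >= 0:
            return f


def _fragment_chains(
    ion_comp: Formula,
    rng: np.random.Generator,
    n_chains: int,
    min_mz: float = 55.0,
) -> List[Formula]:
    """Distinct fragment compositions from successive random neutral losses."""
    seen: Dict[Formula, None] = {}
    for _ in range(n_chains):
        cur = ion_comp
        for _ in range(10):
            losses = [l for l in _LOSSES if _try_subtract(cur, l) is not None]
            losses = [l for l in losses if not (l["N"] and ion_comp["N"] == 0)]
            if not losses:
                break
            cur = _try_subtract(cur, losses[int(rng.integers(len(losses)))])
            if formula_mass(cur, IonType.CATION_GENERIC) < min_mz or cur["C"] == 0:
                break
            seen.setdefault(cur, None)
    return list(seen)


def generate_compound_set(
    n: int,
    seed: int,
    element_pool: Optional[ElementConstraints] = None,
    ambiguity_rate: float = 0.2,
    satellite_omission_rate: float = 0.0,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    ppm: float = 3.0,
    rt_span: Tuple[float, float] = (3.0, 37.0),
    min_fragments: int = 10,
) -> List[TrueCompound]:
    """Generate ``n`` ground-truth compounds, reproducibly under ``seed``.

    Every fragment of a compound without the "ambiguous" mark has a unique
    sum formula at ``ppm`` within ``element_pool`` (verified by enumeration at
    build time); ``round(ambiguity_rate·n)`` compounds additionally carry one
    fragment whose mass admits ≥2 formulas, and ``round(satellite_omission_rate·n)``
    compounds emit no adduct satellites at all.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = element_pool or ElementConstraints.default()
    if not pool.elements():
        raise InputError("element pool admits no elements; cannot build formulas")
    rng = np.random.default_rng(seed)

    n_ambig = int(round(ambiguity_rate * n))
    n_omit = int(round(satellite_omission_rate * n))
    ambig_idx = set(rng.choice(n, size=n_ambig, replace=False).tolist()) if n_ambig else set()
    omit_idx = set(rng.choice(n, size=n_omit, replace=False).tolist()) if n_omit else set()

    rts = np.linspace(rt_span[0], rt_span[1], n) + rng.uniform(-0.05, 0.05, size=n)

    compounds: List[TrueCompound] = []
    for i in range(n):
        want_ambiguous = i in ambig_idx
        compound = None
        for _attempt in range(40):
            neutral = _random_neutral(rng)
            ion_comp = neutral + {"H": 1}
            candidates = _fragment_chains(ion_comp, rng, n_chains=6)
            unique: List[Formula] = []
            ambiguous: List[Formula] = []
            for comp in sorted(candidates, key=lambda f: formula_mass(f)):
                mz = formula_mass(comp, IonType.CATION_GENERIC)
                hits = enumerate_formulas(mz, ppm, pool, IonType.CATION_GENERIC)
                (unique if len(hits) == 1 else ambiguous).append(comp)
            if len(unique) < min_fragments:
                continue
            if want_ambiguous and not ambiguous:
                continue
            frags = list(unique)
            if want_ambiguous:
                # keep the heaviest ambiguous fragment: hardest for the resolver
                frags.append(ambiguous[-1])
            rel = rng.uniform(0.05, 1.0, size=len(frags))
            rel /= rel.max()
            compound = TrueCompound(
                name=f"cmpd{i + 1}",
                neutral=neutral,
                rt_true=float(rts[i]),
                fragments=sorted(
                    zip(frags, rel.tolist()), key=lambda p: formula_mass(p[0])
                ),
                satellites=() if i in omit_idx else tuple(deltas),
                scale=float(rng.uniform(5e5, 5e6)),
                has_ambiguous_fragment=want_ambiguous,
            )
            break
        if compound is None:
            raise InputError(
                "could not build a compound under the given element pool / ambiguity settings"
            )
        compounds.append(compound)
    return compounds


def add_coeluting_heavies(
    compounds: Sequence[TrueCompound],
    indices: Sequence[int],
    seed: int,
    min_extra_mass: float = 60.0,
    rt_offset: float = 0.02,
) -> List[TrueCompound]:
    """Inject, for each selected compound, a heavier analyte eluting within the
    matching window — the classic failure mode where a big co-eluter outranks
    the true molecular ion.  Returns the extended compound list."""
    rng = np.random.default_rng(seed)
    out = list(compounds)
    for k, i in enumerate(indices):
        target = compounds[i]
        for _ in range(200):
            neutral = _random_neutral(rng)
            if formula_mass(neutral) >= formula_mass(target.neutral) + min_extra_mass:
                break
        else:
            raise InputError("could not draw a sufficiently heavy co-eluting compound")
        ion_comp = neutral + {"H": 1}
        frags = _fragment_chains(ion_comp, rng, n_chains=4)[:12]
        rel = rng.uniform(0.05, 1.0, size=max(len(frags), 1))
        rel /= rel.max()
        out.append(
            TrueCompound(
                name=f"heavy@{target.name}",
                neutral=neutral,
                rt_true=target.rt_true + rt_offset,
                fragments=sorted(zip(frags, rel.tolist()), key=lambda p: formula_mass(p[0])),
                satellites=target.satellites or tuple(DEFAULT_DELTAS),
                scale=target.scale * 1.5,
            )
        )
    return out


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the truth table."""

    ei_table: FeatureTable
    ci_table: FeatureTable
    ei_raw: RawRun
    ci_raw: RawRun
    rt_standards: RtStandardTable
    truth: pd.DataFrame  # ei_group_id, ci_group_id, name, neutral, mplush_mz, rt_true


def _shift_fn(model: Tuple):
    kind = model[0]
    if kind == "constant":
        c = model[1]
        return lambda rt: rt + c
    if kind == "affine":
        a, b = model[1], model[2]
        return lambda rt: a * rt + b
    if kind == "none":
        return lambda rt: rt
    raise ValueError(f"unknown rt shift model {model!r}")


def render_datasets(
    compounds: Sequence[TrueCompound],
    rt_shift_model: Tuple = ("affine", 1.01, 0.02),
    noise_rate: float = 0.05,
    seed: int = 0,
    satellite_peaklist_dropout: float = 0.0,
    standards_at: Sequence[float] = (2.0, 20.0, 38.0),
    ci_residual_fragments: bool = True,
) -> SyntheticDataset:
    """Render compounds into paired peak lists, raw runs, RT standards and truth.

    ``satellite_peaklist_dropout``: probability that a compound's satellites are
    present only in the raw CI data (deconvolution "missed" them), exercising
    the raw-search fallback.  ``ci_residual_fragments=False`` renders bare CI
    spectra ([M+H]+, isotopologues, satellites only), isolating the adduct
    pattern from coincidental fragment spacings.  Noise feature counts are
    Poisson with mean ``noise_rate`` × (signal features in the group).
    """
    rng = np.random.default_rng(seed)
    shift = _shift_fn(rt_shift_model)

    ei_rows: List[dict] = []
    ci_rows: List[dict] = []
    ei_scans: List[Scan] = []
    ci_scans: List[Scan] = []
    truth_rows: List[dict] = []

    def emit(rows: List[dict], gid: str, mz: float, rt: float, inten: float, tag: str):
        rows.append(
            {
                "feature_id": f"{gid}:{tag}:{len(rows)}",
                "mz": mz,
                "rt": rt,
                "intensity": inten,
                "group_id": gid,
                "isotope_flag": FLAG_NONE,
            }
        )

    for i, cmpd in enumerate(compounds):
        ei_gid = f"E{i + 1}"
        ci_gid = f"C{i + 1}"
        rt_ei = cmpd.rt_true
        rt_ci = shift(cmpd.rt_true)
        drop_sats = rng.random() < satellite_peaklist_dropout

        # ---- EI pseudospectrum --------------------------------------------
        n_ei_start = len(ei_rows)
        for comp, rel in cmpd.fragments:
            mz = formula_mass(comp, IonType.CATION_GENERIC)
            inten = rel * cmpd.scale
            jitter = rt_ei + float(rng.uniform(-0.002, 0.002))
            emit(ei_rows, ei_gid, mz, jitter, inten, "frag")
            if comp["C"]:
                emit(ei_rows, ei_gid, mz + C13_DELTA, jitter, 0.0107 * comp["C"] * inten, "M1")
            for el, frac in (("S", 0.0442), ("Cl", 0.3196)):
                if comp[el]:
                    emit(ei_rows, ei_gid, mz + A2_DELTA[el], jitter, frac * comp[el] * inten, "A2")
        n_signal = len(ei_rows) - n_ei_start
        for _ in range(int(rng.poisson(noise_rate * n_signal))):
            emit(
                ei_rows,
                ei_gid,
                float(rng.uniform(55.0, 1.1 * cmpd.mplush_mz)),
                rt_ei + float(rng.uniform(-0.002, 0.002)),
                float(rng.uniform(0.01, 0.08)) * cmpd.scale,
                "noise",
            )

        # ---- CI pseudospectrum --------------------------------------------
        n_ci_start = len(ci_rows)
        mzM = cmpd.mplush_mz
        ci_scale = cmpd.scale * float(rng.uniform(0.3, 1.5))
        emit(ci_rows, ci_gid, mzM, rt_ci, ci_scale, "MH")
        nC = cmpd.neutral["C"]
        emit(ci_rows, ci_gid, mzM + C13_DELTA, rt_ci, 0.0107 * nC * ci_scale, "M1")
        emit(ci_rows, ci_gid, mzM + 2 * C13_DELTA, rt_ci, (0.0107 * nC) ** 2 / 2 * ci_scale, "M2")
        for el, frac in (("S", 0.0442), ("Cl", 0.3196)):
            if cmpd.neutral[el]:
                emit(ci_rows, ci_gid, mzM + A2_DELTA[el], rt_ci, frac * cmpd.neutral[el] * ci_scale, "A2")
        sat_rows: List[Tuple[float, float]] = []
        for d in cmpd.satellites:
            sat_rows.append((mzM + d, float(rng.uniform(0.05, 0.15)) * ci_scale))
        if not drop_sats:
            for mz, inten in sat_rows:
                emit(ci_rows, ci_gid, mz, rt_ci, inten, "sat")
        if ci_residual_fragments:  # residual CI fragmentation keeps spectra rich
            for comp, rel in cmpd.fragments:
                mz = formula_mass(comp, IonType.CATION_GENERIC)
                inten = rel * float(rng.uniform(0.01, 0.1)) * ci_scale
                emit(ci_rows, ci_gid, mz, rt_ci, inten, "resid")
                if comp["C"]:
                    emit(
                        ci_rows, ci_gid, mz + C13_DELTA, rt_ci,
                        0.0107 * comp["C"] * inten, "residM1",
                    )
        n_ci_signal = len(ci_rows) - n_ci_start
        for _ in range(int(rng.poisson(noise_rate * n_ci_signal))):
            emit(
                ci_rows,
                ci_gid,
                float(rng.uniform(80.0, 1.1 * mzM)),
                rt_ci,
                float(rng.uniform(0.005, 0.05)) * ci_scale,
                "noise",
            )

        # ---- raw scans: three centroid scans around each apex --------------
        ei_group = [r for r in ei_rows[n_ei_start:]]
        ci_group = [r for r in ci_rows[n_ci_start:]]
        ci_raw_peaks = [(r["mz"], r["intensity"]) for r in ci_group] + (
            sat_rows if drop_sats else []
        )
        for dt in (-0.008, 0.0, 0.008):
            ei_scans.append(
                Scan(
                    rt=rt_ei + dt,
                    mz=np.array([r["mz"] for r in ei_group]),
                    intensity=np.array([r["intensity"] for r in ei_group]),
                )
            )
            ci_scans.append(
                Scan(
                    rt=rt_ci + dt,
                    mz=np.array([p[0] for p in ci_raw_peaks]),
                    intensity=np.array([p[1] for p in ci_raw_peaks]),
                )
            )

        truth_rows.append(
            {
                "ei_group_id": ei_gid,
                "ci_group_id": ci_gid,
                "name": cmpd.name,
                "neutral": cmpd.neutral.hill(),
                "mplush_mz": mzM,
                "rt_true": rt_ei,
                "has_satellites": bool(cmpd.satellites),
            }
        )

    standards = RtStandardTable(
        rt_fragment=np.asarray(standards_at, dtype=float),
        rt_molion=np.asarray([shift(t) for t in standards_at], dtype=float),
    )
    return SyntheticDataset(
        ei_table=FeatureTable(pd.DataFrame(ei_rows), "fragment_run"),
        ci_table=FeatureTable(pd.DataFrame(ci_rows), "molion_run"),
        ei_raw=RawRun(scans=ei_scans),
        ci_raw=RawRun(scans=ci_scans),
        rt_standards=standards,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Minimal mzML serialization (synthetic; only the subset the reader needs).
# ---------------------------------------------------------------------------

def _b64_doubles(values: Sequence[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode("ascii")


def write_mzml(raw: RawRun, path: str, profile: bool = False) -> None:
    """Serialize a :class:`RawRun` as a minimal mzML file (synthetic writer).

    Emits MS1 spectra with 64-bit uncompressed arrays and minute-unit scan
    start times — just enough structure for standard mzML readers; not a
    validating, full-featured exporter.
    """
    mode_acc, mode_name = (
        ("MS:1000128", "profile spectrum") if profile else ("MS:1000127", "centroid spectrum")
    )
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <run id="synthetic">',
        f'    <spectrumList count="{len(raw.scans)}">',
    ]
    for i, scan in enumerate(raw.scans):
        mz_b64 = _b64_doubles(scan.mz.tolist())
        int_b64 = _b64_doubles(scan.intensity.tolist())
        parts += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan.mz)}">',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
            f'        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>',
            '        <scanList count="1">',
            "          <scan>",
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt:.6f}" unitAccession="UO:0000031" unitName="minute"/>',
            "          </scan>",
            "        </scanList>",
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitAccession="MS:1000040" unitName="m/z"/>',
            f"            <binary>{mz_b64}</binary>",
            "          </binaryDataArray>",
            f'          <binaryDataArray encodedLength="{len(int_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitAccession="MS:1000131" unitName="number of detector counts"/>',
            f"            <binary>{int_b64}</binary>",
            "          </binaryDataArray>",
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    parts += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_rt_standards_csv(standards: RtStandardTable, path: str) -> None:
    pd.DataFrame(
        {"rt_fragment_run": standards.rt_fragment, "rt_molion_run": standards.rt_molion}
    ).to_csv(path, index=False, float_format="%.6f")


def rank_of_truth(
    entries,
    true_mz: float,
    ppm: float = 3.0,
    abs_tol: float = 0.002,
) -> Optional[int]:
    """1-based rank of the true molecular ion in a ranked entry list (None if absent)."""
    tol = max(true_mz * ppm * 1e-6, abs_tol)
    for i, e in enumerate(entries):
        if abs(e.candidate.mz - true_mz) <= tol:
            return i + 1
    return None
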