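"""Bottom-up fragment formula assignment and molecular-ion candidate ranking.

The central assumption: every fragment of a molecular ion carries a subformula
of that ion's composition.  Because mass accuracy is relative (ppm), small
fragments usually admit a single sum formula; larger ions admit several.  The
resolver therefore walks a fragment pseudospectrum bottom-up in m/z, and when
an ion is ambiguous, scores each candidate formula by how much already-resolved
smaller-fragment evidence it contains, where each resolved fragment contributes

    weight = m/z × ln(rel_intensity × 100 + 1)

— log-scaled so a handful of dominant peaks cannot monopolize the evidence, and
m/z-weighted because heavy fragments constrain the precursor far more than
light ones.  Molecular-ion candidates are then ranked by the percentage of
total resolved-fragment weight whose formulas fit inside their [M+H]+
composition; that percentage is the reported probability score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .candidate_search import AdductRule, CandidateIon, filter_top_candidates, find_candidates
from .formula_engine import (
    ElementConstraints,
    Formula,
    IonType,
    enumerate_formulas,
    formula_mass,
    golden_rules_filter,
    is_subformula,
    isotope_pattern_check,
)
from .peaklist_io import FLAG_NONE, FeatureTable, RawRun, ResultRow
from .preprocess import SpectrumPair

_H = {"H": 1}


@dataclass
class FragmentAssignment:
    """Outcome of formula assignment for one fragment ion."""

    feature_id: str
    mz: float
    rel_intensity: float
    retained_formulas: Tuple[Formula, ...]
    weight: float
    resolved: bool

    @property
    def formula(self) -> Optional[Formula]:
        return self.retained_formulas[0] if self.resolved else None


@dataclass
class RankedEntry:
    candidate: CandidateIon
    formulas: Tuple[Formula, ...]  # surviving neutral formulas (may be empty)
    best_formula: Optional[Formula]  # neutral molecule M
    probability_score: float  # percent of resolved-fragment weight supporting it
    n_supporting_fragments: int
    dppm: float  # |Δppm| of the best formula's [M+H]+ vs the measured m/z


@dataclass
class RankedAssignment:
    """Ranked molecular-ion candidates for one EI pseudospectrum."""

    ei_group_id: str
    entries: List[RankedEntry]

    def to_result_rows(self) -> List[ResultRow]:
        return [
            ResultRow(
                ei_group_id=self.ei_group_id,
                rank=i + 1,
                candidate_mz=e.candidate.mz,
                candidate_rt=e.candidate.rt,
                assigned_formula=e.best_formula,
                probability_score=e.probability_score,
                n_supporting_fragments=e.n_supporting_fragments,
                adduct_evidence=e.candidate.adduct_evidence,
            )
            for i, e in enumerate(self.entries)
        ]


def fragment_weight(mz: float, rel_intensity: float) -> float:
    """Evidence weight of one fragment: ``mz × ln(rel_intensity × 100 + 1)``.

    ``rel_intensity`` is the fragment's intensity as a fraction of the
    pseudospectrum's base peak, so the logarithm's argument spans 1…101.
    Zero intensity contributes zero weight; the function increases strictly in
    both arguments.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if not (0 <= rel_intensity <= 1):
        raise ValueError("rel_intensity must be within [0, 1]")
    return mz * math.log(rel_intensity * 100.0 + 1.0)


def _ion_dppm(f: Formula, mz: float, ion: IonType) -> float:
    return abs(formula_mass(f, ion) - mz) / mz * 1e6


def _surviving_formulas(
    mz: float,
    rt: float,
    constraints: ElementConstraints,
    ppm: float,
    ion: IonType,
    isotope_source,
    rt_window: float,
    noise_floor: float,
) -> List[Formula]:
    """enumerate → element-ratio filter → A+2 isotope veto, order preserved."""
    formulas = enumerate_formulas(mz, ppm, constraints, ion)
    formulas = golden_rules_filter(formulas)
    if isotope_source is not None:
        formulas = [
            f
            for f in formulas
            if isotope_pattern_check(
                f, mz, rt, isotope_source, ppm, rt_window=rt_window, noise_floor=noise_floor
            )
        ]
    return formulas


def assign_fragment_formulas(
    group: pd.DataFrame,
    constraints: ElementConstraints,
    ppm: float,
    raw: Optional[RawRun] = None,
    rt_window: float = 0.05,
    noise_floor: float = 0.0,
) -> List[FragmentAssignment]:
    """Chain-assign one sum formula per fragment, smallest m/z first.

    Isotope-flagged features are excluded (they are isotopologues, not distinct
    fragments) but remain available as evidence for the A+2 check when no raw
    run is supplied.  Each fragment's candidate formulas are enumerated as
    generic cations, ratio-filtered and isotope-vetoed; a unique survivor is
    assigned outright, while an ambiguous set is resolved to the formula best
    supported by previously resolved smaller fragments (summed weights of those
    whose formulas it contains).  When no smaller fragment discriminates, all
    formulas are retained and the fragment stays unresolved.
    """
    sub = group[group["isotope_flag"] == FLAG_NONE].sort_values(
        ["mz", "feature_id"], kind="stable"
    )
    if sub.empty:
        return []
    base_intensity = float(sub["intensity"].max())
    isotope_source = raw if raw is not None else group["mz"].tolist()

    assignments: List[FragmentAssignment] = []
    resolved: List[FragmentAssignment] = []
    for row in sub.itertuples(index=False):
        rel = float(row.intensity) / base_intensity
        weight = fragment_weight(float(row.mz), rel)
        formulas = _surviving_formulas(
            float(row.mz),
            float(row.rt),
            constraints,
            ppm,
            IonType.CATION_GENERIC,
            isotope_source,
            rt_window,
            noise_floor,
        )
        if len(formulas) == 1:
            a = FragmentAssignment(
                str(row.feature_id), float(row.mz), rel, (formulas[0],), weight, True
            )
        elif len(formulas) == 0:
            a = FragmentAssignment(str(row.feature_id), float(row.mz), rel, (), weight, False)
        else:
            support = [
                sum(r.weight for r in resolved if is_subformula(r.formula, f)) for f in formulas
            ]
            best = max(support)
            if best <= 0:
                a = FragmentAssignment(
                    str(row.feature_id), float(row.mz), rel, tuple(formulas), weight, False
                )
            else:
                # deterministic tie-break: mass agreement, then Hill string
                order = sorted(
                    range(len(formulas)),
                    key=lambda i: (
                        -support[i],
                        _ion_dppm(formulas[i], float(row.mz), IonType.CATION_GENERIC),
                        formulas[i].hill(),
                    ),
                )
                a = FragmentAssignment(
                    str(row.feature_id), float(row.mz), rel, (formulas[order[0]],), weight, True
                )
        assignments.append(a)
        if a.resolved:
            resolved.append(a)
    return assignments


def score_candidates(
    assignments: Sequence[FragmentAssignment],
    candidates: Sequence[Tuple[CandidateIon, Sequence[Formula]]],
    ei_group_id: str = "",
) -> RankedAssignment:
    """Rank molecular-ion candidates by resolved-fragment support.

    The denominator is the summed weight of all resolved fragments (100%).  A
    candidate's numerator sums the weights of resolved fragments whose assigned
    formula fits inside the candidate's [M+H]+ composition (neutral + 1 H); a
    candidate with several surviving formulas is scored by its best one.
    Ties are broken toward higher m/z, then better mass agreement.
    """
    resolved = [a for a in assignments if a.resolved]
    denom = sum(a.weight for a in resolved)

    entries: List[RankedEntry] = []
    for cand, formulas in candidates:
        best_formula: Optional[Formula] = None
        best_score = 0.0
        best_n = 0
        best_dppm = float("inf")
        for f in formulas:
            ion_comp = f + _H
            supporters = [a for a in resolved if is_subformula(a.formula, ion_comp)]
            num = sum(a.weight for a in supporters)
            score = 100.0 * num / denom if denom > 0 else 0.0
            dppm = _ion_dppm(f, cand.mz, IonType.PROTONATED_MOLECULE)
            if best_formula is None or (score, -dppm) > (best_score, -best_dppm):
                best_formula, best_score, best_n, best_dppm = f, score, len(supporters), dppm
        entries.append(
            RankedEntry(
                candidate=cand,
                formulas=tuple(formulas),
                best_formula=best_formula,
                probability_score=best_score,
                n_supporting_fragments=best_n,
                dppm=best_dppm if best_formula is not None else float("inf"),
            )
        )
    # formula-less candidates score 0 and sink below every formula-bearing one
    entries.sort(
        key=lambda e: (
            -e.probability_score,
            e.best_formula is None,
            -e.candidate.mz,
            e.dppm,
        )
    )
    return RankedAssignment(ei_group_id=ei_group_id, entries=entries)


def _dedupe_candidates(
    candidates: List[CandidateIon], ppm: float, rt_tolerance: float
) -> List[CandidateIon]:
    """Merge candidates found in several matched CI groups: same m/z within ppm
    and corrected RT within tolerance collapse to the most intense instance."""
    kept: List[CandidateIon] = []
    for c in sorted(candidates, key=lambda c: (-c.intensity, c.mz)):
        dup = any(
            abs(c.mz - k.mz) <= k.mz * ppm * 1e-6 and abs(c.rt - k.rt) <= rt_tolerance
            for k in kept
        )
        if not dup:
            kept.append(c)
    return kept


def rank_molecular_ions(
    pair: SpectrumPair,
    ei_table: FeatureTable,
    ci_table: FeatureTable,
    rule: AdductRule,
    *,
    constraints: ElementConstraints,
    ppm: float = 3.0,
    top_x: int = 10,
    top_x_mode: str = "by_mz",
    rt_tolerance: float = 0.05,
    ei_raw: Optional[RawRun] = None,
    ci_raw: Optional[RawRun] = None,
    noise_floor: float = 0.0,
) -> RankedAssignment:
    """Full per-pseudospectrum pipeline: candidates → formulas → chain → ranking.

    Deterministic for identical inputs and parameters.  An empty candidate list
    (no molecular ion displayed the adduct pattern) yields empty entries.
    """
    ei_group = ei_table.df[ei_table.df["group_id"] == pair.ei_group_id]

    candidates: List[CandidateIon] = []
    for ci_gid in pair.ci_group_ids:
        ci_group = ci_table.df[ci_table.df["group_id"] == ci_gid]
        candidates.extend(
            find_candidates(
                ci_group, rule, raw=ci_raw, rt_window=rt_tolerance, noise_floor=noise_floor
            )
        )
    candidates = _dedupe_candidates(candidates, rule.ppm, rt_tolerance)
    candidates = filter_top_candidates(candidates, top_x, top_x_mode)

    if not candidates:
        return RankedAssignment(ei_group_id=pair.ei_group_id, entries=[])

    assignments = assign_fragment_formulas(
        ei_group, constraints, ppm, raw=ei_raw, rt_window=rt_tolerance, noise_floor=noise_floor
    )

    scored: List[Tuple[CandidateIon, Sequence[Formula]]] = []
    for cand in candidates:
        ci_group = ci_table.df[ci_table.df["group_id"] == cand.source_group_id]
        isotope_source = ci_raw if ci_raw is not None else ci_group["mz"].tolist()
        formulas = _surviving_formulas(
            cand.mz,
            cand.rt_raw,
            constraints,
            ppm,
            IonType.PROTONATED_MOLECULE,
            isotope_source,
            rt_tolerance,
            noise_floor,
        )
        scored.append((cand, formulas))
    return score_candidates(assignments, scored, ei_group_id=pair.ei_group_id)
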