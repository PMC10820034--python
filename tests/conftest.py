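"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import ionlink as il
from ionlink.formula_engine import ELECTRON_MASS, MONOISOTOPIC_MASS


# ---------------------------------------------------------------------------
# Independent oracles (naive code paths, kept free of the package's search logic)
# ---------------------------------------------------------------------------

def naive_enumerate(mz, ppm, bounds, ion):
    """Exhaustive grid enumeration of formulas within ±ppm of mz.

    ``bounds``: {element: (lo, hi)}.  Builds the full count grid with numpy and
    filters by mass — no pruning, no recursion; independent of the package's
    depth-first search.  Returns a set of frozen (element, count) tuples.
    """
    if ion is il.IonType.PROTONATED_MOLECULE:
        target = mz - (MONOISOTOPIC_MASS["H"] - ELECTRON_MASS)
    else:
        target = mz + ELECTRON_MASS
    tol = mz * ppm * 1e-6
    elems = list(bounds)
    axes = [np.arange(lo, hi + 1) for lo, hi in bounds.values()]
    grids = np.meshgrid(*axes, indexing="ij")
    mass = np.zeros(grids[0].shape)
    for g, el in zip(grids, elems):
        mass = mass + g * MONOISOTOPIC_MASS[el]
    hits = np.argwhere(np.abs(mass - target) <= tol + 1e-12)
    out = set()
    for row in hits:
        counts = tuple(
            sorted(
                (str(el), int(axes[k][i]))
                for k, (el, i) in enumerate(zip(elems, row))
                if axes[k][i] > 0
            )
        )
        if counts:
            out.add(counts)
    return out


def as_key(formula: il.Formula):
    return tuple(sorted(formula.items()))


def naive_subformula(small: dict, big: dict) -> bool:
    return all(big.get(el, 0) >= n for el, n in small.items())


def naive_chain_assign(fragment_specs):
    """Independent sequential resolver used to cross-check the chained assignment.

    ``fragment_specs``: list of (mz, weight, [candidate formula dicts]) already
    sorted ascending in m/z.  Returns the list of resolved formula dicts (None
    where unresolved), applying the same semantics with plain dict arithmetic.
    """
    resolved = []  # (formula dict, weight)
    out = []
    for mz, weight, cands in fragment_specs:
        if len(cands) == 1:
            out.append(cands[0])
            resolved.append((cands[0], weight))
        elif not cands:
            out.append(None)
        else:
            scores = []
            for f in cands:
                scores.append(sum(w for g, w in resolved if naive_subformula(g, f)))
            best = max(scores)
            if best <= 0:
                out.append(None)
            else:
                winners = [f for f, s in zip(cands, scores) if s == best]
                # mirror the package's tie-break: best mass agreement first
                winners.sort(
                    key=lambda f: abs(
                        sum(n * MONOISOTOPIC_MASS[e] for e, n in f.items()) - ELECTRON_MASS - mz
                    )
                )
                out.append(winners[0])
                resolved.append((winners[0], weight))
    return out


def naive_score(resolved_weights, candidate_formula: dict) -> float:
    """Percent of resolved-fragment weight contained in candidate's [M+H]+ composition."""
    ion = dict(candidate_formula)
    ion["H"] = ion.get("H", 0) + 1
    denom = sum(w for _f, w in resolved_weights)
    if denom == 0:
        return 0.0
    num = sum(w for f, w in resolved_weights if naive_subformula(f, ion))
    return 100.0 * num / denom


# ---------------------------------------------------------------------------
# Shared synthetic datasets (module-scoped: generation dominates the runtime)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_compounds():
    return il.generate_compound_set(10, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_compounds):
    return il.render_datasets(small_compounds, seed=1)


@pytest.fixture(scope="session")
def prepared_small(small_dataset):
    """(ei, ci, pairs) after size filter, isotope flagging and RT correction."""
    ds = small_dataset
    ei = il.flag_isotopes(il.filter_pseudospectra(ds.ei_table, 20))
    ci = il.flag_isotopes(il.filter_pseudospectra(ds.ci_table, 20))
    ci = il.correct_rt(ci, ds.rt_standards)
    pairs = il.match_spectra(ei, ci, 0.05)
    return ei, ci, pairs
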