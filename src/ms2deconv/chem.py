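"""Elemental formula arithmetic, formula prediction, and isotope patterns.

Monoisotopic masses and natural isotope abundances come from the NIST table
bundled with pyteomics.  Formula prediction is a bounded CHNOPS enumeration
filtered by ring-plus-double-bond equivalents and simple element-ratio
plausibility, ranked by |Δppm|.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from pyteomics.mass import Composition, nist_mass

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990907

#: adduct name -> (mass shift added to the neutral molecule, charge)
ADDUCT_TABLE = {
    "[M+H]+": (PROTON_MASS, +1),
    "[M+Na]+": (22.98976928 - ELECTRON_MASS, +1),
    "[M+NH4]+": (18.03437413 - ELECTRON_MASS, +1),
    "[M-H]-": (-PROTON_MASS, -1),
}

DEFAULT_ADDUCTS_POS = ("[M+H]+", "[M+Na]+", "[M+NH4]+")
DEFAULT_ADDUCTS_NEG = ("[M-H]-",)

#: default upper bounds for the CHNOPS enumeration
DEFAULT_ELEMENT_BOUNDS = {"C": 40, "H": 80, "N": 10, "O": 20, "P": 5, "S": 5}

_MONO = {el: nist_mass[el][0][0] for el in ("C", "H", "N", "O", "P", "S", "Na", "Cl")}


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into element counts."""
    try:
        comp = Composition(formula=formula)
    except Exception as exc:
        raise ValueError(f"unparseable formula {formula!r}") from exc
    return {el: int(n) for el, n in comp.items() if n}


def formula_to_string(counts: dict[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    counts = {el: n for el, n in counts.items() if n}
    parts = []
    for el in ("C", "H"):
        if el in counts:
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
    for el in sorted(k for k in counts if k not in ("C", "H")):
        n = counts[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: str | dict) -> float:
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(_MONO[el] * n for el, n in counts.items())


def rdbe(counts: dict[str, int]) -> float:
    """Ring-plus-double-bond equivalents over CHNOPS."""
    return (
        counts.get("C", 0)
        - (counts.get("H", 0)) / 2.0
        + (counts.get("N", 0) + counts.get("P", 0)) / 2.0
        + 1.0
    )


def is_submultiset(sub: dict[str, int], sup: dict[str, int]) -> bool:
    """True iff every element count of ``sub`` fits inside ``sup`` and no new
    element type appears."""
    return all(el in sup and n <= sup[el] for el, n in sub.items() if n > 0)


@dataclass
class FormulaCandidate:
    formula: str
    counts: dict[str, int]
    neutral_mass: float
    adduct: str
    ppm_error: float


def _plausible(counts: dict[str, int]) -> bool:
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    if c == 0:
        # small inorganics (water, ammonia, ...) are allowed
        return sum(counts.values()) <= 12
    if h / c > 4.0 or h / c < 0.1:
        return False
    for el, cap in (("N", 2.0), ("O", 3.0), ("P", 1.0), ("S", 1.0)):
        if counts.get(el, 0) / c > cap:
            return False
    return True


def predict_formula(
    mz: float,
    polarity: str = "positive",
    adducts: tuple[str, ...] | None = None,
    ppm_tol: float = 5.0,
    element_bounds: dict[str, int] | None = None,
    neutral: bool = False,
) -> list[FormulaCandidate]:
    """Enumerate CHNOPS formulas matching an observed m/z.

    For each allowed adduct the implied neutral mass is searched; candidates
    require RDBE ≥ 0 and pass element-ratio plausibility, and are ranked by
    |Δppm| (ties by fewer heteroatoms).
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    bounds = dict(DEFAULT_ELEMENT_BOUNDS)
    if element_bounds:
        bounds.update(element_bounds)
    if neutral:
        targets = [("", mz)]
    else:
        if adducts is None:
            adducts = DEFAULT_ADDUCTS_POS if polarity == "positive" else DEFAULT_ADDUCTS_NEG
        targets = []
        for name in adducts:
            shift, charge = ADDUCT_TABLE[name]
            targets.append((name, mz * abs(charge) - shift))

    mC, mH, mN, mO, mP, mS = (_MONO[e] for e in "CHNOPS")
    out: list[FormulaCandidate] = []
    for adduct, target in targets:
        if target <= 0:
            continue
        tol = target * ppm_tol * 1e-6
        for nC in range(0, min(bounds["C"], int(target / mC)) + 1):
            base_c = nC * mC
            if base_c > target + tol:
                break
            for nS in range(0, bounds["S"] + 1):
                base_s = base_c + nS * mS
                if base_s > target + tol:
                    break
                for nP in range(0, bounds["P"] + 1):
                    base_p = base_s + nP * mP
                    if base_p > target + tol:
                        break
                    for nN in range(0, bounds["N"] + 1):
                        base_n = base_p + nN * mN
                        if base_n > target + tol:
                            break
                        for nO in range(0, bounds["O"] + 1):
                            base_o = base_n + nO * mO
                            if base_o > target + tol:
                                break
                            rem = target - base_o
                            # H count window implied by the mass tolerance
                            h_lo = int(np.ceil((rem - tol) / mH))
                            h_hi = int(np.floor((rem + tol) / mH))
                            for nH in range(max(h_lo, 0), min(h_hi, bounds["H"]) + 1):
                                counts = {
                                    "C": nC, "H": nH, "N": nN,
                                    "O": nO, "P": nP, "S": nS,
                                }
                                counts = {k: v for k, v in counts.items() if v}
                                if not counts:
                                    continue
                                if rdbe(counts) < 0 or not _plausible(counts):
                                    continue
                                mass = base_o + nH * mH
                                out.append(FormulaCandidate(
                                    formula=formula_to_string(counts),
                                    counts=counts,
                                    neutral_mass=mass,
                                    adduct=adduct,
                                    ppm_error=1e6 * (mass - target) / target,
                                ))
    out.sort(key=lambda f: (abs(f.ppm_error), sum(
        n for el, n in f.counts.items() if el not in ("C", "H"))))
    return out


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

# per-atom probability of contributing a nominal mass shift of 0 / +1 / +2
_ISOTOPE_POLY: dict[str, np.ndarray] = {}


def _element_poly(el: str) -> np.ndarray:
    if el not in _ISOTOPE_POLY:
        iso = nist_mass[el]
        mono = round(iso[0][0])
        poly = np.zeros(3)
        for nominal, (m, abundance) in iso.items():
            if nominal == 0 or abundance == 0:
                continue
            shift = nominal - mono
            if 0 <= shift <= 2:
                poly[shift] += abundance
        _ISOTOPE_POLY[el] = poly
    return _ISOTOPE_POLY[el]


def _poly_power(poly: np.ndarray, n: int) -> np.ndarray:
    """``poly**n`` truncated to shifts 0..2, by exponentiation-by-squaring."""
    result = np.array([1.0, 0.0, 0.0])
    base = poly.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:3]
        base = np.convolve(base, base)[:3]
        n >>= 1
    return result


@lru_cache(maxsize=4096)
def theoretical_isotope_pattern(formula: str) -> tuple[float, float]:
    """Relative abundances of the M+1 and M+2 isotopologues (fractions of M).

    Considers ¹³C, ²H, ¹⁵N, ¹⁷O/¹⁸O and ³³S/³⁴S; phosphorus is monoisotopic
    and contributes nothing; other elements are rejected.
    """
    counts = parse_formula(formula)
    supported = {"C", "H", "N", "O", "S", "P"}
    for el in counts:
        if el not in supported:
            raise ValueError(f"element {el!r} unsupported in isotope-pattern computation")
    dist = np.array([1.0, 0.0, 0.0])
    for el, n in counts.items():
        if el == "P" or n == 0:
            continue
        dist = np.convolve(dist, _poly_power(_element_poly(el), n))[:3]
    if dist[0] <= 0:
        raise ValueError(f"degenerate isotope distribution for {formula!r}")
    return float(dist[1] / dist[0]), float(dist[2] / dist[0])
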