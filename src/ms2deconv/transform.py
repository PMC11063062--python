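"""One-hop abiotic/bio-transformation networks around a formula.

The rule table is a curated set of common transformation deltas
(hydrogenation, methylation, oxidation, glucuronidation, sulfation, ...)
shipped as an editable tab-separated resource.  Networks are deliberately
one hop deep: neighbors of neighbors are never expanded, which avoids
combinatorial redundancy in downstream spectrum prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .chem import formula_to_string, is_submultiset, monoisotopic_mass, parse_formula
from .spectrum import Spectrum, normalize_spectrum


@dataclass(frozen=True)
class TransformationRule:
    name: str
    delta_formula: str
    sign: int  # +1 addition, -1 loss

    @property
    def mass_shift(self) -> float:
        return self.sign * monoisotopic_mass(self.delta_formula)


@dataclass
class NetworkNeighbor:
    formula: str
    rule: str
    mass_shift: float


@dataclass
class TransformationNetwork:
    center: str
    neighbors: list[NetworkNeighbor]


def load_rule_table(path: str | Path | None = None) -> list[TransformationRule]:
    """Load transformation rules from the bundled (or a user) TSV resource."""
    if path is None:
        text = (resources.files("ms2deconv") / "data/transformation_rules.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for line in text.strip().splitlines()[1:]:
        name, delta, sign = line.split("\t")
        rules.append(TransformationRule(name, delta, +1 if sign.strip() == "+" else -1))
    return rules


def build_transformation_network(
    formula: str, rules: list[TransformationRule] | None = None
) -> TransformationNetwork:
    """Apply every rule to ``formula``; losses leaving a negative element
    count are rejected.  One hop only."""
    center = parse_formula(formula)  # raises ValueError if unparseable
    if rules is None:
        rules = load_rule_table()
    neighbors = []
    for rule in rules:
        delta = parse_formula(rule.delta_formula)
        counts = dict(center)
        ok = True
        for el, n in delta.items():
            counts[el] = counts.get(el, 0) + rule.sign * n
            if counts[el] < 0:
                ok = False
                break
        if not ok:
            continue
        counts = {el: n for el, n in counts.items() if n > 0}
        if not counts:
            continue
        neighbors.append(NetworkNeighbor(
            formula=formula_to_string(counts), rule=rule.name, mass_shift=rule.mass_shift,
        ))
    return TransformationNetwork(center=formula_to_string(center), neighbors=neighbors)


def clean_neighbor_spectrum(
    spectrum: Spectrum, target_formula: str, ppm_tol: float = 10.0
) -> Spectrum:
    """Drop fragments whose elemental composition cannot fit inside
    ``target_formula``.

    A fragment is kept iff its best formula is an element-wise sub-multiset of
    the target (no element count exceeded, no new element type).  Fragments
    without stored formulas are annotated on the fly via neutral CHNOPS
    prediction restricted to the target's elements; unannotatable fragments
    are dropped.  Survivors are normalized; an empty survivor set yields an
    empty peak list for the caller to handle.
    """
    from .chem import predict_formula

    target = parse_formula(target_formula)
    bounds = {el: n for el, n in target.items() if el in "CHNOPS"}
    keep_mz, keep_int, keep_forms = [], [], []
    stored = spectrum.formulas or [None] * len(spectrum)
    for mz, inten, form in zip(spectrum.mz, spectrum.intensity, stored):
        if form:
            try:
                frag_counts = parse_formula(form)
            except ValueError:
                continue
        else:
            # fragment ions keep the precursor charge; treat as protonated
            cands = predict_formula(
                mz, adducts=("[M+H]+",), ppm_tol=ppm_tol,
                element_bounds={**{e: 0 for e in "CHNOPS"}, **bounds},
            )
            if not cands:
                continue
            frag_counts = cands[0].counts
            form = cands[0].formula
        if is_submultiset(frag_counts, target):
            keep_mz.append(mz)
            keep_int.append(inten)
            keep_forms.append(form)
    if not keep_mz:
        return spectrum.with_peaks([], [], None)
    return normalize_spectrum(spectrum.with_peaks(keep_mz, keep_int, keep_forms))
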