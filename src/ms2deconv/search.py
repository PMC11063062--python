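"""Reference-library search with the composite matching score, neutral-loss
fallback, and ranked result export."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import monoisotopic_mass
from .library import LibraryRecord, SpectralLibrary
from .scoring import (
    deviation_similarity,
    isotope_similarity,
    matching_score,
    spectral_similarity,
)
from .spectrum import Spectrum, ppm_delta
from .transform import TransformationRule, build_transformation_network, load_rule_table

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "query_id", "compound_name", "formula", "inchikey", "adduct",
    "matching_score", "ms2_sim", "ms1_sim", "rt_sim", "isotope_sim", "match_kind",
]


@dataclass
class SearchOptions:
    ppm_tol: float = 10.0
    rt_enabled: bool = False
    rt_tol: float = 30.0
    similarity_method: str = "dot_product"
    fragment_mz_tol: float = 0.01
    top_n: int = 5
    nl_fallback_threshold: float = 10.0
    instrument_type: str | None = None
    collision_energy: str | None = None
    #: when True, a missing observed isotope pattern drops the isotope term
    #: and renormalizes the denominator instead of scoring it 0
    drop_missing_isotope_term: bool = False

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0.0 <= self.nl_fallback_threshold <= 100.0):
            raise ValueError("nl_fallback_threshold must lie in [0, 100]")


@dataclass
class MatchResult:
    query_id: str
    record: LibraryRecord
    ms2_similarity: float
    ms1_similarity: float
    rt_similarity: float | None
    isotope_similarity: float
    matching_score: float
    match_kind: str = "standard"  # or "neutral_loss"


def score_match(
    query: Spectrum,
    record: LibraryRecord,
    options: SearchOptions = SearchOptions(),
    observed_isotope: tuple[float, float] | None = None,
    record_rt: float | None = None,
    expected_precursor_mz: float | None = None,
    match_kind: str = "standard",
) -> MatchResult:
    """Score one query spectrum against one library record."""
    ms2 = spectral_similarity(
        query, record.spectrum, method=options.similarity_method,
        mz_tol=options.fragment_mz_tol,
    )
    ref_mz = expected_precursor_mz if expected_precursor_mz is not None else record.precursor_mz
    dppm = ppm_delta(query.precursor_mz, ref_mz)
    ms1 = deviation_similarity(dppm, options.ppm_tol)
    rt_sim = None
    if options.rt_enabled and record_rt is not None and not np.isnan(query.precursor_rt):
        rt_sim = deviation_similarity(query.precursor_rt - record_rt, options.rt_tol)
    if observed_isotope is None and options.drop_missing_isotope_term:
        # renormalized composite without the isotope term
        denom = 3.0 if rt_sim is not None else 2.0
        score = (ms2 + ms1 + (rt_sim or 0.0)) / denom * 100.0
        iso = float("nan")
    else:
        iso = isotope_similarity(observed_isotope, record.formula) if record.formula else 0.0
        score = matching_score(ms2, ms1, rt_sim, iso)
    return MatchResult(
        query_id=query.source_id, record=record, ms2_similarity=ms2,
        ms1_similarity=ms1, rt_similarity=rt_sim, isotope_similarity=iso,
        matching_score=score, match_kind=match_kind,
    )


def search_library(
    query: Spectrum,
    library: SpectralLibrary,
    options: SearchOptions = SearchOptions(),
    observed_isotope: tuple[float, float] | None = None,
    record_rts: dict[int, float] | None = None,
) -> list[MatchResult]:
    """Rank all precursor-matching library records against a query spectrum.

    Candidates within ``ppm_tol`` of the query precursor (and passing the
    instrument / collision-energy filters) are scored with the composite
    matching score and sorted descending; ties break to the lower record_id.
    """
    if np.isnan(query.precursor_mz):
        raise ValueError("query spectrum has no precursor m/z")
    records = library.query_by_precursor(query.precursor_mz, options.ppm_tol, query.polarity)
    if options.instrument_type:
        records = [r for r in records if r.instrument_type == options.instrument_type]
    if options.collision_energy:
        records = [r for r in records if r.collision_energy == options.collision_energy]
    results = []
    for rec in records:
        rt = (record_rts or {}).get(rec.record_id)
        results.append(score_match(query, rec, options, observed_isotope, record_rt=rt))
    results.sort(key=lambda m: (-m.matching_score, m.record.record_id))
    return results


def neutral_loss_spectrum(s: Spectrum) -> Spectrum:
    """Mirror a spectrum into neutral-loss space: each fragment (mz, i)
    becomes (precursor_mz − mz, i); non-positive losses are dropped."""
    if np.isnan(s.precursor_mz):
        raise ValueError("neutral-loss transform requires a precursor m/z")
    nl_mz = s.precursor_mz - s.mz
    keep = nl_mz > 0
    return s.with_peaks(nl_mz[keep], s.intensity[keep])


def neutral_loss_search(
    query: Spectrum,
    nl_library: SpectralLibrary,
    network_rules: list[TransformationRule] | None = None,
    options: SearchOptions = SearchOptions(),
    best_standard_score: float | None = None,
    force: bool = False,
) -> list[MatchResult]:
    """Fallback search in neutral-loss space for poorly matched precursors.

    Performed only when the best standard score falls below the fallback
    threshold (default 10 of 100) or when forced.  The query precursor's
    predicted formula seeds a one-hop transformation network; the neighbors'
    neutral-loss spectra are scored against the query's neutral-loss mirror,
    with the precursor deviation measured against the transformation-shifted
    m/z.  Results carry ``match_kind="neutral_loss"``.
    """
    if (
        not force
        and best_standard_score is not None
        and best_standard_score >= options.nl_fallback_threshold
    ):
        return []
    from .chem import predict_formula

    formulas = predict_formula(query.precursor_mz, polarity=query.polarity, ppm_tol=options.ppm_tol)
    if not formulas:
        return []
    network = build_transformation_network(formulas[0].formula, network_rules)
    if not network.neighbors:
        return []
    query_nl = neutral_loss_spectrum(query)
    if len(query_nl) == 0:
        return []
    results = []
    seen: set[int] = set()
    for neighbor in network.neighbors:
        for rec in nl_library.query_by_formula(neighbor.formula):
            if rec.record_id in seen:
                continue
            seen.add(rec.record_id)
            expected = query.precursor_mz + neighbor.mass_shift
            m = score_match(
                query_nl, rec, options,
                expected_precursor_mz=expected - (expected - rec.precursor_mz),
                match_kind="neutral_loss",
            )
            # MS1 agreement = how well the record precursor matches the
            # transformation-shifted query precursor
            dppm = ppm_delta(expected, rec.precursor_mz)
            m.ms1_similarity = deviation_similarity(dppm, options.ppm_tol)
            m.matching_score = matching_score(
                m.ms2_similarity, m.ms1_similarity, m.rt_similarity,
                0.0 if np.isnan(m.isotope_similarity) else m.isotope_similarity,
            )
            results.append(m)
    results.sort(key=lambda m: (-m.matching_score, m.record.record_id))
    return results


def results_to_frame(matches: list[MatchResult], top_n: int | None = None) -> pd.DataFrame:
    """Tabulate matches, collapsing chemically identical candidates.

    Duplicate InChIKeys keep only their highest-scoring record; at most
    ``top_n`` rows per query, descending score.
    """
    rows = []
    for m in matches:
        rows.append({
            "query_id": m.query_id,
            "compound_name": m.record.compound_name,
            "formula": m.record.formula,
            "inchikey": m.record.inchikey,
            "adduct": m.record.adduct,
            "matching_score": m.matching_score,
            "ms2_sim": m.ms2_similarity,
            "ms1_sim": m.ms1_similarity,
            "rt_sim": m.rt_similarity if m.rt_similarity is not None else np.nan,
            "isotope_sim": m.isotope_similarity,
            "match_kind": m.match_kind,
            "_record_id": m.record.record_id,
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS + ["_record_id"])
    if len(df):
        df = df.sort_values(
            ["query_id", "matching_score", "_record_id"], ascending=[True, False, True]
        )
        df = df.drop_duplicates(subset=["query_id", "inchikey"], keep="first")
        if top_n is not None:
            df = df.groupby("query_id", group_keys=False).head(top_n)
    return df.drop(columns=["_record_id"]).reset_index(drop=True)


def export_results(
    matches: list[MatchResult], top_n: int, path: str | Path, sep: str = ","
) -> pd.DataFrame:
    """Write the deduplicated top-N result table as delimited text."""
    df = results_to_frame(matches, top_n)
    df.to_csv(path, sep=sep, index=False)
    return df
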