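"""Bridging MS2 identifications into pathway-enrichment inputs.

Pathway activity prediction from untargeted data groups MS1 features into
"empirical compounds" — provisional compound hypotheses based on m/z (adduct)
and RT alone — which are inherently ambiguous.  An MS2-based identification
pins a feature to one compound, so candidate lists can be pruned before the
enrichment test (which itself is external prior work).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


def _first_block(inchikey: str) -> str:
    return inchikey.split("-")[0] if inchikey else ""


def format_for_enrichment(
    results: pd.DataFrame,
    id_priority: list[str] | None = None,
    id_mapping: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Per-feature ordered compound-ID lists from a search result table.

    InChIKeys come first; KEGG / HMDB identifiers are appended when an
    ``id_mapping`` table (columns ``inchikey`` plus ID columns) supplies
    them, in ``id_priority`` order.  Features without hits are omitted.
    """
    if id_priority is None:
        id_priority = ["kegg", "hmdb"]
    lookup: dict[str, dict[str, str]] = {}
    if id_mapping is not None:
        for _, row in id_mapping.iterrows():
            lookup[row["inchikey"]] = {
                c: str(row[c]) for c in id_mapping.columns
                if c != "inchikey" and pd.notna(row[c])
            }
    out: dict[str, list[str]] = {}
    for qid, group in results.groupby("query_id", sort=True):
        ids: list[str] = []
        for _, row in group.sort_values("matching_score", ascending=False).iterrows():
            key = row["inchikey"]
            if not key or key in ids:
                continue
            ids.append(key)
            mapped = lookup.get(key, {})
            for col in id_priority:
                if col in mapped and mapped[col] not in ids:
                    ids.append(mapped[col])
        if ids:
            out[str(qid)] = ids
    return out


def filter_empirical_compounds(
    ecpds: dict[str, list[str]],
    ms2_ids: dict[str, str],
    strict: bool = False,
) -> dict[str, list[str]]:
    """Prune empirical-compound candidate lists with MS2 identifications.

    Features with an MS2 identification retain only candidates matching it;
    features without one keep their lists unchanged.  When no candidate
    matches, the MS2-identified compound becomes the sole candidate.  By
    default compounds match on the InChIKey first block (the 2D skeleton,
    tolerant of stereo/protonation variants); ``strict`` compares full keys.
    Idempotent, and never grows a candidate list.
    """
    out: dict[str, list[str]] = {}
    for feature_id, candidates in ecpds.items():
        ms2_id = ms2_ids.get(feature_id)
        if ms2_id is None:
            out[feature_id] = list(candidates)
            continue
        if strict:
            survivors = [c for c in candidates if c == ms2_id]
        else:
            target = _first_block(ms2_id)
            survivors = [c for c in candidates if _first_block(c) == target]
        out[feature_id] = survivors if survivors else [ms2_id]
    return out
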