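"""Seeded synthetic fixtures: reference libraries, DDA runs with known
chimeric composition, SWATH-DIA runs with known co-elution structure, and
replicate sets.

The generators emit ground truth alongside the data, so every downstream
operation can be checked against the construction: which compound each
feature is, which scans are chimeric and with what mixing weights, and which
fragments co-elute in which DIA cluster.  Chromatographic peaks are Gaussian
(width configurable within a 6–20 s base range); intensity noise is
multiplicative log-normal with a stated CV.  All outputs are
seed-deterministic.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import formula_to_string, monoisotopic_mass, PROTON_MASS, theoretical_isotope_pattern
from .library import LibraryRecord, SpectralLibrary
from .spectrum import MS1Feature, RunData, Spectrum

#: instrument-like floor below which a simulated centroid is not recorded
DETECTION_LIMIT = 100.0


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic acquisition."""

    feature_compounds: dict[str, int] = field(default_factory=dict)  # feature -> record_id
    feature_inchikeys: dict[str, str] = field(default_factory=dict)
    chimera: dict[str, tuple[int, float]] = field(default_factory=dict)  # feature -> (partner record, main weight)
    scan_labels: dict[str, str] = field(default_factory=dict)  # scan id -> clean|chimeric
    dia_fragments: dict[str, np.ndarray] = field(default_factory=dict)  # feature -> true fragment m/z
    window_of_feature: dict[str, int] = field(default_factory=dict)
    features: list[MS1Feature] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid, rid in self.feature_compounds.items():
            partner, w = self.chimera.get(fid, (-1, 1.0))
            rows.append({
                "feature_id": fid, "record_id": rid,
                "inchikey": self.feature_inchikeys.get(fid, ""),
                "is_chimeric": fid in self.chimera,
                "partner_record_id": partner, "main_weight": w,
            })
        return pd.DataFrame(rows)


def _random_inchikey(rng: np.random.Generator) -> str:
    letters = np.array(list(string.ascii_uppercase))
    block1 = "".join(rng.choice(letters, 14))
    block2 = "".join(rng.choice(letters, 10))
    return f"{block1}-{block2}-N"


def _random_formula(rng: np.random.Generator) -> dict[str, int]:
    c = int(rng.integers(5, 21))
    h = int(rng.integers(c, 2 * c + 3))
    n = int(rng.integers(0, 3))
    o = int(rng.integers(1, 7))  # >= 1 oxygen so a chimera partner always exists
    return {k: v for k, v in (("C", c), ("H", h), ("N", n), ("O", o)) if v}


def _random_fragments(
    rng: np.random.Generator, precursor_mz: float, n_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    mz = np.sort(rng.uniform(50.0, precursor_mz - 15.0, n))
    # keep fragments at least 0.05 Th apart so alignment bins stay unambiguous
    for i in range(1, n):
        if mz[i] - mz[i - 1] < 0.05:
            mz[i] = mz[i - 1] + 0.05 + rng.uniform(0, 0.05)
    intensity = rng.uniform(5.0, 100.0, n)
    intensity[int(rng.integers(n))] = 100.0  # guarantee a base peak
    return mz, intensity


def make_synthetic_library(
    path,
    n_compounds: int = 50,
    fragments_per_compound: tuple[int, int] = (4, 10),
    mz_range: tuple[float, float] = (120.0, 600.0),
    seed: int = 0,
    chimera_partner_fraction: float = 0.0,
    isomer_fraction: float = 0.0,
    polarity: str = "positive",
) -> tuple[SpectralLibrary, pd.DataFrame]:
    """Create a schema-valid SQLite reference library of random compounds.

    Compounds carry random CHNO formulas with consistent [M+H]+ precursor
    masses and reproducible fragment sets (all fragment m/z below the
    precursor).  A ``chimera_partner_fraction`` of compounds get a partner
    record offset by the CH4-for-O formula swap (+0.0364 Da — close enough to
    co-isolate, far enough to resolve as a separate centroid); an
    ``isomer_fraction`` get an isobaric partner with the identical formula
    but different fragments and InChIKey.  Returns the open library and a
    manifest of what was generated.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[LibraryRecord] = []
    manifest_rows = []
    used_masses: list[float] = []
    record_id = 1
    attempts = 0
    while sum(1 for r in manifest_rows if r["role"] == "primary") < n_compounds:
        attempts += 1
        if attempts > 200 * n_compounds:
            raise RuntimeError("could not place compounds in the requested m/z range")
        counts = _random_formula(rng)
        neutral = monoisotopic_mass(counts)
        precursor = neutral + PROTON_MASS
        if not (mz_range[0] <= precursor <= mz_range[1]):
            continue
        # keep primaries >= 2 Th apart so precursor queries are unambiguous
        if any(abs(precursor - m) < 2.0 for m in used_masses):
            continue
        used_masses.append(precursor)
        formula = formula_to_string(counts)
        mz, inten = _random_fragments(rng, precursor, fragments_per_compound)
        inchikey = _random_inchikey(rng)
        records.append(LibraryRecord(
            record_id=record_id, compound_name=f"SYN-{record_id:04d}", formula=formula,
            inchikey=inchikey, precursor_mz=precursor, adduct="[M+H]+",
            polarity=polarity, collision_energy="30", instrument_type="QTOF",
            spectrum=Spectrum(mz=mz, intensity=inten, precursor_mz=precursor,
                              polarity=polarity, source_id=f"lib:{record_id}"),
        ))
        manifest_rows.append({
            "record_id": record_id, "formula": formula, "precursor_mz": precursor,
            "inchikey": inchikey, "role": "primary", "partner_of": -1,
        })
        primary_id = record_id
        record_id += 1
        if rng.random() < chimera_partner_fraction and counts.get("O", 0) >= 1:
            p_counts = dict(counts)
            p_counts["O"] -= 1
            p_counts["C"] = p_counts.get("C", 0) + 1
            p_counts["H"] = p_counts.get("H", 0) + 4
            p_counts = {k: v for k, v in p_counts.items() if v}
            p_formula = formula_to_string(p_counts)
            p_precursor = monoisotopic_mass(p_counts) + PROTON_MASS
            p_mz, p_inten = _random_fragments(rng, p_precursor, fragments_per_compound)
            p_key = _random_inchikey(rng)
            records.append(LibraryRecord(
                record_id=record_id, compound_name=f"SYN-{record_id:04d}",
                formula=p_formula, inchikey=p_key, precursor_mz=p_precursor,
                adduct="[M+H]+", polarity=polarity, collision_energy="30",
                instrument_type="QTOF",
                spectrum=Spectrum(mz=p_mz, intensity=p_inten, precursor_mz=p_precursor,
                                  polarity=polarity, source_id=f"lib:{record_id}"),
            ))
            manifest_rows.append({
                "record_id": record_id, "formula": p_formula,
                "precursor_mz": p_precursor, "inchikey": p_key,
                "role": "chimera_partner", "partner_of": primary_id,
            })
            record_id += 1
        if rng.random() < isomer_fraction:
            i_mz, i_inten = _random_fragments(rng, precursor, fragments_per_compound)
            i_key = _random_inchikey(rng)
            records.append(LibraryRecord(
                record_id=record_id, compound_name=f"SYN-{record_id:04d}",
                formula=formula, inchikey=i_key, precursor_mz=precursor,
                adduct="[M+H]+", polarity=polarity, collision_energy="30",
                instrument_type="QTOF",
                spectrum=Spectrum(mz=i_mz, intensity=i_inten, precursor_mz=precursor,
                                  polarity=polarity, source_id=f"lib:{record_id}"),
            ))
            manifest_rows.append({
                "record_id": record_id, "formula": formula, "precursor_mz": precursor,
                "inchikey": i_key, "role": "isomer", "partner_of": primary_id,
            })
            record_id += 1
    library = SpectralLibrary.create(path, records)
    return library, pd.DataFrame(manifest_rows)


def _gaussian(t: np.ndarray | float, apex: float, sigma: float) -> np.ndarray | float:
    return np.exp(-0.5 * ((t - apex) / sigma) ** 2)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def simulate_dda_run(
    library: SpectralLibrary,
    manifest: pd.DataFrame,
    n_features: int = 10,
    chimera_fraction: float = 0.5,
    weights_range: tuple[float, float] = (0.1, 0.9),
    noise_cv: float = 0.05,
    n_replicates: int = 1,
    seed: int = 0,
    peak_sigma: float = 4.0,
    isolation_half_width: float = 0.75,
) -> tuple[list[RunData], list[MS1Feature], GroundTruth]:
    """Simulate DDA replicates with a known chimeric composition.

    Features are library primaries eluting as Gaussian peaks with M, M+1 and
    M+2 MS1 satellites from the formula's theoretical pattern.  A
    ``chimera_fraction`` of features co-elute with their library chimera
    partner inside the isolation window; their MS2 scans are the
    weight-blended union of both compounds' fragments (main weight drawn from
    ``weights_range``), multiplied by log-normal noise per replicate.
    """
    rng = np.random.default_rng(seed)
    primaries = manifest[manifest["role"] == "primary"]
    partners = manifest[manifest["role"] == "chimera_partner"].set_index("partner_of")
    n_chimeric = int(round(chimera_fraction * n_features))
    with_partner = primaries[primaries["record_id"].isin(partners.index)]
    if len(with_partner) < n_chimeric:
        raise ValueError(
            f"chimera_fraction {chimera_fraction} needs {n_chimeric} partnered "
            f"compounds but the library has {len(with_partner)}"
        )
    chim_rows = with_partner.sample(n=n_chimeric, random_state=int(rng.integers(2**31)))
    rest = primaries.drop(chim_rows.index)
    if len(rest) < n_features - n_chimeric:
        raise ValueError("library too small for the requested feature count")
    clean_rows = rest.sample(
        n=n_features - n_chimeric, random_state=int(rng.integers(2**31))
    )
    chosen = pd.concat([chim_rows, clean_rows])
    apexes = 100.0 + 25.0 * np.arange(len(chosen))

    truth = GroundTruth()
    features: list[MS1Feature] = []
    compounds = []  # (record, apex, base_height, partner_record | None, weight)
    for (_, row), apex in zip(chosen.iterrows(), apexes):
        rec = library.get(int(row["record_id"]))
        height = 10 ** rng.uniform(5.0, 6.5)
        is_chim = row["record_id"] in set(chim_rows["record_id"])
        partner_rec, w = None, 1.0
        if is_chim:
            partner_rec = library.get(int(partners.loc[row["record_id"], "record_id"]))
            w = float(rng.uniform(*weights_range))
        fid = f"F{rec.record_id:04d}"
        features.append(MS1Feature(
            mz_med=rec.precursor_mz, rt_med=apex,
            mz_min=rec.precursor_mz * (1 - 5e-6), mz_max=rec.precursor_mz * (1 + 5e-6),
            rt_min=apex - 3 * peak_sigma, rt_max=apex + 3 * peak_sigma,
            intensity=height, feature_id=fid,
        ))
        truth.feature_compounds[fid] = rec.record_id
        truth.feature_inchikeys[fid] = rec.inchikey
        if is_chim:
            truth.chimera[fid] = (partner_rec.record_id, w)
        compounds.append((rec, apex, height, partner_rec, w))

    rt_grid = np.arange(60.0, apexes.max() + 40.0, 2.0)
    runs: list[RunData] = []
    for rep in range(n_replicates):
        ms1_scans = []
        for t in rt_grid:
            mz_list, int_list = [], []
            for rec, apex, height, partner_rec, w in compounds:
                elution = float(_gaussian(t, apex, peak_sigma))
                if elution < 1e-4:
                    continue
                m1, m2 = theoretical_isotope_pattern(rec.formula)
                mono = height * elution * (w if partner_rec is not None else 1.0)
                noise = _lognormal_noise(rng, noise_cv, 3)
                for k, frac in enumerate((1.0, m1, m2)):
                    inten = mono * frac * noise[k]
                    if inten >= DETECTION_LIMIT:
                        mz_list.append(rec.precursor_mz + k * 1.003355)
                        int_list.append(inten)
                if partner_rec is not None:
                    p1, p2 = theoretical_isotope_pattern(partner_rec.formula)
                    p_mono = height * elution * (1.0 - w)
                    noise = _lognormal_noise(rng, noise_cv, 3)
                    for k, frac in enumerate((1.0, p1, p2)):
                        inten = p_mono * frac * noise[k]
                        if inten >= DETECTION_LIMIT:
                            mz_list.append(partner_rec.precursor_mz + k * 1.003355)
                            int_list.append(inten)
            if mz_list:
                ms1_scans.append(Spectrum(
                    mz=np.array(mz_list), intensity=np.array(int_list),
                    precursor_rt=float(t), ms_level=1,
                    source_id=f"rep{rep}:ms1:{t:.0f}",
                ))
        ms2_scans = []
        for rec, apex, height, partner_rec, w in compounds:
            fid = f"F{rec.record_id:04d}"
            for j, dt in enumerate((-1.0, 1.0)):
                t = apex + dt
                main = rec.spectrum.normalized()
                if partner_rec is None:
                    mz = main.mz.copy()
                    inten = main.intensity * _lognormal_noise(rng, noise_cv, len(main))
                    label = "clean"
                else:
                    partner = partner_rec.spectrum.normalized()
                    mz = np.concatenate([main.mz, partner.mz])
                    inten = np.concatenate([
                        w * main.intensity, (1.0 - w) * partner.intensity
                    ]) * _lognormal_noise(rng, noise_cv, len(main) + len(partner))
                    label = "chimeric"
                sid = f"rep{rep}:{fid}:ms2:{j}"
                ms2_scans.append(Spectrum(
                    mz=mz, intensity=inten, precursor_mz=rec.precursor_mz,
                    precursor_rt=float(t), ms_level=2, source_id=sid,
                    isolation_low=rec.precursor_mz - isolation_half_width,
                    isolation_high=rec.precursor_mz + isolation_half_width,
                ))
                truth.scan_labels[sid] = label
        runs.append(RunData(ms1_scans=ms1_scans, ms2_scans=ms2_scans))
    truth.features = features
    return runs, features, truth


def make_swath_windows(
    mz_lo: float = 100.0, mz_hi: float = 650.0, n_windows: int = 10,
    overlap: float = 1.0,
) -> pd.DataFrame:
    """Contiguous SWATH window table with the customary 1 Th edge overlap."""
    edges = np.linspace(mz_lo, mz_hi, n_windows + 1)
    rows = [
        {"index": i, "lower_mz": edges[i] - (overlap / 2 if i else 0.0),
         "upper_mz": edges[i + 1] + (overlap / 2 if i < n_windows - 1 else 0.0)}
        for i in range(n_windows)
    ]
    return pd.DataFrame(rows)


def simulate_swath_run(
    library: SpectralLibrary,
    window_table: pd.DataFrame,
    compound_ids: list[int],
    co_elution_pairs: list[tuple[int, int, float]] = (),
    seed: int = 0,
    noise_cv: float = 0.0,
    peak_sigma: float = 4.0,
    cycle_time: float = 1.5,
) -> tuple[RunData, list[MS1Feature], GroundTruth]:
    """Simulate a SWATH-DIA acquisition with known co-elution structure.

    Each cycle holds one MS1 scan plus one MS2 scan per window; the fragments
    of every compound whose precursor falls in a window are superposed on
    that window's scans, scaled by the compound's Gaussian elution profile.
    ``co_elution_pairs`` (id_a, id_b, delta_apex) forces compound b to elute
    ``delta_apex`` seconds after compound a.  Ground truth records each
    feature's true fragment set and window.
    """
    rng = np.random.default_rng(seed)

    def window_of(mz: float) -> int:
        containing = [
            (abs(mz - (r["lower_mz"] + r["upper_mz"]) / 2.0), int(r["index"]))
            for _, r in window_table.iterrows()
            if r["lower_mz"] <= mz <= r["upper_mz"]
        ]
        if not containing:
            raise ValueError(f"precursor {mz:.4f} outside all SWATH windows")
        return min(containing)[1]

    paired_b = {b: (a, d) for a, b, d in co_elution_pairs}
    apex_of: dict[int, float] = {}
    next_apex = 120.0
    for cid in compound_ids:
        if cid in paired_b:
            continue
        apex_of[cid] = next_apex
        next_apex += 40.0
    for b, (a, delta) in paired_b.items():
        apex_of[b] = apex_of[a] + delta

    compounds = []
    truth = GroundTruth()
    features: list[MS1Feature] = []
    for cid in compound_ids:
        rec = library.get(cid)
        if rec is None:
            raise ValueError(f"record {cid} not in library")
        widx = window_of(rec.precursor_mz)
        height = 10 ** rng.uniform(5.0, 6.0)
        fid = f"F{cid:04d}"
        compounds.append((rec, apex_of[cid], height, widx))
        features.append(MS1Feature(
            mz_med=rec.precursor_mz, rt_med=apex_of[cid],
            mz_min=rec.precursor_mz * (1 - 5e-6), mz_max=rec.precursor_mz * (1 + 5e-6),
            rt_min=apex_of[cid] - 3 * peak_sigma, rt_max=apex_of[cid] + 3 * peak_sigma,
            intensity=height, feature_id=fid,
        ))
        truth.feature_compounds[fid] = cid
        truth.feature_inchikeys[fid] = rec.inchikey
        truth.dia_fragments[fid] = rec.spectrum.mz.copy()
        truth.window_of_feature[fid] = widx

    t0 = min(apex_of.values()) - 30.0
    t1 = max(apex_of.values()) + 30.0
    ms1_scans, ms2_scans = [], []
    t = t0
    cycle = 0
    while t <= t1:
        mz_list, int_list = [], []
        for rec, apex, height, _ in compounds:
            elution = float(_gaussian(t, apex, peak_sigma))
            if elution < 1e-4:
                continue
            m1, m2 = theoretical_isotope_pattern(rec.formula)
            noise = _lognormal_noise(rng, noise_cv, 3)
            for k, frac in enumerate((1.0, m1, m2)):
                inten = height * elution * frac * noise[k]
                if inten >= DETECTION_LIMIT:
                    mz_list.append(rec.precursor_mz + k * 1.003355)
                    int_list.append(inten)
        if mz_list:
            ms1_scans.append(Spectrum(
                mz=np.array(mz_list), intensity=np.array(int_list),
                precursor_rt=float(t), ms_level=1, source_id=f"cyc{cycle}:ms1",
            ))
        for _, wrow in window_table.iterrows():
            widx = int(wrow["index"])
            w_mz, w_int = [], []
            for rec, apex, height, cw in compounds:
                if cw != widx:
                    continue
                elution = float(_gaussian(t, apex, peak_sigma))
                if elution < 1e-4:
                    continue
                spec = rec.spectrum.normalized()
                noise = _lognormal_noise(rng, noise_cv, len(spec))
                scaled = height * elution / 100.0 * spec.intensity * noise
                keep = scaled >= DETECTION_LIMIT
                w_mz.extend(spec.mz[keep])
                w_int.extend(scaled[keep])
            if w_mz:
                center = (wrow["lower_mz"] + wrow["upper_mz"]) / 2.0
                ms2_scans.append(Spectrum(
                    mz=np.array(w_mz), intensity=np.array(w_int),
                    precursor_mz=float(center), precursor_rt=float(t), ms_level=2,
                    source_id=f"cyc{cycle}:w{widx}",
                    isolation_low=float(wrow["lower_mz"]),
                    isolation_high=float(wrow["upper_mz"]),
                    window_index=widx,
                ))
        t += cycle_time
        cycle += 1
    truth.features = features
    return RunData(ms1_scans=ms1_scans, ms2_scans=ms2_scans), features, truth
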