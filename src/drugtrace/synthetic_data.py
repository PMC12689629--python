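"""Deterministic generators for libraries, cohorts and MS1 runs with known
ground truth.

The generator emulates the inputs of a drug-exposure metabolomics study:

* a drug spectral library — random but valid molecular formulas, theoretical
  [M+H]+ precursors, fragments drawn as neutral-loss partitions of the
  precursor, controlled-vocabulary pharmacologic metadata, and metabolite
  entries built by applying curated mass offsets;
* a cohort of samples with a group exposure design — exposed samples carry
  the drug's (perturbed) MS/MS spectrum and peak area, plus planted
  companions: co-eluting sodium adducts and isotopes (identical elution
  shape), in-source fragments (precursor equal to a drug fragment), shifted
  metabolites, decoy spectra, laboratory blanks and blank-borne contaminant
  features;
* MS1 runs — Gaussian elution profiles sampled on a shared scan grid, with
  adducts and isotopes sharing the parent's profile (peak-shape R² of 1 by
  construction) and metabolites given an independent, shifted apex.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream per
artifact, so regeneration from (seed, parameters) is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chem_mass import Formula, ion_mz, load_mass_offsets, ISOTOPE_SPACING
from .drug_library import DrugLibrary, DrugLibraryEntry, PharmMetadata
from .spectra_io import FeatureTable, Spectrum

__all__ = [
    "GroundTruth",
    "generate_library",
    "generate_cohort",
    "generate_ms1_runs",
    "write_ms1_mzml",
]

SODIUM_SPACING = 21.981945  # Na - H

#: Small controlled vocabularies used to populate pharmacologic metadata.
_CLASSES = [
    ("statin", "lipid-lowering", "hypercholesterolemia", "HMG-CoA reductase inhibitor"),
    ("SSRI", "psychiatry", "depression", "serotonin reuptake inhibitor"),
    ("NSAID", "analgesics", "pain", "COX inhibitor"),
    ("ACE inhibitor", "cardiology", "hypertension", "ACE inhibitor"),
    ("beta blocker", "cardiology", "hypertension", "beta-adrenergic antagonist"),
    ("proton pump inhibitor", "gastroenterology", "reflux", "H+/K+-ATPase inhibitor"),
    ("antihistamine", "allergy", "allergy", "H1 receptor antagonist"),
    ("antiretroviral", "infectious disease", "HIV", "protease inhibitor"),
    ("benzodiazepine", "psychiatry", "anxiety", "GABA-A modulator"),
    ("antibiotic", "infectious disease", "bacterial infection", "cell wall synthesis inhibitor"),
]


@dataclass
class GroundTruth:
    """Everything a test needs to score a pipeline run against the truth."""

    seed: int
    params: dict = field(default_factory=dict)
    drugs: dict = field(default_factory=dict)        # name -> formula/precursor/...
    metabolites: dict = field(default_factory=dict)  # entry_id -> parent/delta/label
    features: list = field(default_factory=list)     # per-feature records
    exposures: dict = field(default_factory=dict)    # sample -> {drug: area}
    groups: dict = field(default_factory=dict)       # sample -> group name
    demographics: dict = field(default_factory=dict) # sample -> {age, sex}
    apexes: dict = field(default_factory=dict)       # feature_id -> apex scan

    def analog_features(self) -> list[dict]:
        """Feature records for planted non-drug ion forms and metabolites."""
        return [
            f for f in self.features
            if f["role"] in ("adduct", "isotope", "in_source_fragment", "metabolite")
        ]

    def to_json(self, path: str) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)


def _random_formula(rng: np.random.Generator) -> Formula:
    c = int(rng.integers(10, 36))
    h = int(rng.integers(c, 2 * c + 2))
    n = int(rng.integers(0, 4))
    o = int(rng.integers(1, 8))
    s = int(rng.integers(0, 2))
    counts = {"C": c, "H": h, "N": n, "O": o, "S": s}
    return Formula({e: k for e, k in counts.items() if k})


def _random_fragments(
    rng: np.random.Generator, precursor: float, n_min: int = 8, n_max: int = 20
) -> tuple[tuple[float, float], ...]:
    """Fragments as random neutral losses from the precursor, kept clear of
    the ±17 Da precursor-exclusion zone so they survive preprocessing."""
    n = int(rng.integers(n_min, n_max + 1))
    low, high = 50.0, precursor - 25.0
    mzs = np.sort(rng.uniform(low, high, size=n))
    intensities = rng.uniform(10.0, 100.0, size=n)
    intensities[int(rng.integers(0, n))] = 100.0  # guarantee a base peak
    return tuple(zip(mzs.tolist(), intensities.tolist()))


def generate_library(
    n_drugs: int = 50,
    seed: int = 0,
    endogenous_fraction: float = 0.1,
    metabolite_fraction: float = 0.5,
    n_offsets: int = 10,
    min_precursor_spacing: float = 0.05,
) -> tuple[DrugLibrary, GroundTruth]:
    """Build a synthetic drug library with metabolite entries.

    Each drug gets a random formula (resampled until every precursor-derived
    ion value keeps ``min_precursor_spacing`` from all existing ones, so
    annotations are unambiguous), a theoretical [M+H]+ precursor, 8-20
    fragments, and vocabulary-valid metadata; ``endogenous_fraction`` of the
    drugs get an extra endogenous/food source.  ``metabolite_fraction`` of
    drugs gain one metabolite entry built by applying one of the first
    ``n_offsets`` curated metabolism offsets (precursor shift plus shifting
    a random subset of fragments).
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = [
        o for o in load_mass_offsets() if o.category == "metabolism"
    ][:n_offsets]
    truth = GroundTruth(
        seed=seed,
        params={
            "n_drugs": n_drugs,
            "endogenous_fraction": endogenous_fraction,
            "metabolite_fraction": metabolite_fraction,
            "n_offsets": n_offsets,
        },
    )
    library = DrugLibrary()
    claimed: list[float] = []  # ion m/z values that must stay separated

    for i in range(n_drugs):
        for _attempt in range(10_000):
            formula = _random_formula(rng)
            precursor = ion_mz(formula, "[M+H]+")
            # every ion value this drug may spawn downstream
            spawn = [precursor, precursor + ISOTOPE_SPACING,
                     precursor + 2 * ISOTOPE_SPACING, precursor + SODIUM_SPACING]
            spawn += [precursor + o.delta_mass for o in offsets]
            if all(
                abs(v - c) > min_precursor_spacing for v in spawn for c in claimed
            ):
                claimed.extend(spawn)
                break
        else:
            raise RuntimeError(
                "could not place a drug with the requested precursor spacing; "
                "lower n_drugs or min_precursor_spacing"
            )
        name = f"drug_{i:03d}"
        cls, area, indication, moa = _CLASSES[i % len(_CLASSES)]
        sources = {"medical"}
        if rng.random() < endogenous_fraction:
            sources.add("endogenous" if rng.random() < 0.5 else "food")
        metadata = PharmMetadata(
            exposure_sources=frozenset(sources),
            therapeutic_area=area,
            pharmacologic_class=cls,
            therapeutic_indication=indication,
            mechanism_of_action=moa,
        )
        peaks = _random_fragments(rng, precursor)
        spectrum = Spectrum(
            spectrum_id=name, precursor_mz=precursor, peaks=peaks,
            rt=float(rng.uniform(1.0, 12.0)),
        )
        library.add(
            DrugLibraryEntry(
                entry_id=name, compound_name=name, parent_drug=name,
                annotation_type="drug", spectrum=spectrum, metadata=metadata,
            )
        )
        truth.drugs[name] = {
            "formula": str(formula),
            "precursor_mz": precursor,
            "exposure_sources": sorted(sources),
            "pharmacologic_class": cls,
            "rt": spectrum.rt,
        }

        if rng.random() < metabolite_fraction:
            offset = offsets[int(rng.integers(0, len(offsets)))]
            met_id = f"{name}_met"
            met_precursor = precursor + offset.delta_mass
            # fragments retaining the modified substructure shift with the
            # precursor; if a state falls outside the usable m/z range the
            # other state is used (the modification sat in the lost neutral)
            shift_mask = rng.random(len(peaks)) < 0.5
            met_peaks = []
            for keep_shift, (mz, inten) in zip(shift_mask, peaks):
                in_range = lambda v: 50.0 < v < met_precursor - 25.0
                shifted_mz = mz + offset.delta_mass
                preferred = shifted_mz if keep_shift else mz
                fallback = mz if keep_shift else shifted_mz
                if in_range(preferred):
                    met_peaks.append((preferred, inten))
                elif in_range(fallback):
                    met_peaks.append((fallback, inten))
            if len(met_peaks) < 5:
                continue  # too few informative fragments to be usable
            met_spectrum = Spectrum(
                spectrum_id=met_id, precursor_mz=met_precursor,
                peaks=tuple(met_peaks), rt=float(rng.uniform(1.0, 12.0)),
            )
            library.add(
                DrugLibraryEntry(
                    entry_id=met_id,
                    compound_name=f"{offset.label} {name}",
                    parent_drug=name, annotation_type="metabolite",
                    spectrum=met_spectrum, metadata=metadata,
                )
            )
            truth.metabolites[met_id] = {
                "parent_drug": name,
                "delta_mass": offset.delta_mass,
                "label": offset.label,
            }
    return library, truth


def _perturb(
    rng: np.random.Generator,
    spectrum: Spectrum,
    spectrum_id: str,
    mz_jitter: float,
    intensity_sd: float,
) -> Spectrum:
    mzs = spectrum.mz + rng.uniform(-mz_jitter, mz_jitter, size=len(spectrum.peaks))
    intensities = spectrum.intensity * np.exp(
        rng.normal(0.0, intensity_sd, size=len(spectrum.peaks))
    )
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=spectrum.precursor_mz
        + float(rng.uniform(-mz_jitter, mz_jitter)),
        peaks=tuple(zip(mzs.tolist(), intensities.tolist())),
        rt=spectrum.rt,
    )


def generate_cohort(
    library: DrugLibrary,
    n_samples: int = 60,
    n_blanks: int = 6,
    exposure_design: dict[str, list[str]] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    mean_log_area: float = np.log(5e5),
    p_adduct: float = 0.35,
    p_isotope: float = 0.35,
    p_insource: float = 0.35,
    p_metabolite: float = 0.6,
    n_decoys: int = 20,
    n_contaminants: int = 5,
    mz_jitter: float = 0.005,
    n_scans: int = 30,
) -> tuple[FeatureTable, GroundTruth]:
    """Generate an aligned feature table, MS2 spectra and sample metadata for
    a cohort with a known exposure design.

    ``exposure_design`` maps group name -> list of exposed drug names; the
    groups partition the non-blank samples evenly in order.  By default two
    groups split the library's drugs into two disjoint halves.  Peak areas
    are lognormal around ``mean_log_area`` with s.d. ``noise_sd``; companion
    ion forms are planted per drug with the ``p_*`` probabilities and carry
    areas proportional to the parent's.
    """
    rng = np.random.default_rng(seed)
    drug_entries = [e for e in library if e.annotation_type == "drug"]
    drug_names = [e.compound_name for e in drug_entries]
    if exposure_design is None:
        half = len(drug_names) // 2
        exposure_design = {
            "group_A": drug_names[:half],
            "group_B": drug_names[half:],
        }
    unknown = {
        d for drugs in exposure_design.values() for d in drugs
    } - set(drug_names)
    if unknown:
        raise ValueError(f"exposure design references unknown drugs: {sorted(unknown)}")

    truth = GroundTruth(
        seed=seed,
        params={
            "n_samples": n_samples, "n_blanks": n_blanks, "noise_sd": noise_sd,
            "n_decoys": n_decoys, "n_contaminants": n_contaminants,
            "n_scans": n_scans,
        },
    )
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    blank_ids = [f"B{i:03d}" for i in range(n_blanks)]
    group_names = list(exposure_design)
    for i, sample in enumerate(sample_ids):
        group = group_names[i * len(group_names) // n_samples]
        truth.groups[sample] = group
        truth.demographics[sample] = {
            "age": int(rng.integers(18, 90)),
            "sex": "female" if rng.random() < 0.5 else "male",
        }
        truth.exposures[sample] = {}

    # ---- features: one aligned feature per planted compound/ion form ----
    features: list[dict] = []
    spectra: dict[str, Spectrum] = {}
    by_drug = {e.compound_name: e for e in drug_entries}
    met_by_drug = {
        e.parent_drug: e for e in library if e.annotation_type == "metabolite"
    }

    def add_feature(role, mz, rt, parent, entry_id, spectrum, apex):
        fid = f"F{len(features):04d}"
        record = {
            "feature_id": fid, "role": role, "mz": mz, "rt": rt,
            "parent_drug": parent, "entry_id": entry_id,
            "spectrum_id": spectrum.spectrum_id if spectrum else "",
        }
        features.append(record)
        if spectrum is not None:
            spectra[spectrum.spectrum_id] = spectrum
        truth.apexes[fid] = apex
        return fid

    drug_feature: dict[str, str] = {}
    companion_features: dict[str, list[tuple[str, float]]] = {}
    for entry in drug_entries:
        name = entry.compound_name
        apex = int(rng.integers(6, n_scans - 6))
        spectrum = _perturb(rng, entry.spectrum, f"q_{name}", mz_jitter, noise_sd)
        fid = add_feature(
            "drug", spectrum.precursor_mz, entry.spectrum.rt, name, entry.entry_id,
            spectrum, apex,
        )
        drug_feature[name] = fid
        companions: list[tuple[str, float]] = []

        if rng.random() < p_adduct:
            mz = entry.spectrum.precursor_mz + SODIUM_SPACING
            # sodiated form: same fragments plus the protonated precursor ion
            peaks = entry.spectrum.peaks + ((entry.spectrum.precursor_mz, 40.0),)
            s = _perturb(
                rng,
                Spectrum(f"q_{name}_Na", mz, peaks, rt=entry.spectrum.rt),
                f"q_{name}_Na", mz_jitter, noise_sd,
            )
            cid = add_feature("adduct", mz, entry.spectrum.rt, name, "", s, apex)
            companions.append((cid, 0.30))
        if rng.random() < p_isotope:
            mz = entry.spectrum.precursor_mz + ISOTOPE_SPACING
            s = _perturb(
                rng,
                Spectrum(f"q_{name}_iso", mz, entry.spectrum.peaks,
                         rt=entry.spectrum.rt),
                f"q_{name}_iso", mz_jitter, noise_sd,
            )
            cid = add_feature("isotope", mz, entry.spectrum.rt, name, "", s, apex)
            companions.append((cid, 0.25))
        if rng.random() < p_insource and len(entry.spectrum.peaks) >= 4:
            # precursor of the in-source ion equals one mid-list drug fragment
            frag_index = int(rng.integers(1, len(entry.spectrum.peaks) - 1))
            frag_mz = entry.spectrum.peaks[frag_index][0]
            sub_peaks = tuple(
                p for p in entry.spectrum.peaks if p[0] < frag_mz - 25.0
            )
            if len(sub_peaks) >= 5:
                s = _perturb(
                    rng,
                    Spectrum(f"q_{name}_isf", frag_mz, sub_peaks,
                             rt=entry.spectrum.rt),
                    f"q_{name}_isf", mz_jitter, noise_sd,
                )
                cid = add_feature(
                    "in_source_fragment", frag_mz, entry.spectrum.rt, name, "", s, apex
                )
                companions.append((cid, 0.40))
        if name in met_by_drug and rng.random() < p_metabolite:
            met = met_by_drug[name]
            s = _perturb(
                rng, met.spectrum, f"q_{met.entry_id}", mz_jitter, noise_sd
            )
            met_apex = min(apex + 5, n_scans - 1)  # independent, shifted elution
            cid = add_feature(
                "metabolite", met.spectrum.precursor_mz, met.spectrum.rt,
                name, met.entry_id, s, met_apex,
            )
            companions.append((cid, 0.50))
        companion_features[name] = companions

    all_precursors = [e.spectrum.precursor_mz for e in library]
    for i in range(n_decoys):
        while True:
            mz = float(rng.uniform(150.0, 600.0))
            if all(abs(mz - p) > 0.1 for p in all_precursors):
                break
        peaks = tuple(
            zip(
                np.sort(rng.uniform(50.0, mz - 25.0, size=8)).tolist(),
                rng.uniform(10.0, 100.0, size=8).tolist(),
            )
        )
        s = Spectrum(f"q_decoy_{i:02d}", mz, peaks, rt=float(rng.uniform(1, 12)))
        add_feature("decoy", mz, s.rt, None, "", s, int(rng.integers(6, n_scans - 6)))
    for i in range(n_contaminants):
        mz = float(rng.uniform(150.0, 600.0))
        add_feature(
            "contaminant", mz, float(rng.uniform(1, 12)), None, "", None,
            int(rng.integers(6, n_scans - 6)),
        )

    truth.features = features

    # ---- area matrix ----
    all_ids = sample_ids + blank_ids
    areas = pd.DataFrame(0.0, index=[f["feature_id"] for f in features],
                         columns=all_ids)
    for sample in sample_ids:
        for drug in exposure_design[truth.groups[sample]]:
            area = float(np.exp(rng.normal(mean_log_area, noise_sd)))
            truth.exposures[sample][drug] = area
            areas.loc[drug_feature[drug], sample] = area
            for cid, ratio in companion_features[drug]:
                areas.loc[cid, sample] = area * ratio * float(
                    np.exp(rng.normal(0.0, noise_sd))
                )
    decoy_ids = [f["feature_id"] for f in features if f["role"] == "decoy"]
    for fid in decoy_ids:
        chosen = rng.random(n_samples) < 0.2
        for sample, hit in zip(sample_ids, chosen):
            if hit:
                areas.loc[fid, sample] = float(
                    np.exp(rng.normal(mean_log_area - 1.0, noise_sd))
                )
    contaminant_ids = [
        f["feature_id"] for f in features if f["role"] == "contaminant"
    ]
    for fid in contaminant_ids:  # present everywhere at comparable level
        areas.loc[fid, :] = np.exp(
            rng.normal(mean_log_area - 1.0, noise_sd, size=len(all_ids))
        )

    feature_frame = pd.DataFrame(
        {
            "feature_id": [f["feature_id"] for f in features],
            "mz": [f["mz"] for f in features],
            "rt": [f["rt"] for f in features],
            "ms2_spectrum_id": [f["spectrum_id"] for f in features],
        }
    )
    sample_frame = pd.DataFrame(
        {
            "sample_id": all_ids,
            "is_blank": [s in blank_ids for s in all_ids],
            "group": [truth.groups.get(s, "") for s in all_ids],
            "age": [truth.demographics.get(s, {}).get("age", np.nan)
                    for s in all_ids],
            "sex": [truth.demographics.get(s, {}).get("sex", "") for s in all_ids],
        }
    ).set_index("sample_id")
    table = FeatureTable(
        features=feature_frame, areas=areas, samples=sample_frame, spectra=spectra
    )
    return table, truth


def generate_ms1_runs(
    table: FeatureTable,
    truth: GroundTruth,
    scans_per_peak: int = 10,
    sigma_scans: float = 1.5,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-sample MS1 scan sets with Gaussian elution profiles.

    Every feature with a nonzero area in a sample contributes a Gaussian
    profile centered on its apex scan (companions share the parent's apex by
    construction of the cohort).  Returns, per sample, a long DataFrame with
    columns scan, rt, mz, intensity — at least ``scans_per_peak`` scans cover
    each peak.
    """
    n_scans = int(truth.params.get("n_scans", 30))
    if n_scans < scans_per_peak:
        raise ValueError("run too short for the requested scans per peak")
    runs: dict[str, pd.DataFrame] = {}
    scan_grid = np.arange(n_scans)
    for sample in table.areas.columns:
        rows = []
        for f in truth.features:
            area = float(table.areas.loc[f["feature_id"], sample])
            if area <= 0:
                continue
            apex = truth.apexes[f["feature_id"]]
            profile = area * np.exp(
                -0.5 * ((scan_grid - apex) / sigma_scans) ** 2
            )
            for scan, intensity in zip(scan_grid, profile):
                if intensity > 0:
                    rows.append(
                        (int(scan), float(scan) * 0.05, f["mz"], float(intensity))
                    )
        runs[sample] = pd.DataFrame(
            rows, columns=["scan", "rt", "mz", "intensity"]
        ).sort_values(["scan", "mz"], ignore_index=True)
    return runs


def write_ms1_mzml(run: pd.DataFrame, path: str) -> None:
    """Write one generated MS1 run as a minimal centroid mzML file.

    Uncompressed 64-bit arrays, one spectrum element per MS1 scan; readable
    by standard mzML parsers.
    """
    import base64
    import struct

    def encode(values: list[float]) -> str:
        return base64.b64encode(
            struct.pack(f"<{len(values)}d", *values)
        ).decode()

    scans = sorted(run["scan"].unique()) if len(run) else []
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<run id="run">',
        f'<spectrumList count="{len(scans)}">',
    ]
    for index, scan in enumerate(scans):
        block = run[run["scan"] == scan]
        mzs = block["mz"].tolist()
        intensities = block["intensity"].tolist()
        rt = float(block["rt"].iloc[0]) if len(block) else 0.0
        mz_b64 = encode(mzs)
        int_b64 = encode(intensities)
        parts.append(
            f'<spectrum index="{index}" id="scan={scan}" '
            f'defaultArrayLength="{len(mzs)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt}" unitName="minute"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
            f"<binary>{mz_b64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
            f"<binary>{int_b64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    parts += ["</spectrumList>", "</run>", "</mzML>"]
    with open(path, "w") as handle:
        handle.write("\n".join(parts))
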