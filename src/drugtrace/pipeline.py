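"""End-to-end orchestration on in-memory objects: simulate -> annotate ->
curate -> classify ion forms -> exposure readout -> stratify, with a
machine-readable run report.

This is the composition root used by the command-line interface, the test
suite and the reproduction script; every stage is an ordinary function from
the corresponding module.
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .analog_curation import (
    AnalogCandidate,
    cooccurrence_fraction,
    run_curation,
)
from .chem_mass import load_mass_offsets
from .config import RunConfig
from .drug_library import DrugLibrary
from .exposure_readout import (
    blank_filter,
    exclude_nonmedical,
    group_by_parent,
    noise_floor,
    summarize_ontology,
)
from .ion_form import XICTrace, classify_ion_form
from .spectra_io import FeatureTable
from .spectral_match import analog_search, library_search
from .stratification import cluster_samples
from .synthetic_data import GroundTruth, generate_cohort, generate_library, generate_ms1_runs

__all__ = [
    "annotate_cohort",
    "classify_planted_analogs",
    "evaluate_recovery",
    "extract_trace",
    "pipeline_run",
]


def extract_trace(
    run: pd.DataFrame,
    target_mz: float,
    apex_scan: int,
    tol: float = 0.01,
    width: int = 10,
    n_scans: int | None = None,
) -> XICTrace:
    """Apex-centered XIC from a generated MS1 run (long scan table).

    Sums intensity within ``±tol`` of ``target_mz`` over ``width``
    consecutive scans centered on ``apex_scan``; the window is truncated at
    run boundaries with a warning.
    """
    if n_scans is None:
        n_scans = int(run["scan"].max()) + 1 if len(run) else width
    start = apex_scan - width // 2
    stop = start + width
    if start < 0 or stop > n_scans:
        warnings.warn("apex window truncated at run boundary")
        start = max(start, 0)
        stop = min(stop, n_scans)
    points = []
    for scan in range(start, stop):
        block = run[(run["scan"] == scan) & (np.abs(run["mz"] - target_mz) <= tol)]
        points.append((scan, float(block["intensity"].sum())))
    return XICTrace(target_mz=target_mz, points=tuple(points))


def annotate_cohort(
    table: FeatureTable, library: DrugLibrary, config: RunConfig
) -> pd.DataFrame:
    """Library-search every MS2 spectrum of a cohort and join accepted
    best annotations back onto feature ids."""
    spectra = list(table.spectra.values())
    annotations = library_search(
        spectra,
        library,
        precursor_tol=config.precursor_tol,
        frag_tol=config.frag_tol,
        search_min_score=config.search_min_score,
        search_min_peaks=config.search_min_peaks,
        accept_min_score=config.accept_min_score,
        accept_min_peaks=config.accept_min_peaks,
    )
    accepted = annotations[annotations["accepted"] & annotations["best"]]
    link = table.features[["feature_id", "ms2_spectrum_id"]].rename(
        columns={"ms2_spectrum_id": "spectrum_id"}
    )
    return accepted.merge(link, on="spectrum_id", how="inner")


def classify_planted_analogs(
    table: FeatureTable,
    truth: GroundTruth,
    runs: dict[str, pd.DataFrame],
    config: RunConfig,
) -> pd.DataFrame:
    """Run the three-stage ion-form classifier on every planted analog
    feature, using XIC traces from samples where analog and parent co-occur.

    Returns a table with the planted role, the assigned label and evidence.
    """
    drug_features = {
        f["parent_drug"]: f for f in truth.features if f["role"] == "drug"
    }
    rows = []
    for record in truth.analog_features():
        parent = drug_features[record["parent_drug"]]
        parent_spectrum = table.spectra[parent["spectrum_id"]]
        analog_spectrum = table.spectra[record["spectrum_id"]]
        offset = record["mz"] - parent["mz"]
        traces = []
        for sample, run in runs.items():
            fid = record["feature_id"]
            if (
                table.areas.loc[fid, sample] > 0
                and table.areas.loc[parent["feature_id"], sample] > 0
            ):
                apex = truth.apexes[parent["feature_id"]]
                traces.append(
                    (
                        extract_trace(run, parent["mz"], apex, tol=config.offset_tol),
                        extract_trace(run, record["mz"], apex, tol=config.offset_tol),
                    )
                )
            if len(traces) >= 3:  # max-over-files saturates quickly
                break
        label = classify_ion_form(
            offset,
            parent_spectrum,
            analog_spectrum,
            cooccurring_traces=traces,
            r2_threshold=config.r2_threshold,
            offset_tol=config.offset_tol,
            frag_tol=config.frag_tol,
        )
        planted = record["role"] if record["role"] != "metabolite" else "derivative"
        rows.append(
            {
                "feature_id": record["feature_id"],
                "parent_drug": record["parent_drug"],
                "planted": planted,
                "label": label.label,
                "evidence": label.evidence,
                "detail": label.detail,
            }
        )
    return pd.DataFrame(rows)


def evaluate_recovery(
    table: FeatureTable,
    truth: GroundTruth,
    library: DrugLibrary,
    config: RunConfig,
) -> dict:
    """Score the annotate -> filter -> group pipeline against ground truth.

    Returns recall of planted (sample, drug) exposures, count of detected
    pairs that were never planted, and the adjusted Rand index of Ward
    clustering at k = number of design groups.
    """
    annotations = annotate_cohort(table, library, config)
    filtered = blank_filter(table, fold=config.blank_fold)
    filtered = noise_floor(filtered, floor=config.noise_floor_value)
    exposure = group_by_parent(annotations, filtered, library)
    exposure, removed_nonmedical = exclude_nonmedical(exposure)

    planted_medical = {
        (sample, drug)
        for sample, drugs in truth.exposures.items()
        for drug in drugs
        if drug not in removed_nonmedical
    }
    detected_pairs = {
        (sample, drug)
        for drug in exposure.parent_drugs
        for sample in exposure.detected.index[exposure.detected[drug]]
    }
    true_hits = detected_pairs & planted_medical
    recall = len(true_hits) / len(planted_medical) if planted_medical else np.nan
    false_pairs = detected_pairs - planted_medical

    k = len(set(truth.groups.values()))
    ari = np.nan
    if k >= 2 and len(exposure.areas) >= k:
        assignment = cluster_samples(exposure.areas, k=k)
        labels_true = [truth.groups[s] for s in exposure.areas.index]
        labels_pred = [assignment.labels[str(s)] for s in exposure.areas.index]
        ari = float(adjusted_rand_score(labels_true, labels_pred))

    return {
        "n_planted": len(planted_medical),
        "n_detected_pairs": len(detected_pairs),
        "recall": recall,
        "false_pairs": sorted(false_pairs),
        "n_false_pairs": len(false_pairs),
        "removed_nonmedical": removed_nonmedical,
        "adjusted_rand": ari,
        "exposure": exposure,
        "annotations": annotations,
    }


def pipeline_run(
    config: RunConfig,
    n_drugs: int = 50,
    n_samples: int = 60,
    n_blanks: int = 6,
    stages: tuple[str, ...] = (
        "simulate", "search", "curate", "ionform", "readout",
    ),
) -> dict:
    """Execute the standard stage sequence on a simulated cohort and return
    a run report with per-stage counts, wall-clock and warnings."""
    known = {"simulate", "search", "curate", "ionform", "readout"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict = {"config": config.to_dict(), "stages": {}}
    t0 = time.perf_counter()

    library, lib_truth = generate_library(n_drugs, seed=config.seed)
    table, truth = generate_cohort(
        library, n_samples=n_samples, n_blanks=n_blanks, seed=config.seed
    )
    report["stages"]["simulate"] = {
        "n_library_entries": len(library),
        "n_features": len(table.features),
        "n_samples": n_samples,
        "n_blanks": n_blanks,
    }

    results: dict = {"library": library, "table": table, "truth": truth,
                     "library_truth": lib_truth}

    if "search" in stages:
        annotations = annotate_cohort(table, library, config)
        report["stages"]["search"] = {
            "n_spectra": len(table.spectra),
            "n_accepted": int(len(annotations)),
        }
        results["annotations"] = annotations

    if "curate" in stages:
        offsets = load_mass_offsets()
        spectra = list(table.spectra.values())
        candidates = []
        for entry in library:
            if entry.annotation_type != "drug":
                continue
            hits = analog_search(
                entry.spectrum,
                spectra,
                precursor_window=config.analog_window,
                min_score=config.analog_min_score,
                min_peaks=config.analog_min_peaks,
                frag_tol=config.frag_tol,
            )
            for hit in hits:
                if abs(hit.mass_offset) < config.precursor_tol:
                    continue  # the drug itself, not an analog
                candidates.append(
                    AnalogCandidate(
                        match=hit,
                        parent_drug=entry.compound_name,
                        analog_spectrum=table.spectra[hit.target_id],
                    )
                )
        curated, curation_report = run_curation(
            candidates, library, offsets, full_library=library,
            offset_tol=config.offset_tol,
            library_score_thr=config.library_score_thr,
            library_peaks_thr=config.library_peaks_thr,
            max_frequency=config.max_frequency,
            dedup_min_score=config.dedup_min_score,
        )
        report["stages"]["curate"] = curation_report.to_dict()
        results["curated"] = curated
        results["curation_report"] = curation_report

        detections = {
            sample: {
                f["spectrum_id"]
                for f in truth.features
                if f["spectrum_id"] and table.areas.loc[f["feature_id"], sample] > 0
            }
            | {
                f["parent_drug"]
                for f in truth.features
                if f["role"] == "drug" and table.areas.loc[f["feature_id"], sample] > 0
            }
            for sample in table.sample_ids
        }
        fractions = [
            cooccurrence_fraction(c.analog_id, c.parent_drug, detections)
            for c in curated
        ]
        fractions = [f for f in fractions if f is not None]
        report["stages"]["curate"]["mean_cooccurrence"] = (
            float(np.mean(fractions)) if fractions else None
        )

    if "ionform" in stages:
        runs = generate_ms1_runs(table, truth, seed=config.seed)
        labels = classify_planted_analogs(table, truth, runs, config)
        agreement = (
            float((labels["planted"] == labels["label"]).mean())
            if len(labels)
            else np.nan
        )
        report["stages"]["ionform"] = {
            "n_analogs": int(len(labels)),
            "label_agreement": agreement,
        }
        results["ionform_labels"] = labels

    if "readout" in stages:
        recovery = evaluate_recovery(table, truth, library, config)
        summary = summarize_ontology(recovery["exposure"], level="pharmacologic_class")
        report["stages"]["readout"] = {
            "n_parent_drugs": len(recovery["exposure"].parent_drugs),
            "recall": recovery["recall"],
            "n_false_pairs": recovery["n_false_pairs"],
            "adjusted_rand": recovery["adjusted_rand"],
            "n_classes": int(summary.shape[1]),
        }
        results["recovery"] = recovery

    report["wall_clock_s"] = time.perf_counter() - t0
    report["results"] = results
    return report
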