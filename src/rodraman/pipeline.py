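"""End-to-end orchestration: simulate -> preprocess -> ratios -> classify ->
majority-vote aggregation, with every artifact written to disk.

One global seed fans out into independent substreams for the synthetic
cohort and for fold shuffling, so changing the classifier seed never
perturbs the simulated spectra. ``run_pipeline`` is deterministic given its
config and finishes with a checksummed manifest of everything it wrote.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .aggregate import AggregationInputs, aggregate, error_curves
from .biomarkers import biomarker_table
from .classify import (crossval_table, diagnostic_report, fit_logit_lda,
                       fit_pca_lsvm)
from .preprocess import (DEFAULT_WINDOWS, crop, extract_all_bands,
                         linear_baseline_subtract, normalize_to_reference)
from .synth import Cohort, SimConfig, simulate_cohort
from .viz import score_histogram, save_error_curves_plot, save_score_histogram_plot

logger = logging.getLogger("rodraman")

__all__ = ["PipelineConfig", "run_pipeline", "extract_feature_table",
           "preprocess_spectrum", "preprocessed_matrix"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    ``classifier`` is ``"lda4"`` (linear discriminant on the four biomarker
    ratios) or ``"pca20_lsvm"`` (PCA to 20 components + linear SVM on the
    preprocessed spectra). ``spectra_per_class`` scales the cohort down from
    full 150 x 150 maps; ``None`` keeps the configured map geometry.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    classifier: str = "lda4"
    folds: int = 10
    classifier_seed: int | None = None
    alpha: float = 0.05
    n_spectra: int = 11
    n_max_curve: int = 51
    spectra_per_class: int | None = 2000
    phenylalanine_bands: str = "both"
    write_plots: bool = True

    def __post_init__(self):
        if self.classifier not in ("lda4", "pca20_lsvm"):
            raise ValueError("classifier must be 'lda4' or 'pca20_lsvm'")

    def seeds(self) -> tuple[int, int]:
        """(cohort_seed, fold_seed) fanned out from the global seed."""
        ss = np.random.SeedSequence(self.sim.seed).spawn(2)
        cohort_seed = int(ss[0].generate_state(1)[0] % (2**31))
        fold_seed = (int(ss[1].generate_state(1)[0] % (2**31))
                     if self.classifier_seed is None else self.classifier_seed)
        return cohort_seed, fold_seed


def preprocess_spectrum(spectrum, lo=377.0, hi=1720.0):
    """Standard per-spectrum chain: crop, normalize to the laser line,
    subtract the global linear background."""
    return linear_baseline_subtract(normalize_to_reference(crop(spectrum, lo, hi)))


def extract_feature_table(cohort: Cohort, windows=DEFAULT_WINDOWS,
                          phenylalanine_bands: str = "both"):
    """Cohort -> per-spectrum band areas -> biomarker feature table.

    Returns (features, n_invalid): one row per valid spectrum with
    spectrum_id / sample_id / class and the four ratios.
    """
    rows = []
    for smap in cohort.maps:
        for idx, spec in enumerate(smap.iter_spectra()):
            pre = preprocess_spectrum(spec)
            areas = extract_all_bands(pre, windows)
            areas["spectrum_id"] = f"{smap.sample_id}:{idx}"
            areas["sample_id"] = smap.sample_id
            areas["class"] = smap.class_label
            rows.append(areas)
    area_df = pd.DataFrame(rows)
    features, n_invalid = biomarker_table(
        area_df, phenylalanine_bands=phenylalanine_bands)
    logger.info("extracted %d spectra (%d invalid records excluded)",
                len(features), n_invalid)
    return features, n_invalid


def preprocessed_matrix(cohort: Cohort):
    """Cohort -> (X, y, sample_ids, spectrum_ids) of preprocessed full
    spectra for the PCA + linear SVM route."""
    X, y, sids, specids = [], [], [], []
    for smap in cohort.maps:
        for idx, spec in enumerate(smap.iter_spectra()):
            pre = preprocess_spectrum(spec)
            X.append(pre.intensities)
            y.append(smap.class_label)
            sids.append(smap.sample_id)
            specids.append(f"{smap.sample_id}:{idx}")
    return np.asarray(X), np.asarray(y), sids, specids


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the whole analysis; returns the artifact manifest as a dict.

    Artifacts: per-sample map CSVs, cohort manifest, echoed config, feature
    table, scored-spectrum table, single-spectrum metrics, error-curve table,
    N-spectra metrics, optional plots, and ``manifest.csv`` with a sha256
    checksum per file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_seed, fold_seed = config.seeds()
    sim = replace(config.sim, seed=cohort_seed)
    if sim.n_normal_samples < 1 or sim.n_rod_samples < 1:
        raise ValueError("need at least one sample of each class "
                         "(classifier training requires both)")

    logger.info("simulating cohort (seed %d)", cohort_seed)
    if config.spectra_per_class is not None:
        n_norm, n_rod = sim.n_normal_samples, sim.n_rod_samples
        per = ([-(-config.spectra_per_class // n_norm)] * n_norm
               + [-(-config.spectra_per_class // n_rod)] * n_rod)
        cohort = simulate_cohort(sim, spectra_per_sample=per)
    else:
        cohort = simulate_cohort(sim)
    logger.info("cohort: %s", dict(zip(cohort.manifest["sample_id"],
                                       cohort.manifest["n_spectra"])))

    artifacts: list[Path] = []

    def emit(path: Path):
        artifacts.append(path)
        return path

    for smap in cohort.maps:
        rio.write_map(emit(outdir / f"map_{smap.sample_id}.csv"), smap)
    rio.write_manifest(emit(outdir / "cohort_manifest.csv"), cohort.manifest)
    rio.write_config(emit(outdir / "config.yaml"), config)

    features, n_invalid = extract_feature_table(
        cohort, phenylalanine_bands=config.phenylalanine_bands)
    rio.write_features(emit(outdir / "features.csv"), features)

    logger.info("cross-validating %s (%d folds, seed %d)",
                config.classifier, config.folds, fold_seed)
    if config.classifier == "lda4":
        scored = crossval_table(features, fitter=fit_logit_lda,
                                k=config.folds, seed=fold_seed)
    else:
        X, y, sids, specids = preprocessed_matrix(cohort)
        from .classify import crossval_scores
        scored = crossval_scores(X, y, fitter=fit_pca_lsvm, k=config.folds,
                                 seed=fold_seed, sample_ids=sids,
                                 spectrum_ids=specids)
    pd.DataFrame([{
        "spectrum_id": s.spectrum_id, "sample_id": s.sample_id,
        "true_class": s.true_class, "score": s.score,
        "fold_index": s.fold_index,
    } for s in scored]).to_csv(emit(outdir / "scores.csv"), index=False)

    report = diagnostic_report(scored)
    single = report.to_dict()
    single_pct = report.to_dict(percent=True)
    rio.write_metrics(emit(outdir / "single_spectrum_metrics.json"), {
        **{k: single[k] for k in single},
        **{f"{k}_pct": v for k, v in single_pct.items()
           if k not in ("tp", "fp", "fn", "tn")},
        "n_invalid_records": n_invalid,
    })
    logger.info("single-spectrum accuracy %.3f (sens %.3f, spec %.3f)",
                report.accuracy, report.sensitivity, report.specificity)

    inputs = AggregationInputs(p1=report.specificity, p2=report.sensitivity,
                               prevalence=report.prevalence, alpha=config.alpha)
    result = aggregate(inputs, n=config.n_spectra)
    curves = error_curves(inputs, n_max=config.n_max_curve)
    curves.to_csv(emit(outdir / "error_curves.csv"), index=False)
    agg_metrics = result.confusion.to_dict()
    rio.write_metrics(emit(outdir / "aggregate_metrics.json"), {
        "p1": inputs.p1, "p2": inputs.p2, "prevalence": inputs.prevalence,
        "alpha": inputs.alpha, "N": result.n,
        "q1_type1_error": result.q1, "q2_type2_error": result.q2,
        "n_star_type1": result.n_star_type1,
        "n_star_type2": result.n_star_type2,
        **{f"n_spectra_{k}": v for k, v in agg_metrics.items()},
        **{f"n_spectra_{k}_pct": v for k, v in
           result.confusion.to_dict(percent=True).items()
           if k not in ("tp", "fp", "fn", "tn")},
    })
    logger.info("majority vote: n*_typeI=%d n*_typeII=%d, "
                "accuracy at N=%d: %.4f", result.n_star_type1,
                result.n_star_type2, result.n, result.confusion.accuracy)

    if config.write_plots:
        hist = score_histogram(scored)
        pd.DataFrame({
            "bin_lo": hist["bin_edges"][:-1], "bin_hi": hist["bin_edges"][1:],
            "normal_density": hist["normal_density"],
            "rod_density": hist["rod_density"],
        }).to_csv(emit(outdir / "score_histogram.csv"), index=False)
        save_score_histogram_plot(hist, emit(outdir / "score_histogram.png"))
        save_error_curves_plot(curves, emit(outdir / "error_curves.png"))

    manifest = pd.DataFrame(
        [(p.name, _sha256(p)) for p in artifacts],
        columns=["artifact", "sha256"],
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return {
        "report": report,
        "aggregation": result,
        "manifest": manifest,
        "n_invalid": n_invalid,
        "outdir": outdir,
    }
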