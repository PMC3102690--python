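"""End-to-end workflows: preprocess -> normalize -> select K-mers -> fit ->
predict -> evaluate, plus the parameter-sensitivity sweeps (maximum K-mer
length and regularized 7/8-mer count) run on synthetic bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .io import PBMSample
from .kmers import select_kmers, build_design_matrix
from .model import (AffinityModel, NoiseModel, center_intensities, evaluate,
                    fit_affinities, fit_stepwise, predict,
                    tie_reverse_complements)
from .preprocess import (filter_low_intensity, log_transform,
                         quantile_normalize, spatial_detrend)

logger = logging.getLogger("pbmlin")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    log_base: float = 2.0
    filter: bool = True
    filter_fraction: float = 0.05
    bins: int = 100
    detrend: bool = True
    window: int = 7
    normalize: bool = True
    n7: int = 2000
    n8: int = 1000
    gapped_n: int = 0
    gap_offset: int = 4
    strand_tied: bool = False
    stepwise: bool = False
    cg_iters: int = 10
    cg_tol: float = 0.0
    seed: int = 0


def preprocess_sample(sample: PBMSample, config: RunConfig) -> PBMSample:
    """Log transform plus the enabled filtering/detrending steps."""
    s = sample
    if s.log_base is None:
        s = log_transform(s, base=config.log_base)
    if config.filter:
        s = filter_low_intensity(s, fraction=config.filter_fraction,
                                 n_bins=config.bins)
    if config.detrend:
        s = spatial_detrend(s, window=config.window)
    return s


def run_pipeline(
    train: PBMSample,
    target_design: PBMSample,
    target_truth: PBMSample | None = None,
    config: RunConfig | None = None,
    normalize_group: list[PBMSample] | None = None,
    noise_model: NoiseModel | None = None,
    median_cache: dict | None = None,
    kmer_selection: dict | None = None,
) -> dict:
    """Full prediction workflow; returns a report dict.

    ``normalize_group`` supplies additional samples whose pooled
    distribution defines the quantile-normalization reference (normalizing
    a single sample against itself is the identity, so it is skipped).
    ``kmer_selection`` overrides the feature-selection arguments passed to
    :func:`pbmlin.kmers.select_kmers` (used by the sweeps).
    """
    config = config or RunConfig()
    logger.info("pbmlin %s run_pipeline config=%s", __version__, asdict(config))

    t = preprocess_sample(train, config)
    if config.normalize and normalize_group:
        group = [preprocess_sample(g, config) for g in normalize_group]
        t = quantile_normalize([t] + group)[0]

    if kmer_selection is None:
        kmer_selection = dict(full_ks=(4, 5, 6),
                              top_counts={7: config.n7, 8: config.n8},
                              gapped_top=config.gapped_n,
                              gap_offset=config.gap_offset)
    kset = select_kmers(t, median_cache=median_cache, **kmer_selection)

    v = t.intensities()
    ok = ~np.isnan(v)
    sequences = [s for s, keep in zip(t.sequences(), ok) if keep]
    row_ids = [p for p, keep in zip(t.probes["probe_id"], ok) if keep]
    design = build_design_matrix(sequences, kset, row_ids=row_ids)
    if config.strand_tied:
        kset, design = tie_reverse_complements(kset, design)
    p, mean = center_intensities(v[ok])

    fitter = fit_stepwise if config.stepwise else fit_affinities
    model = fitter(design, p, iterations=config.cg_iters, tol=config.cg_tol,
                   noise_model=noise_model, training_mean=mean,
                   log_base=config.log_base,
                   training_probe_length=len(sequences[0]))

    predictions = predict(model, target_design.sequences())
    report = {
        "config": asdict(config),
        "version": __version__,
        "n_training_probes": int(ok.sum()),
        "n_features": len(kset),
        "training_mean": mean,
        "model": model,
        "predictions": pd.DataFrame({
            "probe_id": target_design.probes["probe_id"],
            "predicted_intensity": predictions,
        }),
    }
    if target_truth is not None:
        truth = target_truth
        if truth.log_base is None:
            truth = log_transform(truth, base=config.log_base)
        pearson, spearman = evaluate(predictions, truth.intensities())
        report["pearson"] = pearson
        report["spearman"] = spearman
        logger.info("evaluation: pearson=%.4f spearman=%.4f", pearson, spearman)
    return report


def sweep_kmer_length(
    train: PBMSample,
    target_design: PBMSample,
    target_truth: PBMSample,
    k_values: tuple[int, ...] = (4, 5, 6, 7, 8),
    n_top: int = 1000,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Prediction accuracy as a function of the maximum K-mer length.

    Lengths up to 6 enter in full; 7-9-mers are regularized to the
    ``n_top`` highest-median-intensity K-mers per length.
    """
    config = config or RunConfig()
    cache: dict = {}
    rows = []
    for k_max in k_values:
        if not 4 <= k_max <= 9:
            raise ValueError(f"k_max {k_max} outside 4..9")
        selection = dict(
            full_ks=tuple(range(4, min(k_max, 6) + 1)),
            top_counts={k: n_top for k in range(7, k_max + 1)},
            gapped_top=0,
        )
        report = run_pipeline(train, target_design, target_truth,
                              config=config, median_cache=cache,
                              kmer_selection=selection)
        rows.append({"k_max": k_max, "n_features": report["n_features"],
                     "pearson": report["pearson"],
                     "spearman": report["spearman"]})
    return pd.DataFrame(rows)


def sweep_regularization(
    train: PBMSample,
    target_design: PBMSample,
    target_truth: PBMSample,
    n78_grid: tuple[int, ...] = (0, 100, 1000),
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Prediction accuracy as a function of the regularized 7/8-mer count
    (the same count n is used for both lengths)."""
    config = config or RunConfig()
    cache: dict = {}
    rows = []
    for n in n78_grid:
        selection = dict(full_ks=(4, 5, 6), top_counts={7: n, 8: n},
                         gapped_top=0)
        report = run_pipeline(train, target_design, target_truth,
                              config=config, median_cache=cache,
                              kmer_selection=selection)
        rows.append({"n78": n, "n_features": report["n_features"],
                     "pearson": report["pearson"],
                     "spearman": report["spearman"]})
    return pd.DataFrame(rows)
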