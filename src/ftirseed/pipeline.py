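"""End-to-end experiment protocols.

Two experiments mirror the two halves of the analysis:

* the *cluster* experiment — 10 specimens per class, 17-peak tables, Ward
  dendrogram plus the fuzzy transitive-closure λ-series with its validity
  index — probes whether whole-peak-table similarity separates the classes
  (it separates the distinct class but not the sibling pair);
* the *classification* experiment — the full benchmark of 20 specimens per
  (class × batch) cell in each split — runs replicate averaging, baseline
  correction, training-split-only region selection, wavelet-energy
  featurization and RBF classification, and reports per-cell recognition
  rates in percent.

Nothing computed from the test split (regions, feature scaling, network
weights) ever feeds back into training; a ``leak_regions`` switch exists
solely so tests can verify that breaking this protocol can only help, never
hurt, apparent accuracy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fuzzy
from .dwt import WaveletSpec, dwt_multilevel
from .errors import SchemaError
from .features import (
    REGION_COUNTS,
    FeatureRegion,
    featurize_batch,
    select_regions,
)
from .preprocess import align_peak_tables, average_replicates, baseline_correct, pick_peaks
from .rbf import RecognitionReport, TrainConfig, evaluate, train
from .synth import CLASSES, GeneratorConfig, Spectrum, generate_dataset, generate_spectrum


@dataclass
class RunConfig:
    """Every knob of one benchmark run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_per_cell: int = 20
    m_peaks: int = 17
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    levels: int = 5
    region_counts: Mapping[int, int] = field(default_factory=lambda: dict(REGION_COUNTS))
    smooth_window: int = 3
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0


def run_config_from_mapping(raw: Mapping) -> RunConfig:
    """Build a :class:`RunConfig` from a plain (YAML/JSON) mapping.

    Unknown keys raise :class:`SchemaError` naming the offending key path, as
    do wrongly-typed sections.
    """
    if not isinstance(raw, Mapping):
        raise SchemaError("run configuration must be a mapping")
    cfg = RunConfig()
    allowed = {
        "generator", "n_per_cell", "m_peaks", "wavelet", "levels",
        "region_counts", "smooth_window", "train", "seed",
    }
    for key in raw:
        if key not in allowed:
            raise SchemaError(f"unknown configuration key {key!r}")
    try:
        if "generator" in raw:
            cfg.generator = GeneratorConfig(**dict(raw["generator"]))
        if "wavelet" in raw:
            cfg.wavelet = WaveletSpec(**dict(raw["wavelet"]))
        if "train" in raw:
            cfg.train = TrainConfig(**dict(raw["train"]))
    except TypeError as exc:
        raise SchemaError(str(exc)) from exc
    for key in ("n_per_cell", "m_peaks", "levels", "smooth_window", "seed"):
        if key in raw:
            setattr(cfg, key, int(raw[key]))
    if "region_counts" in raw:
        cfg.region_counts = {int(k): int(v) for k, v in raw["region_counts"].items()}
    return cfg


# ---------------------------------------------------------------------------
# Cluster experiment


@dataclass
class ClusterResult:
    dendrogram: fuzzy.Dendrogram
    top_cut: np.ndarray            # 2-group labels from the top split
    sample_ids: list[str]
    class_ids: np.ndarray
    partitions: list[fuzzy.Partition]
    validity: pd.DataFrame
    peak_matrix: pd.DataFrame


_CLASS_PREFIX = {1: "a", 2: "b", 3: "c"}


def run_cluster_experiment(
    config: RunConfig | None = None,
    n_per_class: int = 10,
    seed: int | None = None,
) -> ClusterResult:
    """Generate specimens, build aligned 17-peak tables, cluster them.

    ``n_per_class`` specimens per class are drawn with batches cycled so the
    three locations contribute evenly; each specimen is the baseline-corrected
    average of its three replicate scans.  Sample ids follow the a/b/c-prefix
    convention (a = class 1, b = class 2, c = class 3).
    """
    config = config or RunConfig()
    gen = config.generator
    if seed is not None:
        gen = replace(gen, seed=seed)
    spectra: list[Spectrum] = []
    specimen_id = 0
    for class_id in CLASSES:
        for i in range(n_per_class):
            batch_id = gen.batches[i % len(gen.batches)]
            reps = [
                generate_spectrum(gen, class_id, batch_id, specimen_id, r)
                for r in (1, 2, 3)
            ]
            spectra.append(baseline_correct(average_replicates(reps)))
            specimen_id += 1

    tables = [pick_peaks(s, m=config.m_peaks) for s in spectra]
    centers = [b.center for b in gen.bands]
    aligned = align_peak_tables(tables, centers, spectra=spectra)
    attr_cols = [c for c in aligned.columns if c not in ("class_id", "batch_id")]
    matrix = aligned[attr_cols].to_numpy(dtype=float)

    sample_ids = []
    counter: dict[int, int] = defaultdict(int)
    for s in spectra:
        counter[s.class_id] += 1
        sample_ids.append(f"{_CLASS_PREFIX[s.class_id]}{counter[s.class_id]}")

    dend = fuzzy.ward_dendrogram(matrix, object_ids=sample_ids)
    top_cut = dend.cut(2)

    norm = fuzzy.normalize(fuzzy.crisp_matrix(matrix, object_ids=sample_ids,
                                              attribute_names=attr_cols))
    Rt = fuzzy.transitive_closure(fuzzy.compatibility(norm))
    partitions = fuzzy.lambda_series(Rt)
    validity = fuzzy.validity_table(norm, partitions)

    return ClusterResult(
        dendrogram=dend,
        top_cut=top_cut,
        sample_ids=sample_ids,
        class_ids=np.array([s.class_id for s in spectra]),
        partitions=partitions,
        validity=validity,
        peak_matrix=aligned,
    )


# ---------------------------------------------------------------------------
# Classification experiment


@dataclass
class ClassificationResult:
    report: RecognitionReport      # all cells, train and test strata together
    regions: list[FeatureRegion]
    features: pd.DataFrame         # specimen-level feature matrix, both splits
    model: object                  # trained RBFModel


def _specimen_spectra(dataset: Sequence[Spectrum]) -> list[Spectrum]:
    """Baseline-corrected replicate averages, one spectrum per specimen."""
    groups: dict[int, list[Spectrum]] = defaultdict(list)
    for s in dataset:
        groups[s.specimen_id].append(s)
    out = []
    for sid in sorted(groups):
        out.append(baseline_correct(average_replicates(groups[sid])))
    return out


def run_classification_experiment(
    config: RunConfig | None = None,
    seed: int | None = None,
    dataset: Sequence[Spectrum] | None = None,
    leak_regions: bool = False,
) -> ClassificationResult:
    """The full recognition benchmark on one generated (or supplied) dataset.

    Steps: generate the stratified train/test cells, average the three
    replicate scans per specimen, baseline-correct, select feature regions on
    the training split only (unless ``leak_regions`` deliberately selects
    them on the test split, for protocol-violation tests), featurize both
    splits, train the RBF network on training features, and report per-cell
    recognition rates over every (class × batch × split) stratum.
    """
    config = config or RunConfig()
    if dataset is None:
        dataset = generate_dataset(
            config.generator, n_per_cell=config.n_per_cell,
            seed=seed if seed is not None else config.seed,
        )
    specimens = _specimen_spectra(dataset)

    selection_pool = [
        s for s in specimens if s.split == ("test" if leak_regions else "train")
    ]
    decomps = [
        dwt_multilevel(s.absorbance, wavelet=config.wavelet,
                       levels=config.levels, grid=s.grid)
        for s in selection_pool
    ]
    regions = select_regions(
        decomps,
        [s.class_id for s in selection_pool],
        region_counts=config.region_counts,
        smooth_window=config.smooth_window,
    )

    feats = featurize_batch(specimens, regions, wavelet=config.wavelet,
                            levels=config.levels)
    s_cols = [f"S{i + 1}" for i in range(5)]
    train_mask = feats["split"] == "train"
    model = train(
        feats.loc[train_mask, s_cols].to_numpy(),
        feats.loc[train_mask, "class_id"].tolist(),
        config.train,
    )
    report = evaluate(
        model,
        feats[s_cols].to_numpy(),
        feats["class_id"].tolist(),
        feats["batch_id"].tolist(),
        feats["split"].tolist(),
    )
    return ClassificationResult(
        report=report, regions=regions, features=feats, model=model
    )


# ---------------------------------------------------------------------------
# Multi-seed benchmark


@dataclass
class BenchmarkResult:
    per_seed: list[ClassificationResult]
    seeds: list[int]
    class_averages: dict[int, float]   # mean over seeds of per-class cell means
    min_cell_rate: dict[int, float]    # worst single cell per class, any seed
    summary: pd.DataFrame              # one row per seed x class


def benchmark(
    config: RunConfig | None = None, seeds: Sequence[int] = (1, 2, 3, 4, 5)
) -> BenchmarkResult:
    """Run the classification experiment over several seeds and pool rates."""
    config = config or RunConfig()
    per_seed = [run_classification_experiment(config, seed=s) for s in seeds]
    rows = []
    for s, res in zip(seeds, per_seed):
        for class_id, avg in res.report.class_averages.items():
            rows.append(dict(seed=s, class_id=class_id, avg_rate_pct=avg))
    summary = pd.DataFrame(rows)
    class_averages = {
        int(c): float(g["avg_rate_pct"].mean())
        for c, g in summary.groupby("class_id")
    }
    min_cell: dict[int, float] = {}
    for res in per_seed:
        cells = res.report.cell_rates
        for class_id, g in cells.groupby("class_id"):
            worst = float(g["rate_pct"].min())
            min_cell[int(class_id)] = min(min_cell.get(int(class_id), 100.0), worst)
    return BenchmarkResult(
        per_seed=per_seed,
        seeds=list(seeds),
        class_averages=class_averages,
        min_cell_rate=min_cell,
        summary=summary,
    )
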