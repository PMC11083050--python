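"""End-to-end orchestration: simulate/read -> calibrate -> segment ->
extract -> preprocess -> features -> evaluate.

Stages communicate through files (ENVI pairs, CSV tables) so each can be
re-run in isolation, and every run is a pure function of its configuration
and seed.  :func:`simulate_and_extract` is the in-memory shortcut used for
benchmarks: it renders each scan, calibrates and segments it, and returns
the pooled per-seed spectra table without touching disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ReferenceFrames, calibrate
from .chemometrics import sfs_select
from .classify import (
    ClassifierSpec,
    EvalReport,
    default_specs,
    evaluate_repeated_split,
    pca_feature_extractor,
)
from .envi import read_envi
from .preprocessing import PreprocessConfig, preprocess_pipeline
from .segmentation import SpectraTable, background_mask, extract_mean_spectra, label_seeds
from .synthetic import (
    SceneConfig,
    TruthManifest,
    default_wavelength_axis,
    generate_dataset,
    make_signatures,
    render_scan,
)

logger = logging.getLogger("milletspec")

__all__ = ["RunConfig", "run", "process_dataset", "simulate_and_extract", "evaluate_table"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "milletspec_run"
    dataset_dir: str | None = None  # None -> simulate into out_dir/dataset
    n_cultivars: int = 10
    scans_per_cultivar: int = 10
    separation: float = 0.01
    noise_sd: float = 5.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    feature_mode: str = "pca"  # full_band | pca | sfs:<k>
    pca_components: int = 2
    classifiers: list = field(default_factory=default_specs)
    test_fraction: float = 0.2
    repeats: int = 5
    rng_seed: int = 0
    mask_band_nm: float = 1050.0
    mask_method: str = "otsu"
    min_area: int = 10
    connectivity: int = 8

    def __post_init__(self) -> None:
        mode = self.feature_mode
        if mode not in ("full_band", "pca") and not mode.startswith("sfs:"):
            raise ValueError(f"feature_mode must be full_band, pca or sfs:<k>, got '{mode}'")
        if mode.startswith("sfs:"):
            k = int(mode.split(":", 1)[1])
            if k < 1:
                raise ValueError("sfs:<k> requires k >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        kwargs = dict(mapping)
        if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
            kwargs["preprocess"] = PreprocessConfig.from_mapping(kwargs["preprocess"])
        if "classifiers" in kwargs:
            kwargs["classifiers"] = [
                c if isinstance(c, ClassifierSpec) else ClassifierSpec(**c)
                for c in kwargs["classifiers"]
            ]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            return str(obj)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _process_scan(raw, white, dark, cultivar, scan_id, cfg: RunConfig) -> SpectraTable:
    refl = calibrate(raw, ReferenceFrames(white=white, dark=dark))
    mask, _ = background_mask(refl, band_nm=cfg.mask_band_nm, method=cfg.mask_method)
    labelmap = label_seeds(mask, connectivity=cfg.connectivity, min_area=cfg.min_area)
    return extract_mean_spectra(refl, labelmap, {"cultivar": cultivar, "scan_id": scan_id})


def process_dataset(manifest: TruthManifest | str | Path, cfg: RunConfig | None = None) -> SpectraTable:
    """Calibrate, segment and extract every scan listed in a manifest."""
    cfg = cfg or RunConfig()
    if not isinstance(manifest, TruthManifest):
        manifest = TruthManifest.from_csv(manifest)
    tables = []
    ref_cache: dict[tuple, tuple] = {}
    for rec in manifest.scans:
        try:
            key = (rec.white_header_path, rec.dark_header_path)
            if key not in ref_cache:
                ref_cache[key] = (read_envi(rec.white_header_path), read_envi(rec.dark_header_path))
            white, dark = ref_cache[key]
            raw = read_envi(rec.header_path)
            tables.append(_process_scan(raw, white, dark, rec.cultivar, rec.scan_id, cfg))
        except Exception as exc:
            raise RuntimeError(f"stage 'process' failed on scan '{rec.scan_id}': {exc}") from exc
    return SpectraTable.concat(tables)


def simulate_and_extract(
    n_cultivars: int = 10,
    scans_per_cultivar: int = 10,
    scene: SceneConfig | None = None,
    separation: float = 0.01,
    noise_sd: float = 5.0,
    rng_seed: int = 0,
    cfg: RunConfig | None = None,
) -> SpectraTable:
    """Render, calibrate and segment a whole synthetic dataset in memory."""
    cfg = cfg or RunConfig()
    scene = SceneConfig() if scene is None else scene
    axis = default_wavelength_axis()
    signatures = make_signatures(n_cultivars, axis, separation=separation, rng_seed=rng_seed)
    ss = np.random.SeedSequence(rng_seed)
    scan_seeds = [int(s) % (2**31) for s in ss.generate_state(n_cultivars * scans_per_cultivar)]

    tables, k = [], 0
    for sig in signatures:
        for rep in range(scans_per_cultivar):
            scan_id = f"{sig.cultivar_name}_{rep:02d}"
            raw, white, dark, _ = render_scan(
                sig, replace(scene, rng_seed=scan_seeds[k]), noise_sd=noise_sd
            )
            k += 1
            tables.append(_process_scan(raw, white, dark, sig.cultivar_name, scan_id, cfg))
    return SpectraTable.concat(tables)


def evaluate_table(table: SpectraTable, cfg: RunConfig) -> dict[str, EvalReport]:
    """Preprocess a spectra table and run the classifier bench on it."""
    pre = preprocess_pipeline(table, cfg.preprocess)
    extractor = None
    features = pre.spectra
    if cfg.feature_mode == "pca":
        extractor = pca_feature_extractor(cfg.pca_components)
    elif cfg.feature_mode.startswith("sfs:"):
        k = int(cfg.feature_mode.split(":", 1)[1])
        sel = sfs_select(pre, k=k, estimator=cfg.classifiers[0], rng_seed=cfg.rng_seed)
        logger.info(
            "SFS selected %d wavebands (%s nm), eliminating %.2f%% of features",
            k, sel.format_wavelengths(), sel.elimination_percent,
        )
        features = pre.spectra[:, sel.selected_band_indices]
    return evaluate_repeated_split(
        features,
        pre.labels,
        cfg.classifiers,
        test_fraction=cfg.test_fraction,
        repeats=cfg.repeats,
        base_seed=cfg.rng_seed,
        feature_extractor=extractor,
    )


def run(config: RunConfig) -> dict[str, EvalReport]:
    """Execute the full pipeline and serialize every intermediate.

    Writes the synthetic dataset (unless ``dataset_dir`` points at an
    existing one), the raw and preprocessed spectra tables, a summary table
    of train/test accuracy per classifier and per-class metric tables, plus
    a run log with the config hash and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run config hash %s, seed %d", config.config_hash(), config.rng_seed)

        if config.dataset_dir is None:
            dataset_dir = out / "dataset"
            logger.info("stage simulate -> %s", dataset_dir)
            manifest = generate_dataset(
                dataset_dir,
                n_cultivars=config.n_cultivars,
                scans_per_cultivar=config.scans_per_cultivar,
                rng_seed=config.rng_seed,
                separation=config.separation,
                noise_sd=config.noise_sd,
            )
        else:
            manifest = TruthManifest.from_csv(Path(config.dataset_dir) / "manifest.csv")

        logger.info("stage process: %d scans", len(manifest.scans))
        table = process_dataset(manifest, config)
        table.to_csv(out / "spectra.csv")

        logger.info("stage preprocess: %d spectra", table.n_rows)
        pre = preprocess_pipeline(table, config.preprocess)
        pre.to_csv(out / "spectra_preprocessed.csv")

        logger.info("stage evaluate: mode %s", config.feature_mode)
        reports = evaluate_table(table, config)

        summary = pd.DataFrame([r.summary_row() for r in reports.values()])
        summary.to_csv(out / "accuracy_summary.csv", index=False)
        for name, rep in reports.items():
            rep.per_class.to_csv(out / f"per_class_{name}.csv", index=False)
            pd.DataFrame(
                rep.confusion, index=rep.class_labels, columns=rep.class_labels
            ).to_csv(out / f"confusion_{name}.csv")
        logger.info("done: %s", ", ".join(f"{r.classifier} {r.test_mean:.2f}%" for r in reports.values()))
        return reports
    finally:
        logger.removeHandler(handler)
        handler.close()
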