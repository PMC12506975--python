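"""End-to-end study orchestration: cohort simulation -> dual reconstruction
-> vascular post-processing -> feature extraction -> selection -> CNN
train/test -> report.

All randomness flows from the single study seed through named substreams
(``numpy.random.SeedSequence([seed, ...])``), so a case can be recomputed in
isolation bit-identically, and a full re-run with the same config reproduces
the metrics exactly.  The default study keeps the full 512-element
photoacoustic aperture but reduces the ultrasound arm (4 emitters, every
second receiver) and samples at 20 MHz on 0.25-mm pixels, confining
quantitative analysis to the well-sampled central field of view -- a
fidelity/compute balance that keeps a 160-case cohort tractable on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnosis as dx
from .errors import StageError
from .geometry import assign_element_roles, build_grid, build_half_ring_geometry
from .pact_recon import das_unipolar
from .phantom_forward import (
    add_noise,
    forward_pa,
    forward_urct_frame,
    generate_breast_phantom,
    make_fluence,
    sample_scatterers,
)
from .tumor_features import (
    ALL_FEATURES,
    PACT_FEATURES,
    URCT_FEATURES,
    define_zones,
    extract_features,
)
from .urct_recon import log_compress, sa_compound_recon
from .vessel_postproc import (
    depth_compensate,
    detect_skin_surface,
    frangi_enhance,
    skeletonize_vessels,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "run_modality_ablation",
           "simulate_case", "case_seed"]


@dataclass
class StudyConfig:
    n_cases: int = 160
    malignant_fraction: float = 0.5
    seed: int = 1234
    # acquisition
    n_elements: int = 512
    n_emitters: int = 4
    pitch_mm: float = 0.25
    grid_width_mm: float = 120.0
    grid_depth_mm: float = 50.0
    grid_center_xy: tuple[float, float] = (0.0, -5.0)
    fs_MHz: float = 20.0
    c_mm_per_us: float = 1.52
    # quantitative analysis is confined to the well-sampled central FOV
    analysis_width_mm: float = 80.0
    analysis_depth_mm: float = 36.0
    snr_db: float = 30.0
    n_scatterers: int = 1200
    us_rx_stride: int = 2
    fluence_depth_ratio: float = 62.0
    # analysis
    halo_width_mm: float = 3.0
    train_fraction: float = 0.5
    modality: str = "combined"             # combined | pact | urct
    p_thresh: float = 0.01
    r_thresh: float = 0.85
    overlap_thresh: float = 0.75
    min_sensitivity: float = 0.95
    importance_repeats: int = 5
    hyperparams: dx.CNNHyperparams = field(default_factory=dx.CNNHyperparams)
    # archetype overrides: {'benign': ArchetypeParams, 'malignant': ...}
    archetypes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hyperparams"] = dataclasses.asdict(self.hyperparams)
        d["archetypes"] = {
            k: dataclasses.asdict(v) for k, v in self.archetypes.items()
        }
        return d


@dataclass
class StudyReport:
    config: StudyConfig
    feature_table: dx.FeatureTable
    selection: dx.SelectionResult | None
    model: dx.TrainedModel
    roc: dx.ROCResult
    importance: pd.Series
    metrics: dict
    pom: pd.DataFrame                      # mass_id, label, split, pom


def case_seed(study_seed: int, case_index: int, stream: str = "case") -> int:
    """Deterministic sub-seed for one case (independent of all other cases)."""
    offsets = {"case": 0, "noise_pa": 1, "noise_us": 2}
    ss = np.random.SeedSequence([study_seed, case_index, offsets[stream]])
    return int(ss.generate_state(1)[0] % (2**31))


def _case_labels(config: StudyConfig) -> list[str]:
    n_mal = int(round(config.n_cases * config.malignant_fraction))
    return ["malignant" if i < n_mal else "benign" for i in range(config.n_cases)]


def _analysis_grid(config: StudyConfig):
    top = config.grid_center_xy[1] + config.grid_depth_mm / 2.0
    return build_grid(
        config.analysis_width_mm, config.analysis_depth_mm, config.pitch_mm,
        (config.grid_center_xy[0], top - config.analysis_depth_mm / 2.0),
    )


def _geometry(config: StudyConfig):
    geom = build_half_ring_geometry(n_elements=config.n_elements)
    return assign_element_roles(geom, n_emitters=config.n_emitters)


def simulate_case(config: StudyConfig, case_index: int, label: str) -> dict:
    """Simulate, reconstruct and analyse one mass; returns feature row + images.

    Depends only on (config, case_index, label), never on other cases.
    """
    cid = f"case{case_index:04d}"
    grid = build_grid(config.grid_width_mm, config.grid_depth_mm,
                      config.pitch_mm, config.grid_center_xy)
    ana = _analysis_grid(config)
    row0 = int(round((config.grid_center_xy[1] + config.grid_depth_mm / 2
                      - (ana.center_xy[1] + ana.depth_mm / 2)) / config.pitch_mm))
    col0 = int(round((ana.center_xy[0] - ana.width_mm / 2
                      - (config.grid_center_xy[0] - config.grid_width_mm / 2))
                     / config.pitch_mm))

    def crop(a):
        return a[row0: row0 + ana.n_y, col0: col0 + ana.n_x]

    geom = _geometry(config)
    seed = case_seed(config.seed, case_index)
    try:
        phantom = generate_breast_phantom(
            grid, label, archetype_params=config.archetypes.get(label), seed=seed
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("phantom", cid, e) from e
    try:
        fluence = make_fluence("dark_field", config.fluence_depth_ratio,
                               grid.depth_mm)
        cd = forward_pa(phantom, fluence, geom, config.fs_MHz, config.c_mm_per_us)
        cd = add_noise(cd, config.snr_db,
                       seed=case_seed(config.seed, case_index, "noise_pa"),
                       columns=geom.receiver_idx)
        pa = das_unipolar(cd, geom, ana, apodization="cosine")
    except Exception as e:  # noqa: BLE001
        raise StageError("pact_recon", cid, e) from e
    try:
        skin = detect_skin_surface(pa)
        pa_comp = depth_compensate(pa, skin)
        enhanced = frangi_enhance(pa_comp)
        skeleton = skeletonize_vessels(enhanced)
    except Exception as e:  # noqa: BLE001
        raise StageError("vessel_postproc", cid, e) from e
    try:
        scat = sample_scatterers(phantom, config.n_scatterers)
        noise_seed = case_seed(config.seed, case_index, "noise_us")
        frames = []
        us_rx = geom.receiver_idx[::max(config.us_rx_stride, 1)]
        for k, e_idx in enumerate(geom.emitter_idx):
            f = forward_urct_frame(
                phantom, geom, int(e_idx), config.fs_MHz, config.c_mm_per_us,
                scatterers=scat, receivers=us_rx,
            )
            frames.append(add_noise(f, config.snr_db, seed=noise_seed + k,
                                    columns=us_rx))
        env = sa_compound_recon(frames, geom, ana,
                                rx_stride=config.us_rx_stride)
        us = log_compress(env)
    except Exception as e:  # noqa: BLE001
        raise StageError("urct_recon", cid, e) from e
    try:
        zones = define_zones(us, crop(phantom.tumor_mask), skin,
                             halo_width_mm=config.halo_width_mm,
                             breast_mask=crop(phantom.breast_mask))
        fv = extract_features(pa_comp, us, skeleton, zones,
                              mass_id=cid, label=label)
    except Exception as e:  # noqa: BLE001
        raise StageError("features", cid, e) from e
    return {"row": fv.as_dict(), "phantom": phantom, "pa": pa_comp, "us": us,
            "skeleton": skeleton, "zones": zones, "skin": skin}


def build_feature_table(config: StudyConfig, keep_images: bool = False):
    """Simulate the whole cohort and assemble the split-tagged feature table."""
    labels = _case_labels(config)
    rows = []
    artifacts = []
    for i, label in enumerate(labels):
        case = simulate_case(config, i, label)
        rows.append(case["row"])
        if keep_images:
            artifacts.append(case)
    df = pd.DataFrame(rows)
    df["split"] = _assign_split(df, config)
    table = dx.FeatureTable(df=df, feature_names=list(ALL_FEATURES))
    return (table, artifacts) if keep_images else (table, None)


def _assign_split(df: pd.DataFrame, config: StudyConfig) -> pd.Series:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 990_001]).generate_state(1)[0]
    )
    split = pd.Series("test", index=df.index)
    for _, idx in df.groupby("label").groups.items():
        idx = np.asarray(list(idx))
        perm = rng.permutation(idx.size)
        n_train = int(round(config.train_fraction * idx.size))
        split.loc[idx[perm[:n_train]]] = "train"
    return split


_MODALITY_SETS = {
    "combined": list(ALL_FEATURES),
    "pact": list(PACT_FEATURES),
    "urct": list(URCT_FEATURES),
}


def _fit_and_eval(table: dx.FeatureTable, config: StudyConfig, modality: str):
    names = _MODALITY_SETS[modality]
    sub = dx.FeatureTable(df=table.df.copy(), feature_names=names)
    # drop features the training rows cannot scale
    train = sub.rows("train")
    usable = [f for f in names if train[f].std(ddof=0) > 0]
    sub = dx.FeatureTable(df=sub.df, feature_names=usable)
    std = dx.standardize(sub)
    selection = dx.select_features(std, config.p_thresh, config.r_thresh,
                                   config.overlap_thresh)
    retained = selection.retained or usable  # fall back to all usable features
    model_seed = int(
        np.random.SeedSequence([config.seed, 990_002]).generate_state(1)[0]
        % (2**31)
    )
    model = dx.train_cnn(std, retained, config.hyperparams, seed=model_seed)
    pom_test = dx.predict_pom(model, std, split="test")
    roc = dx.roc_and_threshold(pom_test, std.y("test"), config.min_sensitivity)
    model.pom_threshold = roc.threshold
    importance = dx.permutation_importance(
        model, std, split="test", n_repeats=config.importance_repeats,
        seed=model_seed + 1,
    )
    pom_all = dx.predict_pom(model, std)
    pom_df = std.df[["mass_id", "label", "split"]].copy()
    pom_df["pom"] = pom_all
    stats99 = dx.confusion_interval_stats(roc.counts)
    metrics = {
        "modality": modality,
        "n_cases": int(len(std.df)),
        "n_train": int((std.df["split"] == "train").sum()),
        "n_test": int((std.df["split"] == "test").sum()),
        "features_retained": list(retained),
        "selection_fallback": not bool(selection.retained),
        "test_auc": roc.auc,
        "pom_threshold": roc.threshold,
        "test_sensitivity": roc.sensitivity,
        "test_specificity": roc.specificity,
        "sens_ci99": [stats99.sensitivity.ci_lower, stats99.sensitivity.ci_upper],
        "spec_ci99": [stats99.specificity.ci_lower, stats99.specificity.ci_upper],
        "confusion": dataclasses.asdict(roc.counts),
        "importance": {k: float(v) for k, v in importance.items()},
    }
    return StudyReport(config=config, feature_table=std, selection=selection,
                       model=model, roc=roc, importance=importance,
                       metrics=metrics, pom=pom_df)


def run_study(config: StudyConfig | None = None,
              out_dir: str | Path | None = None) -> StudyReport:
    """Run the full simulated study for one modality setting."""
    config = config or StudyConfig()
    table, _ = build_feature_table(config)
    report = _fit_and_eval(table, config, config.modality)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def run_modality_ablation(config: StudyConfig | None = None,
                          out_dir: str | Path | None = None) -> dict:
    """Train/test with PACT-only, URCT-only and combined features.

    The cohort is simulated once; the three arms share identical splits,
    scaling bases and model seeds, differing only in the candidate feature
    set.
    """
    config = config or StudyConfig()
    table, _ = build_feature_table(config)
    arms = {m: _fit_and_eval(table, config, m) for m in ("pact", "urct", "combined")}
    split_hash = hash(tuple(table.df["split"]))
    comparison = {
        "auc": {m: arms[m].metrics["test_auc"] for m in arms},
        "specificity": {m: arms[m].metrics["test_specificity"] for m in arms},
        "split_hash": {m: split_hash for m in arms},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, rep in arms.items():
            _write_report(rep, out / m)
        (out / "ablation.json").write_text(json.dumps(comparison, indent=2))
    return {"arms": arms, "comparison": comparison}


def _write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["mass_id", "label", "split"] + report.feature_table.feature_names
    report.feature_table.df[cols].to_csv(out_dir / "features.csv", index=False)
    report.pom.to_csv(out_dir / "pom.csv", index=False)
    (out_dir / "metrics.json").write_text(json.dumps(report.metrics, indent=2))
    lines = [
        "duotomo study report",
        f"cases: {report.metrics['n_cases']} "
        f"(train {report.metrics['n_train']} / test {report.metrics['n_test']})",
        f"modality: {report.metrics['modality']}",
        f"retained features: {', '.join(report.metrics['features_retained'])}",
        f"test AUC: {report.metrics['test_auc']:.3f}",
        f"POM threshold: {report.metrics['pom_threshold']:.4f}",
        f"test sensitivity: {report.metrics['test_sensitivity']:.3f}",
        f"test specificity: {report.metrics['test_specificity']:.3f}",
        "per-mass POM: see pom.csv",
    ]
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
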