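"""End-to-end pipeline orchestration with fixed on-disk contracts.

Stages (in order): ``simulate`` -> ``deconvolve`` -> ``segment`` ->
``margins`` -> ``morphometrics`` -> ``quantify`` -> ``cluster`` ->
``analyze`` -> ``report``.  Each stage reads the previous stage's artifacts
from the project directory and is deterministic given the project seed;
missing upstream artifacts fail with the name of the stage to run first.
Every excluded record is written once to ``exclusions.csv`` with a reason
code.

The project layout under ``out_dir``::

    config.yaml                 resolved configuration + seed
    cohort/{lesions,tls_truth,tumors_truth}.csv
    images/<lesion>_{ihc,he}.tiff (+ .png), annotations/<lesion>.geojson
    deconvolved/<lesion>_{eosin,hematoxylin}.tiff
    segmentation/<lesion>_fibrillary.tiff, classifier.pkl
    margins/bands.csv, margins/<tumor>_band.tiff
    morphometrics/metrics.csv
    quantified/{tls_records,tumor_records}.csv
    clustering/{pca_model,contributions,clusters,characterization,cluster_til}.csv,
               dendrogram.nwk
    report/{prevalence,table2_fixture}.csv
    pipeline.log, exclusions.csv
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify, clustering, geometry, morphometrics, prevalence, quantify
from .stains import HE_STAINS, separate_stains
from .stats import log_transform, fit_random_intercept_lmm
from .synth import CohortGenParams, build_scene, generate_cohort
from .synth.render import LABEL_CODES

__all__ = ["ProjectConfig", "run", "build_table2", "STAGES"]

STAGES = (
    "simulate",
    "deconvolve",
    "segment",
    "margins",
    "morphometrics",
    "quantify",
    "cluster",
    "analyze",
    "report",
)


@dataclass
class ProjectConfig:
    out_dir: str = "tmefib_project"
    seed: int = 0
    n_lesions: int = 30
    n_scenes: int = 6  # lesions rendered as images (tables cover all)
    image_size: int = 512
    pixel_size: float = 1.0  # um / px
    max_tumors_per_scene: int = 4
    max_tls_per_scene: int = 2
    band_width_um: float = geometry.STROMAL_BAND_UM
    proximity_cutoff_um: float = geometry.PROXIMITY_CUTOFF_UM
    retain_pcs: int = 7
    k_clusters: int = 3
    rf_trees: int = 60
    feature_scales: tuple = (1.0, 2.0, 4.0)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "feature_scales" in data:
            data["feature_scales"] = tuple(data["feature_scales"])
        return cls(**data)

    @property
    def root(self) -> Path:
        return Path(self.out_dir)


def _log(cfg, msg):
    line = f"{datetime.datetime.now().isoformat(timespec='seconds')} {msg}"
    print(line)
    with open(cfg.root / "pipeline.log", "a") as fh:
        fh.write(line + "\n")


def _exclude(cfg, record_id, reason):
    path = cfg.root / "exclusions.csv"
    new = not path.exists()
    with open(path, "a") as fh:
        if new:
            fh.write("record_id,reason\n")
        fh.write(f"{record_id},{reason}\n")


def _require(cfg, path, produced_by):
    p = cfg.root / path
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {path!r}; run stage {produced_by!r} first"
        )
    return p


def _write_tiff(path, arr, pixel_size):
    tifffile.imwrite(
        path,
        arr,
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        metadata={"unit": "um", "pixel_size_um": pixel_size},
    )


def _scene_lesions(lesions: pd.DataFrame, cfg) -> list:
    # render TLS-bearing lesions first so every stage has both kinds
    ordered = pd.concat(
        [lesions[lesions.any_tls == 1], lesions[lesions.any_tls == 0]]
    )
    return list(ordered.lesion_id.iloc[: cfg.n_scenes])


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: ProjectConfig):
    root = cfg.root
    for sub in ("cohort", "images", "annotations"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    params = CohortGenParams(n_lesions=cfg.n_lesions, seed=cfg.seed)
    lesions, tls, tumors = generate_cohort(params)
    lesions.to_csv(root / "cohort/lesions.csv", index=False)
    tls.to_csv(root / "cohort/tls_truth.csv", index=False)
    tumors.to_csv(root / "cohort/tumors_truth.csv", index=False)
    _log(cfg, f"simulate: {len(lesions)} lesions, {len(tls)} TLS, {len(tumors)} tumors")

    truth_counts = {}
    for i, lid in enumerate(_scene_lesions(lesions, cfg)):
        scene = build_scene(
            lid,
            tumors[tumors.lesion_id == lid].to_dict("records"),
            tls[tls.lesion_id == lid].to_dict("records"),
            size=cfg.image_size,
            pixel_size=cfg.pixel_size,
            seed=cfg.seed + 1000 + i,
            max_tumors=cfg.max_tumors_per_scene,
            max_tls=cfg.max_tls_per_scene,
        )
        _write_tiff(root / f"images/{lid}_ihc.tiff", scene.image_ihc, cfg.pixel_size)
        _write_tiff(root / f"images/{lid}_he.tiff", scene.image_he, cfg.pixel_size)
        _write_tiff(root / f"images/{lid}_truth.tiff", scene.truth_labels, cfg.pixel_size)
        try:
            import imageio.v3 as iio

            iio.imwrite(root / f"images/{lid}_ihc.png", scene.image_ihc)
            iio.imwrite(root / f"images/{lid}_he.png", scene.image_he)
        except Exception:
            pass
        scene.regions.save(root / f"annotations/{lid}.geojson")
        truth_counts[lid] = scene.truth_counts
    with open(root / "cohort/truth_counts.json", "w") as fh:
        json.dump(truth_counts, fh)
    _log(cfg, f"simulate: rendered {min(cfg.n_scenes, len(lesions))} scenes")


def stage_deconvolve(cfg: ProjectConfig):
    root = cfg.root
    _require(cfg, "cohort/lesions.csv", "simulate")
    (root / "deconvolved").mkdir(exist_ok=True)
    n = 0
    for he in sorted((root / "images").glob("*_he.tiff")):
        lid = he.name.replace("_he.tiff", "")
        img = tifffile.imread(he)
        channels = separate_stains(img, HE_STAINS)
        _write_tiff(
            root / f"deconvolved/{lid}_eosin.tiff",
            channels["eosin"].astype(np.float32),
            cfg.pixel_size,
        )
        _write_tiff(
            root / f"deconvolved/{lid}_hematoxylin.tiff",
            channels["hematoxylin"].astype(np.float32),
            cfg.pixel_size,
        )
        n += 1
    _log(cfg, f"deconvolve: {n} images, stains={HE_STAINS.names}")


def _train_project_classifier(cfg, eosin_paths):
    """One classifier per project, trained on the first scene's truth raster."""
    root = cfg.root
    lid = eosin_paths[0].name.replace("_eosin.tiff", "")
    truth = tifffile.imread(root / f"images/{lid}_truth.tiff")
    eosin = tifffile.imread(eosin_paths[0])
    # scribbles: truth classes mapped into the classifier vocabulary
    palette = np.zeros_like(truth)
    palette[truth == LABEL_CODES["background"]] = 1  # background
    palette[truth == LABEL_CODES["tumor"]] = 1  # treated as non-stromal background
    palette[truth == LABEL_CODES["tls"]] = 1
    palette[truth == LABEL_CODES["fibrillary_matrix"]] = 2
    palette[truth == LABEL_CODES["nuclei"]] = 3
    palette[truth == LABEL_CODES["mucin"]] = 4
    palette[truth == LABEL_CODES["amyloid"]] = 5
    scribbles = classify.LabelScribbles.from_label_image(
        palette, max_per_class=2000, seed=cfg.seed
    )
    scribbles.coords = {
        k: v for k, v in scribbles.coords.items() if len(v) >= classify.MIN_SCRIBBLE_PX
    }
    feats = classify.compute_feature_stack(eosin, cfg.feature_scales)
    clf = classify.train_classifier(
        feats, scribbles, seed=cfg.seed, n_estimators=cfg.rf_trees, scales=cfg.feature_scales
    )
    clf.save(root / "segmentation/classifier.pkl")
    return clf


def stage_segment(cfg: ProjectConfig):
    root = cfg.root
    _require(cfg, "deconvolved", "deconvolve")
    (root / "segmentation").mkdir(exist_ok=True)
    eosin_paths = sorted((root / "deconvolved").glob("*_eosin.tiff"))
    if not eosin_paths:
        raise FileNotFoundError("no deconvolved eosin channels; run stage 'deconvolve' first")
    clf = _train_project_classifier(cfg, eosin_paths)
    n_ok = 0
    for p in eosin_paths:
        lid = p.name.replace("_eosin.tiff", "")
        eosin = tifffile.imread(p)
        eligible, reasons = classify.qc_eligibility(eosin)
        if not eligible:
            _exclude(cfg, lid, "qc:" + "+".join(reasons))
            _log(cfg, f"segment: {lid} excluded ({reasons})")
            continue
        feats = classify.compute_feature_stack(eosin, cfg.feature_scales)
        _, labels, fib, area = classify.predict_maps(feats, clf, cfg.pixel_size)
        _write_tiff(root / f"segmentation/{lid}_fibrillary.tiff", fib.astype(np.uint8), cfg.pixel_size)
        n_ok += 1
    _log(cfg, f"segment: {n_ok}/{len(eosin_paths)} images segmented")


def stage_margins(cfg: ProjectConfig):
    root = cfg.root
    ann_dir = _require(cfg, "annotations", "simulate")
    (root / "margins").mkdir(exist_ok=True)
    rows = []
    for gj in sorted(ann_dir.glob("*.geojson")):
        regions = geometry.RegionSet.load(gj)
        lid = gj.stem
        tls_polys = [r.polygon for r in regions.by_role("tls")]
        stroma_mask = np.zeros((cfg.image_size, cfg.image_size), dtype=bool)
        for r in regions.by_role("stroma"):
            stroma_mask |= geometry.rasterize_region(r.polygon, stroma_mask.shape)
        for t in regions.by_role("tumor"):
            band, area = geometry.stromal_band(
                t.polygon, stroma_mask, cfg.pixel_size, cfg.band_width_um
            )
            prox, dist, _ = geometry.classify_proximity(
                t.polygon, tls_polys, cfg.pixel_size, cfg.proximity_cutoff_um
            )
            _write_tiff(
                root / f"margins/{t.region_id}_band.tiff",
                band.astype(np.uint8),
                cfg.pixel_size,
            )
            rows.append(
                {
                    "tumor_id": t.region_id,
                    "lesion_id": lid,
                    "band_area_um2": area,
                    "proximity": str(prox),
                    "distance_um": dist,
                }
            )
            if area == 0:
                _log(cfg, f"margins: warning, empty band for {t.region_id}")
    pd.DataFrame(rows).to_csv(root / "margins/bands.csv", index=False)
    _log(cfg, f"margins: {len(rows)} tumor bands")


def stage_morphometrics(cfg: ProjectConfig):
    root = cfg.root
    _require(cfg, "margins/bands.csv", "margins")
    _require(cfg, "segmentation", "segment")
    (root / "morphometrics").mkdir(exist_ok=True)
    bands = pd.read_csv(root / "margins/bands.csv")
    truth_tumors = pd.read_csv(_require(cfg, "cohort/tumors_truth.csv", "simulate"))
    phen = dict(zip(truth_tumors.tumor_id, truth_tumors.phenotype))
    rows = []
    from scipy import ndimage as ndi

    for _, rec in bands.iterrows():
        lid = rec["lesion_id"]
        fib_path = root / f"segmentation/{lid}_fibrillary.tiff"
        if not fib_path.exists():
            _exclude(cfg, rec["tumor_id"], "no_segmentation")
            continue
        fib = tifffile.imread(fib_path).astype(bool)
        band = tifffile.imread(root / f"margins/{rec['tumor_id']}_band.tiff").astype(bool)
        eosin = tifffile.imread(root / f"deconvolved/{lid}_eosin.tiff")
        if not band.any():
            _exclude(cfg, rec["tumor_id"], "empty_band")
            continue
        # each connected band component is one stromal region; combine per tumor
        lab, ncomp = ndi.label(band)
        parts = []
        for c in range(1, ncomp + 1):
            comp = lab == c
            if comp.sum() < 200:
                continue
            parts.append(
                morphometrics.compute_metrics(
                    fib & comp,
                    intensity=eosin,
                    roi_mask=comp,
                    pixel_size=cfg.pixel_size,
                    region_id=f"{rec['tumor_id']}_s{c}",
                )
            )
        if not parts:
            _exclude(cfg, rec["tumor_id"], "band_too_small")
            continue
        fm = morphometrics.combine_regions(parts)
        row = fm.as_dict()
        row["tumor_id"] = rec["tumor_id"]
        row["lesion_id"] = lid
        row["proximity"] = rec["proximity"]
        row["true_phenotype"] = phen.get(rec["tumor_id"])
        row["provenance"] = ";".join(fm.region_ids)
        rows.append(row)
    pd.DataFrame(rows).to_csv(root / "morphometrics/metrics.csv", index=False)
    _log(cfg, f"morphometrics: {len(rows)} tumors measured")


def stage_quantify(cfg: ProjectConfig):
    root = cfg.root
    ann_dir = _require(cfg, "annotations", "simulate")
    (root / "quantified").mkdir(exist_ok=True)
    tls_rows, tumor_rows = [], []
    for gj in sorted(ann_dir.glob("*.geojson")):
        lid = gj.stem
        img = tifffile.imread(root / f"images/{lid}_ihc.tiff")
        slide = quantify.AnnotatedSlide(img, geometry.RegionSet.load(gj), lesion_id=lid)
        tls_rows += [vars(r) for r in quantify.tls_properties(slide)]
        tumor_rows += [vars(r) for r in quantify.til_counts(slide)]
    pd.DataFrame(tls_rows).to_csv(root / "quantified/tls_records.csv", index=False)
    pd.DataFrame(tumor_rows).to_csv(root / "quantified/tumor_records.csv", index=False)
    _log(cfg, f"quantify: {len(tls_rows)} TLS, {len(tumor_rows)} tumors")


def stage_cluster(cfg: ProjectConfig):
    root = cfg.root
    path = _require(cfg, "morphometrics/metrics.csv", "morphometrics")
    (root / "clustering").mkdir(exist_ok=True)
    df = pd.read_csv(path)
    metric_cols = [m for m in morphometrics.METRIC_NAMES if m in df.columns]
    metrics = df.set_index("tumor_id")[metric_cols].dropna()
    if len(metrics) < max(cfg.k_clusters, 3):
        _log(cfg, "cluster: not enough complete rows; skipped")
        return
    model = clustering.fit_pca(metrics, standardize=True)
    k = min(cfg.k_clusters, len(metrics))
    fcm = clustering.hcpc(model, k=k, retain=cfg.retain_pcs, metrics=metrics)
    model.loadings.to_csv(root / "clustering/pca_model.csv")
    pd.DataFrame(
        {"explained_variance_ratio": model.explained_variance_ratio},
        index=model.loadings.columns,
    ).to_csv(root / "clustering/variance.csv")
    pd.concat(
        [clustering.variable_contributions(model, i).assign(pc=i) for i in (1, 2)]
    ).to_csv(root / "clustering/contributions.csv")
    fcm.labels.to_csv(root / "clustering/clusters.csv")
    fcm.characterization.to_csv(root / "clustering/characterization.csv", index=False)
    with open(root / "clustering/dendrogram.nwk", "w") as fh:
        fh.write(clustering.linkage_to_newick(fcm.linkage, fcm.labels.index))
    # TIL comparison needs the quantified tumors
    tq = root / "quantified/tumor_records.csv"
    if tq.exists():
        tils = pd.read_csv(tq).set_index("tumor_id")["til_count"]
        common = fcm.labels.index.intersection(tils.index)
        if len(common) >= 4:
            clustering.cluster_til_comparison(
                tils.loc[common], fcm.labels.loc[common]
            ).to_csv(root / "clustering/cluster_til.csv", index=False)
    _log(
        cfg,
        f"cluster: k={k}, retained {fcm.retained} PCs "
        f"({fcm.cumulative_variance:.1%} cumulative variance)",
    )


def stage_analyze(cfg: ProjectConfig):
    root = cfg.root
    path = _require(cfg, "cohort/lesions.csv", "simulate")
    (root / "report").mkdir(exist_ok=True)
    lesions = pd.read_csv(path)
    prevalence.prevalence_table(lesions).to_csv(root / "report/prevalence.csv", index=False)
    build_table2().to_csv(root / "report/table2_fixture.csv", index=False)
    # stage -> TIL mixed model on the simulated cohort (TLS-bearing lesions)
    tumors = pd.read_csv(root / "cohort/tumors_truth.csv")
    sub = tumors[tumors.proximity.isin(["proximal"])].copy()
    if sub.lesion_id.nunique() >= 2:
        y = log_transform(sub.til_count.to_numpy())
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "primary_stage": (sub.nearest_tls_stage == "primary").astype(float),
            }
        )
        fit = fit_random_intercept_lmm(y, X, sub.lesion_id.to_numpy())
        with open(root / "report/stage_effect_lmm.txt", "w") as fh:
            fh.write(fit.summary() + "\n")
        _log(
            cfg,
            f"analyze: stage effect beta={fit.params['primary_stage']:.3f} "
            f"p={fit.pvalues['primary_stage']:.3g}",
        )
    _log(cfg, "analyze: prevalence tables written")


def stage_report(cfg: ProjectConfig):
    root = cfg.root
    _require(cfg, "report/prevalence.csv", "analyze")
    manifest = {}
    for sub in ("cohort", "quantified", "morphometrics", "clustering", "report"):
        d = root / sub
        if d.exists():
            manifest[sub] = sorted(p.name for p in d.iterdir())
    with open(root / "report/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    _log(cfg, "report: manifest written")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "deconvolve": stage_deconvolve,
    "segment": stage_segment,
    "margins": stage_margins,
    "morphometrics": stage_morphometrics,
    "quantify": stage_quantify,
    "cluster": stage_cluster,
    "analyze": stage_analyze,
    "report": stage_report,
}


def run(stage: str, cfg: ProjectConfig):
    """Run one stage or ``all`` in order; config + seed recorded on disk."""
    cfg.root.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.root / "config.yaml")
    if stage == "all":
        for s in STAGES:
            _STAGE_FUNCS[s](cfg)
    elif stage in _STAGE_FUNCS:
        _STAGE_FUNCS[stage](cfg)
    else:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")


def build_table2(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Lesion-level prevalence table (packaged cohort fixture by default)."""
    if df is None:
        df = prevalence.load_table1()
    return prevalence.prevalence_table(df)
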