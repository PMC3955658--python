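"""End-to-end analysis: simulate or load, preprocess, ReHo, group statistics.

:func:`run_pipeline` chains the stages with a single configuration object
and writes every artifact with a provenance sidecar (configuration hash,
seed, package version).  All numeric outputs are deterministic functions of
the configuration, so one configuration run twice yields byte-identical
numeric artifacts; wall-clock information goes only to the log file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .mesh import (SurfaceMesh, build_icosphere, build_neighborhoods,
                   calibrate_smoothing_iterations, smooth_on_surface)
from .preprocess import PreprocessParams, SurfaceBold, preprocess_surface
from .reho import global_mean_reho, extract_cluster_mean, reho_surface
from .simulate import (Cohort, EffectROI, SubjectData, SubjectRecord,
                       SyntheticSpec, default_effect_roi, simulate_cohort)
from .stats import (CohortDesign, cluster_fwe, cluster_table,
                    group_compare_scalars, pearson_corr, sex_ratio_chi2)

log = logging.getLogger("surfreho")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class SimulateConfig:
    icosphere_subdivisions: int = 3
    icosphere_radius: float = 100.0
    n_patients: int = 15
    n_controls: int = 15
    n_frames: int = 212
    effect: bool = True
    lam_patient: float = 0.15
    lam_control: float = 0.30
    roi_rings: int = 3


@dataclass
class AnalysisConfig:
    """All knobs of the end-to-end analysis; defaults are the study settings.

    ``simulate`` may be None when ``data_dir`` points at an on-disk cohort
    (a ``manifest.json`` as written by :func:`surfreho.simulate.write_cohort`).
    """

    output_dir: str = "surfreho_out"
    data_dir: str | None = None
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    n_drop: int = 5
    normalize_target: float = 10000.0
    band: tuple = (0.01, 0.1)
    detrend_order: int = 2
    head_radius: float = 50.0
    variants: tuple = ("ring1", "ring2")
    fwhm: float = 6.0
    p_form: float = 0.01
    alpha: float = 0.05
    n_perm: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name, v in (("p_form", self.p_form), ("alpha", self.alpha)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.fwhm < 0:
            raise ValueError("fwhm must be >= 0")
        if self.simulate is None and self.data_dir is None:
            raise ValueError("either simulate or data_dir must be given")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", "default")
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulate"})
        if sim is None:
            cfg.simulate = None
        elif sim != "default" and isinstance(sim, dict):
            cfg.simulate = SimulateConfig(**sim)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        if isinstance(cfg.variants, list):
            cfg.variants = tuple(cfg.variants)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("data_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# data acquisition

def _simulated_cohort(cfg: AnalysisConfig) -> tuple[Cohort, list]:
    sc = cfg.simulate
    mesh = build_icosphere(sc.icosphere_subdivisions, sc.icosphere_radius)
    rois = []
    if sc.effect:
        rois = [default_effect_roi(mesh, sc.lam_patient, sc.lam_control, rings=sc.roi_rings)]
    spec = SyntheticSpec(
        n_patients=sc.n_patients, n_controls=sc.n_controls,
        n_frames=sc.n_frames, effect_rois=rois, seed=cfg.seed,
    )
    return simulate_cohort(mesh, spec), rois


def load_cohort(data_dir) -> tuple[SurfaceMesh, list, pd.DataFrame, float]:
    """Load an on-disk cohort from its manifest (mesh, subjects, phenotype)."""
    data_dir = Path(data_dir)
    manifest = sio.read_json(data_dir / "manifest.json")
    mesh = sio.read_mesh(data_dir / manifest["mesh"])
    phenotype = pd.read_csv(data_dir / manifest["phenotype"])
    tr = float(manifest.get("tr", 2.0))
    subjects = []
    for entry in manifest["subjects"]:
        bold = SurfaceBold(sio.read_vertex_data(data_dir / entry["bold"]), tr)
        motion = sio.read_motion(data_dir / entry["motion"])
        wm, csf = sio.read_nuisance(data_dir / entry["nuisance"])
        rec = SubjectRecord(
            subject_id=entry["subject_id"],
            group=str(phenotype.set_index("subject_id").loc[entry["subject_id"], "group"]),
            age=0.0, sex="F", education=0.0, mcbbr=0.0,
        )
        subjects.append(SubjectData(rec, bold, motion, wm, csf))
    return mesh, subjects, phenotype, tr


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineResult:
    mesh: SurfaceMesh
    design: CohortDesign
    reho_maps: dict          # variant -> list of smoothed ReHoMap
    glm_reports: dict        # variant -> ClusterReport
    global_reho: pd.DataFrame
    cohort_table: pd.DataFrame
    correlation_tables: dict
    output_dir: Path
    roi_vertices: np.ndarray | None = None


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Execute the full analysis chain and write all artifacts.

    Stages: simulate-or-load, preprocess, ReHo per variant, surface
    smoothing, vertexwise ANCOVA with cluster-extent FWE correction, and the
    report (cohort table, cluster tables, correlation tables).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    stage = "setup"
    try:
        stage = "acquire"
        t0 = time.time()
        roi_vertices = None
        if config.simulate is not None:
            cohort, rois = _simulated_cohort(config)
            mesh, subjects, phenotype = cohort.mesh, cohort.subjects, cohort.phenotype
            if rois:
                roi_vertices = rois[0].vertices
        else:
            mesh, subjects, phenotype, _ = load_cohort(config.data_dir)
        log.info("acquire: %d subjects, %d vertices (%.1fs)",
                 len(subjects), mesh.n_vertices, time.time() - t0)

        stage = "preprocess"
        t0 = time.time()
        pp = PreprocessParams(
            n_drop=config.n_drop, normalize_target=config.normalize_target,
            band=tuple(config.band), detrend_order=config.detrend_order,
            head_radius=config.head_radius,
        )
        processed = []
        for subj in subjects:
            clean, info = preprocess_surface(subj.bold, subj.motion, subj.wm, subj.csf, pp)
            processed.append(clean)
        log.info("preprocess: order=%s (%.1fs)", info["order"], time.time() - t0)

        stage = "reho"
        t0 = time.time()
        n_iter = calibrate_smoothing_iterations(mesh, config.fwhm) if config.fwhm > 0 else 0
        reho_maps: dict = {}
        for variant in config.variants:
            nb = build_neighborhoods(mesh, variant)
            maps = []
            for clean in processed:
                m = reho_surface(clean, nb)
                m.values = smooth_on_surface(m.values, mesh, config.fwhm, n_iter=n_iter)
                m.smoothed_fwhm = config.fwhm
                maps.append(m)
            reho_maps[variant] = maps
        log.info("reho: variants=%s, smoothing iterations=%d (%.1fs)",
                 list(config.variants), n_iter, time.time() - t0)

        stage = "groupstats"
        t0 = time.time()
        design = CohortDesign(phenotype)
        glm_reports = {
            variant: cluster_fwe(
                maps, design, mesh, p_form=config.p_form, alpha=config.alpha,
                n_perm=config.n_perm, seed=config.seed,
            )
            for variant, maps in reho_maps.items()
        }
        log.info("groupstats: n_perm=%d (%.1fs)", config.n_perm, time.time() - t0)

        stage = "report"
        result = PipelineResult(
            mesh=mesh, design=design, reho_maps=reho_maps,
            glm_reports=glm_reports,
            global_reho=_global_reho_table(reho_maps, design),
            cohort_table=pd.DataFrame(), correlation_tables={},
            output_dir=outdir, roi_vertices=roi_vertices,
        )
        result.cohort_table = _cohort_table(design, result.global_reho)
        result.correlation_tables = _correlation_tables(result)
        write_report(result, config)
        return result
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    for h in list(log.handlers):  # one run-scoped file handler at a time
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


# ---------------------------------------------------------------------------
# report pieces

VARIANT_LABEL = {"ring1": "ReHo", "ring2": "ReHo2"}


def _global_reho_table(reho_maps: dict, design: CohortDesign) -> pd.DataFrame:
    rows = []
    for variant, maps in reho_maps.items():
        for sid, m in zip(design.table["subject_id"], maps):
            rows.append({
                "subject_id": sid,
                "variant": VARIANT_LABEL.get(variant, variant),
                "global_reho": global_mean_reho(m),
            })
    return pd.DataFrame(rows)


def _cohort_table(design: CohortDesign, global_reho: pd.DataFrame) -> pd.DataFrame:
    t = design.table
    pat = t[t["group"] == "patient"]
    con = t[t["group"] == "control"]

    def trow(label, col):
        tval, p = group_compare_scalars(design, t[col].to_numpy())
        return {
            "measure": label,
            "patients_mean": pat[col].mean(), "patients_sd": pat[col].std(ddof=1),
            "controls_mean": con[col].mean(), "controls_sd": con[col].std(ddof=1),
            "p": p, "test": "two-sample t",
        }

    rows = [
        trow("Age (years)", "age"),
        trow("Years of education", "education"),
        trow("mcBBR", "mcbbr"),
        trow("rmsFD (mm)", "rmsfd"),
    ]
    chi2, p = sex_ratio_chi2(design)
    sex = t["sex"].map({"M": 1, "F": 0}) if t["sex"].dtype == object else t["sex"]
    rows.insert(1, {
        "measure": "Gender (male proportion)",
        "patients_mean": sex[t["group"] == "patient"].mean(), "patients_sd": np.nan,
        "controls_mean": sex[t["group"] == "control"].mean(), "controls_sd": np.nan,
        "p": p, "test": "chi-square",
    })
    for label in sorted(global_reho["variant"].unique()):
        sub = global_reho[global_reho["variant"] == label]
        merged = t[["subject_id", "group"]].merge(sub, on="subject_id")
        vals = merged["global_reho"].to_numpy()
        tval, p = group_compare_scalars(design, vals)
        gm = merged.groupby("group")["global_reho"]
        rows.append({
            "measure": f"Global {label}",
            "patients_mean": gm.mean().get("patient", np.nan),
            "patients_sd": gm.std(ddof=1).get("patient", np.nan),
            "controls_mean": gm.mean().get("control", np.nan),
            "controls_sd": gm.std(ddof=1).get("control", np.nan),
            "p": p, "test": "two-sample t",
        })
    for label, col in (("Illness onset age", "onset_age"),
                       ("Illness duration (months)", "duration_months"),
                       ("HRSD", "hrsd")):
        if col in t.columns and t[col].notna().any():
            rows.append({
                "measure": label,
                "patients_mean": pat[col].mean(), "patients_sd": pat[col].std(ddof=1),
                "controls_mean": np.nan, "controls_sd": np.nan,
                "p": np.nan, "test": "",
            })
    return pd.DataFrame(rows)


def _correlation_tables(result: PipelineResult) -> dict:
    """Cluster-mean ReHo vs demographic/clinical variables, per variant."""
    out = {}
    t = result.design.table
    for variant, report in result.glm_reports.items():
        neg = report.significant_clusters("negative")
        rows = []
        if neg:
            cluster = neg[0]  # largest-extent / smallest corrected p
            means = np.array([
                extract_cluster_mean(m, cluster.vertices)
                for m in result.reho_maps[variant]
            ])
            pat = (t["group"] == "patient").to_numpy()
            pairs = [("age", t["age"].to_numpy(), slice(None)),
                     ("education", t["education"].to_numpy(), slice(None))]
            for col in ("onset_age", "duration_months", "hrsd"):
                if col in t.columns and t[col].notna().any():
                    pairs.append((col, t[col].to_numpy(), pat))
                else:
                    log.info("correlation table: column %s missing, row skipped", col)
            for name, vals, sel in pairs:
                x = np.asarray(vals, dtype=float)[sel]
                y = means[sel]
                try:
                    r, p = pearson_corr(x, y)
                except ValueError as exc:
                    log.info("correlation %s skipped: %s", name, exc)
                    continue
                rows.append({"variable": name, "r": r, "p": p, "n": int(np.isfinite(x).sum())})
        out[variant] = pd.DataFrame(rows, columns=["variable", "r", "p", "n"])
    return out


_CSV_FLOAT = "%.17g"


def write_report(result: PipelineResult, config: AnalysisConfig) -> None:
    """Write the cohort table, cluster tables, correlation tables and maps."""
    outdir = result.output_dir
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    sio.write_json(provenance, outdir / "provenance.json")
    result.cohort_table.to_csv(outdir / "cohort_table.csv", index=False,
                               float_format=_CSV_FLOAT)
    result.global_reho.to_csv(outdir / "global_reho.csv", index=False,
                              float_format=_CSV_FLOAT)
    report_json: dict = {"variants": {}, "thresholds": {
        "p_form": config.p_form, "alpha": config.alpha,
        "n_perm": config.n_perm, "fwhm": config.fwhm, "seed": config.seed,
    }}
    for variant, report in result.glm_reports.items():
        tab = cluster_table(report)
        tab.to_csv(outdir / f"clusters_{variant}.csv", index=False,
                   float_format=_CSV_FLOAT)
        result.correlation_tables[variant].to_csv(
            outdir / f"correlations_{variant}.csv", index=False,
            float_format=_CSV_FLOAT)
        stack = np.column_stack([m.values for m in result.reho_maps[variant]])
        sio.write_vertex_data(stack, outdir / f"reho_{variant}.txt")
        report_json["variants"][variant] = {
            "n_clusters": len(report.clusters),
            "n_significant_negative": len(report.significant_clusters("negative")),
            "n_significant_positive": len(report.significant_clusters("positive")),
            "warnings": report.warnings,
        }
    sio.write_json(report_json, outdir / "report.json")
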