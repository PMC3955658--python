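"""Synthetic resting-state cohorts with controllable local temporal coherence.

The generator emulates a typical 3 T acquisition (TR = 2 s, 212 volumes) and
a two-group case-control design.  Vertex ``v`` of subject ``i`` receives

    y_v(t) = lambda_v * s_{patch(v)}(t) + (1 - lambda_v) * eps_v(t),

where ``s_p`` is one shared AR(1) series per local patch (patches tile the
mesh at roughly two-ring scale), ``eps_v`` is independent AR(1) noise, and
the mixing weight ``lambda`` controls local temporal coherence: lambda = 0
gives independent noise (expected Kendall's W ~ 1/K), lambda = 1 identical
series (W = 1), and W increases monotonically in between.  Inside a
designated effect region lambda takes a group-specific value, so a patient
deficit in regional homogeneity is injected as lowered patch coherence.
Each series is z-scored and then mapped to a positive-mean intensity scale
so that global intensity normalization downstream is meaningful.

Motion is a 6-parameter random walk whose step scale sets the expected
framewise displacement; white-matter- and CSF-like nuisance series are
shared AR(1) signals weakly coupled into every vertex.  Covariates (age,
sex, education, a registration-cost proxy, clinical scores) are drawn from
distributions mirroring a mid-life depression cohort; clinical scores are
generated independent of the injected coherence effect.

Cohort generation is a pure function of (mesh, spec): the same spec
reproduces bit-identical data.  Per-subject generators are spawned from the
spec seed, so any subject can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, k_ring
from .preprocess import SurfaceBold, compute_rmsfd


@dataclass
class EffectROI:
    """A contiguous vertex set with group-specific coherence."""

    vertices: np.ndarray
    lam_patient: float
    lam_control: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        for lam in (self.lam_patient, self.lam_control):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("coherence lambda must lie in [0, 1]")


@dataclass
class CovariateModel:
    """Sampling distributions for the phenotype table.

    Defaults mirror a mid-life, mildly-moving cohort: age ~ N(34.4, 10.4)
    years, education ~ N(13.5, 3.0) years, registration-cost proxy
    (mcBBR-like) ~ N(0.6, 0.05), HRSD ~ N(20.2, 3.2) for patients, illness
    duration ~ Exponential(mean 6) months.  ``motion_severity`` is the
    random-walk step SD in mm, chosen to yield rmsFD near 0.14 mm.
    """

    age_mean: float = 34.4
    age_sd: float = 10.4
    education_mean: float = 13.5
    education_sd: float = 3.0
    mcbbr_mean: float = 0.60
    mcbbr_sd: float = 0.05
    motion_severity: float = 0.03
    hrsd_mean: float = 20.2
    hrsd_sd: float = 3.2
    duration_mean_months: float = 6.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    ``base_coherence`` is the background mixing weight lambda0; 0.55 puts
    the one-ring Kendall's W of interior vertices in the mid-0.6 range
    typical of real cortical data.  ``ar1`` is the lag-1 autocorrelation of
    both shared and private series.
    """

    n_patients: int = 33
    n_controls: int = 32
    n_frames: int = 212
    tr: float = 2.0
    ar1: float = 0.4
    base_coherence: float = 0.55
    effect_rois: list = field(default_factory=list)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    sex_ratio: float = 0.4
    nuisance_weight: float = 0.05
    baseline: float = 1000.0
    amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")
        if not 0.0 <= self.base_coherence <= 1.0:
            raise ValueError("base_coherence must lie in [0, 1]")


@dataclass
class SubjectRecord:
    """Phenotype of one subject; clinical fields are patient-only."""

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    education: float
    mcbbr: float
    hrsd: float | None = None
    onset_age: float | None = None
    duration_months: float | None = None


@dataclass
class SubjectData:
    record: SubjectRecord
    bold: SurfaceBold
    motion: np.ndarray
    wm: np.ndarray
    csf: np.ndarray


@dataclass
class Cohort:
    subjects: list
    phenotype: pd.DataFrame
    patch_labels: np.ndarray
    spec: SyntheticSpec
    mesh: SurfaceMesh


# ---------------------------------------------------------------------------
# building blocks

def _ar1(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """Stationary AR(1) series along the last axis, unit marginal variance."""
    n = shape[-1]
    innov = rng.standard_normal(shape)
    out = np.empty(shape)
    out[..., 0] = innov[..., 0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        out[..., t] = phi * out[..., t - 1] + scale * innov[..., t]
    return out


def tile_patches(mesh: SurfaceMesh, rng: np.random.Generator) -> np.ndarray:
    """Greedy two-ring tiling: per-vertex patch labels.

    Vertices are visited in a seeded random order; each unassigned vertex
    seeds a new patch absorbing the unassigned part of its two-ring.
    """
    labels = np.full(mesh.n_vertices, -1, dtype=np.int64)
    order = rng.permutation(mesh.n_vertices)
    next_label = 0
    for v in order:
        if labels[v] < 0:
            patch = k_ring(mesh, int(v), 2)
            free = patch[labels[patch] < 0]
            labels[free] = next_label
            next_label += 1
    return labels


def simulate_motion(n_frames: int, severity: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk 6-parameter motion trace.

    Translation steps have SD ``severity`` (mm); rotation steps have SD
    ``severity / 50`` (radians), so both contribute comparably to FD under
    the 50 mm head-radius convention.  ``severity = 0`` gives zero motion.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    steps = rng.standard_normal((n_frames, 6))
    steps[0] = 0.0
    steps[:, :3] *= severity
    steps[:, 3:] *= severity / 50.0
    return np.cumsum(steps, axis=0)


def _lambda_map(mesh: SurfaceMesh, spec: SyntheticSpec, group: str) -> np.ndarray:
    lam = np.full(mesh.n_vertices, spec.base_coherence)
    for roi in spec.effect_rois:
        v = roi.vertices
        if v.size and (v.min() < 0 or v.max() >= mesh.n_vertices):
            raise ValueError("effect ROI vertex index out of range")
        lam[v] = roi.lam_patient if group == "patient" else roi.lam_control
    return lam


def simulate_subject(
    mesh: SurfaceMesh,
    spec: SyntheticSpec,
    record: SubjectRecord,
    rng: np.random.Generator,
    patch_labels: np.ndarray | None = None,
) -> SubjectData:
    """Generate one subject's surface BOLD, motion and nuisance series."""
    if patch_labels is None:
        patch_labels = tile_patches(mesh, np.random.default_rng(spec.seed))
    n_patch = int(patch_labels.max()) + 1
    n = spec.n_frames
    shared = _ar1(rng, (n_patch, n), spec.ar1)
    noise = _ar1(rng, (mesh.n_vertices, n), spec.ar1)
    wm = _ar1(rng, (n,), spec.ar1)
    csf = _ar1(rng, (n,), spec.ar1)
    lam = _lambda_map(mesh, spec, record.group)[:, None]
    y = lam * shared[patch_labels] + (1.0 - lam) * noise
    y = y + spec.nuisance_weight * (0.5 * wm + 0.5 * csf)
    # per-vertex z-score, then map onto a positive intensity scale
    y = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
    y = spec.baseline + spec.amplitude * y
    motion = simulate_motion(n, spec.covariates.motion_severity, rng)
    bold = SurfaceBold(y, spec.tr)
    return SubjectData(record, bold, motion, wm, csf)


def _draw_record(i: int, group: str, spec: SyntheticSpec, rng: np.random.Generator) -> SubjectRecord:
    cov = spec.covariates
    age = float(np.clip(rng.normal(cov.age_mean, cov.age_sd), 18.0, 65.0))
    sex = "M" if rng.random() < spec.sex_ratio else "F"
    education = float(np.clip(rng.normal(cov.education_mean, cov.education_sd), 6.0, 22.0))
    mcbbr = float(np.clip(rng.normal(cov.mcbbr_mean, cov.mcbbr_sd), 0.3, 0.9))
    rec = SubjectRecord(
        subject_id=f"sub-{i + 1:03d}", group=group,
        age=age, sex=sex, education=education, mcbbr=mcbbr,
    )
    if group == "patient":
        rec.hrsd = float(np.clip(rng.normal(cov.hrsd_mean, cov.hrsd_sd), 8.0, 40.0))
        rec.duration_months = float(rng.exponential(cov.duration_mean_months))
        rec.onset_age = max(age - rec.duration_months / 12.0, 16.0)
    return rec


def simulate_cohort(mesh: SurfaceMesh, spec: SyntheticSpec) -> Cohort:
    """Generate the full cohort plus its phenotype table.

    Per-subject generators are spawned deterministically from ``spec.seed``;
    rmsFD in the phenotype table is computed from each subject's generated
    motion trace.
    """
    n_total = spec.n_patients + spec.n_controls
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(n_total + 2)
    patch_rng = np.random.default_rng(streams[0])
    cov_rng = np.random.default_rng(streams[1])
    patch_labels = tile_patches(mesh, patch_rng)

    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    subjects = []
    rows = []
    for i, group in enumerate(groups):
        record = _draw_record(i, group, spec, cov_rng)
        rng = np.random.default_rng(streams[i + 2])
        subj = simulate_subject(mesh, spec, record, rng, patch_labels)
        subjects.append(subj)
        rows.append(
            {
                "subject_id": record.subject_id,
                "group": record.group,
                "age": record.age,
                "sex": record.sex,
                "education": record.education,
                "mcbbr": record.mcbbr,
                "rmsfd": compute_rmsfd(subj.motion),
                "hrsd": record.hrsd,
                "onset_age": record.onset_age,
                "duration_months": record.duration_months,
            }
        )
    phenotype = pd.DataFrame(rows)
    return Cohort(subjects, phenotype, patch_labels, spec, mesh)


# ---------------------------------------------------------------------------
# on-disk cohorts

def write_cohort(cohort: Cohort, outdir, fmt: str = "text") -> dict:
    """Write per-subject files, the phenotype CSV and a manifest.

    ``fmt`` is ``"text"`` or ``"gifti"`` for the BOLD matrices.  Returns the
    manifest dict (also written as ``manifest.json``).
    """
    from pathlib import Path

    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".func.gii" if fmt == "gifti" else ".txt"
    manifest: dict = {"subjects": [], "tr": cohort.spec.tr, "format": fmt}
    sio.write_mesh(cohort.mesh, outdir / "mesh.txt")
    manifest["mesh"] = "mesh.txt"
    for subj in cohort.subjects:
        sid = subj.record.subject_id
        bold_path = outdir / f"{sid}_bold{ext}"
        sio.write_vertex_data(subj.bold.data, bold_path)
        sio.write_motion(subj.motion, outdir / f"{sid}_motion.txt")
        sio.write_nuisance(subj.wm, subj.csf, outdir / f"{sid}_nuisance.txt")
        manifest["subjects"].append(
            {
                "subject_id": sid,
                "bold": bold_path.name,
                "motion": f"{sid}_motion.txt",
                "nuisance": f"{sid}_nuisance.txt",
            }
        )
    cohort.phenotype.to_csv(outdir / "phenotype.csv", index=False)
    manifest["phenotype"] = "phenotype.csv"
    np.savetxt(outdir / "patch_labels.txt", cohort.patch_labels, fmt="%d")
    manifest["patch_labels"] = "patch_labels.txt"
    spec_echo = asdict(cohort.spec)
    spec_echo["effect_rois"] = [
        {"vertices": r.vertices.tolist(), "lam_patient": r.lam_patient,
         "lam_control": r.lam_control}
        for r in cohort.spec.effect_rois
    ]
    manifest["spec"] = spec_echo
    sio.write_json(manifest, outdir / "manifest.json")
    return manifest


def default_effect_roi(
    mesh: SurfaceMesh,
    lam_patient: float,
    lam_control: float,
    center: int | None = None,
    rings: int = 3,
) -> EffectROI:
    """A contiguous k-ring patch as the effect region.

    By default centered on a regular (maximum-degree) vertex, mimicking a
    single focal cortical region of reduced coherence in patients.
    """
    if center is None:
        deg = mesh.degrees
        center = int(np.flatnonzero(deg == deg.max())[0])
    return EffectROI(k_ring(mesh, center, rings), lam_patient, lam_control)
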