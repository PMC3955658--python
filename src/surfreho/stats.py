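"""Vertexwise group comparison with cluster-extent familywise-error control.

The group model is a main-effects ANCOVA: at each vertex the (smoothed)
ReHo value is regressed on ``[intercept | group | age, sex, education,
mcBBR, rmsFD]`` by ordinary least squares; the group coefficient's t-test
(df = N - 7 with the full covariate set) is the comparison.  Supra-threshold
vertices (uncorrected p below the cluster-forming threshold, 0.01 by
default) are grouped into sign-homogeneous connected components over mesh
edges, with extents measured both in vertices and in summed vertex area
(mm^2).

Familywise error across the surface is controlled by a Freedman-Lane
permutation scheme: ReHo maps are residualized against the nuisance
covariates, the residual rows are permuted across subjects, the covariate
fit is re-added, and the full model is refit; the maximum cluster extent
(area, pooled over both signs) per permutation forms the null distribution.
The corrected p-value of an observed cluster of extent ``e`` is
``(1 + #{perm max >= e}) / (n_perm + 1)``, which is valid (never
anti-conservative in expectation) by the inclusion of the observed
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .mesh import SurfaceMesh, vertex_areas

COVARIATE_COLUMNS = ("age", "sex", "education", "mcbbr", "rmsfd")


@dataclass
class CohortDesign:
    """Subject covariate table for the vertexwise ANCOVA.

    ``table`` must contain ``subject_id``, ``group`` (``patient`` /
    ``control``) and the covariate columns (age, sex, education, mcbbr,
    rmsfd); sex may be given as M/F strings or 0/1 codes.  Clinical columns
    (hrsd, onset_age, duration_months), when present, are available for
    correlation analyses but never enter the group model.
    """

    table: pd.DataFrame
    covariate_columns: tuple = COVARIATE_COLUMNS

    def __post_init__(self) -> None:
        required = {"subject_id", "group", *self.covariate_columns}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        groups = set(self.table["group"])
        if not groups <= {"patient", "control"}:
            raise ValueError(f"unknown group labels: {groups - {'patient', 'control'}}")
        modeled = self.table[list(self.covariate_columns)].drop(columns="sex", errors="ignore")
        if modeled.isna().any().any():
            raise ValueError("missing values in modeled covariate columns")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def group_indicator(self) -> np.ndarray:
        return (self.table["group"].to_numpy() == "patient").astype(np.float64)

    def design_matrix(self) -> tuple[np.ndarray, list]:
        cols = [np.ones(self.n_subjects), self.group_indicator]
        names = ["intercept", "group"]
        for c in self.covariate_columns:
            v = self.table[c]
            if c == "sex":
                v = v.map({"M": 1.0, "F": 0.0}) if v.dtype == object else v.astype(float)
            cols.append(np.asarray(v, dtype=np.float64))
            names.append(c)
        X = np.column_stack(cols)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in design matrix")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design matrix; columns: {names}")
        return X, names


@dataclass
class GlmResult:
    """Per-vertex group effect: coefficient, t, two-tailed p, df."""

    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    sigma2: np.ndarray


@dataclass
class Cluster:
    vertices: np.ndarray
    sign: str  # "positive" | "negative" (sign of the group coefficient)
    extent_vertices: int
    extent_area: float
    peak_t: float
    peak_vertex: int
    corrected_p: float | None = None
    significant: bool | None = None


@dataclass
class ClusterReport:
    clusters: list
    n_perm: int
    p_form: float
    alpha: float
    seed: int
    null_max_extents: np.ndarray
    warnings: list = field(default_factory=list)

    def significant_clusters(self, sign: str | None = None) -> list:
        out = [c for c in self.clusters if c.significant]
        if sign is not None:
            out = [c for c in out if c.sign == sign]
        return out


# ---------------------------------------------------------------------------
# GLM

def _fit_glm_stack(Y: np.ndarray, X: np.ndarray, group_col: int = 1) -> GlmResult:
    """OLS of each column of Y (subjects x vertices) on X; group-column test."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                          # (p, V)
    resid = Y - X @ beta
    sigma2 = np.sum(resid**2, axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[group_col, group_col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[group_col] / se
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    return GlmResult(coef=beta[group_col], t=t, p=pvals, df=df, sigma2=sigma2)


def stack_maps(maps) -> np.ndarray:
    """Stack per-subject ReHo maps (or arrays) into a subjects x V matrix."""
    rows = []
    for m in maps:
        rows.append(np.asarray(getattr(m, "values", m), dtype=np.float64).reshape(-1))
    return np.vstack(rows)


def fit_vertex_glm(maps, design: CohortDesign) -> GlmResult:
    """Vertexwise ANCOVA of ReHo maps on group plus nuisance covariates.

    Vertices where any subject's map is undefined (NaN) yield NaN results
    and never enter cluster formation.  Requires at least two subjects per
    group.
    """
    Y = stack_maps(maps)
    if Y.shape[0] != design.n_subjects:
        raise ValueError("number of maps does not match the design table")
    g = design.group_indicator
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    X, _ = design.design_matrix()
    valid = np.all(np.isfinite(Y), axis=0)
    out_coef = np.full(Y.shape[1], np.nan)
    out_t = np.full(Y.shape[1], np.nan)
    out_p = np.full(Y.shape[1], np.nan)
    out_s2 = np.full(Y.shape[1], np.nan)
    res = _fit_glm_stack(Y[:, valid], X)
    out_coef[valid], out_t[valid], out_p[valid], out_s2[valid] = (
        res.coef, res.t, res.p, res.sigma2,
    )
    return GlmResult(out_coef, out_t, out_p, res.df, out_s2)


# ---------------------------------------------------------------------------
# clusters

def form_clusters(
    result: GlmResult,
    mesh: SurfaceMesh,
    p_form: float = 0.01,
    areas: np.ndarray | None = None,
) -> list:
    """Sign-split connected components of supra-threshold vertices."""
    if result.p.shape[0] != mesh.n_vertices:
        raise ValueError("result vertex count does not match mesh")
    if not 0 < p_form < 1:
        raise ValueError("p_form must lie in (0, 1)")
    if areas is None:
        areas = vertex_areas(mesh)
    clusters: list = []
    with np.errstate(invalid="ignore"):
        supra = (result.p < p_form) & np.isfinite(result.coef)
    for sign, name in ((1.0, "positive"), (-1.0, "negative")):
        sel = supra & (np.sign(result.coef) == sign)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        sub = mesh.adjacency[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            tvals = result.t[members]
            peak = members[np.argmax(np.abs(tvals))]
            clusters.append(
                Cluster(
                    vertices=members,
                    sign=name,
                    extent_vertices=int(members.size),
                    extent_area=float(areas[members].sum()),
                    peak_t=float(result.t[peak]),
                    peak_vertex=int(peak),
                )
            )
    return clusters


def _max_extent(clusters) -> float:
    return max((c.extent_area for c in clusters), default=0.0)


def cluster_fwe(
    maps,
    design: CohortDesign,
    mesh: SurfaceMesh,
    p_form: float = 0.01,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterReport:
    """Cluster-extent FWE correction by Freedman-Lane permutation.

    The null distribution is the per-permutation maximum cluster area,
    pooled over both signs and the whole surface, so the corrected p-values
    control the familywise error of any supra-threshold cluster anywhere.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    warnings = []
    if 1.0 / (n_perm + 1) > alpha:
        warnings.append(
            f"n_perm={n_perm} cannot resolve alpha={alpha}: "
            f"minimum attainable corrected p is {1.0 / (n_perm + 1):.4g}"
        )
    Y = stack_maps(maps)
    if Y.shape[0] != design.n_subjects:
        raise ValueError("number of maps does not match the design table")
    X, _ = design.design_matrix()
    areas = vertex_areas(mesh)
    valid = np.all(np.isfinite(Y), axis=0)
    Yv = Y[:, valid]

    observed = fit_vertex_glm(maps, design)
    clusters = form_clusters(observed, mesh, p_form, areas)

    # reduced model: everything except the group column
    Z = np.delete(X, 1, axis=1)
    pz = np.linalg.pinv(Z)
    fitted = Z @ (pz @ Yv)
    resid = Yv - fitted

    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = np.full_like(Y, np.nan)
        Yb[:, valid] = fitted + resid[perm]
        res_b = _fit_glm_stack(Yb[:, valid], X)
        glm_b = GlmResult(
            coef=_scatter(res_b.coef, valid),
            t=_scatter(res_b.t, valid),
            p=_scatter(res_b.p, valid),
            df=res_b.df,
            sigma2=_scatter(res_b.sigma2, valid),
        )
        null_max[b] = _max_extent(form_clusters(glm_b, mesh, p_form, areas))

    for c in clusters:
        exceed = int(np.sum(null_max >= c.extent_area))
        c.corrected_p = (1.0 + exceed) / (n_perm + 1.0)
        c.significant = bool(c.corrected_p < alpha)
    clusters.sort(key=lambda c: (c.corrected_p, -c.extent_area))
    return ClusterReport(
        clusters=clusters, n_perm=n_perm, p_form=p_form, alpha=alpha,
        seed=seed, null_max_extents=null_max, warnings=warnings,
    )


def _scatter(vals: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.full(valid.shape[0], np.nan)
    out[valid] = vals
    return out


def cluster_table(report: ClusterReport) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": i + 1,
            "sign": c.sign,
            "extent_vertices": c.extent_vertices,
            "extent_area_mm2": c.extent_area,
            "peak_t": c.peak_t,
            "peak_vertex": c.peak_vertex,
            "corrected_p": c.corrected_p,
            "significant": c.significant,
        }
        for i, c in enumerate(report.clusters)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "sign", "extent_vertices", "extent_area_mm2",
            "peak_t", "peak_vertex", "corrected_p", "significant",
        ],
    )


# ---------------------------------------------------------------------------
# scalar comparisons and correlations

def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with its two-tailed t-approximation p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input to correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_compare_scalars(
    design: CohortDesign, values: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test of a per-subject scalar (pooled variance default)."""
    values = np.asarray(values, dtype=np.float64)
    g = design.group_indicator.astype(bool)
    a, b = values[g], values[~g]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.size > 1 and b.size > 1:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def sex_ratio_chi2(design: CohortDesign) -> tuple[float, float]:
    """Pearson chi-square test of the 2x2 group-by-sex table."""
    sex = design.table["sex"]
    sex = sex.map({"M": 1, "F": 0}) if sex.dtype == object else sex.astype(int)
    g = design.group_indicator.astype(int)
    table = pd.crosstab(g, sex).to_numpy()
    if table.shape != (2, 2):
        raise ValueError("need both sexes present in both groups")
    if (table == table[0:1]).all():  # identical rows -> chi2 exactly 0
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
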