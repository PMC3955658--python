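"""Functional preprocessing of BOLD series and motion-derived quantities.

The default chain reproduces a conventional resting-state pipeline operating
on already-realigned data: drop initial volumes, global-mean intensity
normalization (grand mean 10,000), nuisance regression (white-matter and CSF
mean series plus the Friston-24 motion expansion), 0.01-0.1 Hz band-pass
filtering, and removal of linear and quadratic trends.  Each step is a pure
function of its inputs; :func:`preprocess_surface` runs the configurable
chain and logs the executed order.

Quality-control summaries follow the framewise-displacement convention:
FD at frame t is the sum of absolute translation increments plus the head
radius (50 mm default) times the sum of absolute rotation increments, and
rmsFD is the root mean square of FD over the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import butter, filtfilt


@dataclass
class SurfaceBold:
    """Per-vertex BOLD time series: ``data`` is (vertices, frames)."""

    data: np.ndarray
    tr: float
    frames_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("SurfaceBold data must be (vertices, frames)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SurfaceBold data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class VolumeBold:
    """4-D volumetric BOLD: ``data`` is (x, y, z, frames)."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("VolumeBold data must be 4-D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial dimensions")


@dataclass
class RegressorMatrix:
    """Nuisance design block: ``values`` is (frames, p) with column labels."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not self.labels:
            self.labels = [f"reg{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressors must be finite")


def hstack_regressors(*blocks: RegressorMatrix) -> RegressorMatrix:
    vals = np.hstack([b.values for b in blocks])
    labels = [lab for b in blocks for lab in b.labels]
    return RegressorMatrix(vals, labels)


# ---------------------------------------------------------------------------
# individual steps

def drop_initial_volumes(bold: SurfaceBold, n_drop: int = 5) -> SurfaceBold:
    """Discard the first ``n_drop`` frames (scanner equilibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if bold.n_frames <= n_drop:
        raise ValueError(f"cannot drop {n_drop} of {bold.n_frames} frames")
    return SurfaceBold(bold.data[:, n_drop:], bold.tr, bold.frames_dropped + n_drop)


def intensity_normalize(bold: SurfaceBold, target: float = 10000.0) -> SurfaceBold:
    """Scale the whole 4-D series so its grand mean equals ``target``."""
    grand = float(bold.data.mean())
    if grand <= 0:
        raise ValueError("global mean must be positive for intensity normalization")
    return replace(bold, data=bold.data * (target / grand))


def friston24(motion: np.ndarray) -> RegressorMatrix:
    """Friston 24-parameter motion expansion.

    Columns 1-6 are the rigid-body parameters, 7-12 their one-frame lags
    (first row zero-padded), 13-24 the squares of both sets.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (frames, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    lagged = np.zeros_like(motion)
    lagged[1:] = motion[:-1]
    vals = np.hstack([motion, lagged, motion**2, lagged**2])
    par = [f"mp{i + 1}" for i in range(6)]
    labels = par + [f"{p}_lag" for p in par] + [f"{p}_sq" for p in par] + [
        f"{p}_lag_sq" for p in par
    ]
    return RegressorMatrix(vals, labels)


def nuisance_regress(bold: SurfaceBold, regressors: RegressorMatrix | None) -> SurfaceBold:
    """Per-vertex OLS removal of nuisance regressors, temporal means restored.

    The design is ``[intercept | regressors]``; residuals are orthogonal to
    every regressor column.  A rank-deficient design raises an error naming
    the collinear columns.
    """
    if regressors is None or regressors.values.shape[1] == 0:
        return replace(bold, data=bold.data.copy())
    R = regressors.values
    if R.shape[0] != bold.n_frames:
        raise ValueError("regressor rows must match BOLD frames")
    X = np.column_stack([np.ones(R.shape[0]), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, ["intercept"] + list(regressors.labels))
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, bold.data.T, rcond=None)
    resid = bold.data.T - X @ beta
    means = bold.data.mean(axis=1)
    return replace(bold, data=resid.T + means[:, None])


def _collinear_columns(X: np.ndarray, labels: list) -> list:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol] + [
        labels[j] for j in piv[len(diag):]
    ]


def bandpass(
    bold: SurfaceBold,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
    method: str = "butterworth",
) -> SurfaceBold:
    """Zero-phase band-pass filter of each vertex series.

    Default is a 4th-order Butterworth applied forward-backward
    (:func:`scipy.signal.filtfilt`); ``method="fft"`` uses an ideal
    brick-wall filter in the frequency domain instead.
    """
    nyquist = 0.5 / bold.tr
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high >= nyquist:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyquist} Hz")
    if method == "fft":
        freqs = np.fft.rfftfreq(bold.n_frames, d=bold.tr)
        spec = np.fft.rfft(bold.data, axis=1)
        keep = (freqs >= low) & (freqs <= high)
        spec[:, ~keep] = 0.0
        out = np.fft.irfft(spec, n=bold.n_frames, axis=1)
    elif method == "butterworth":
        wn = [max(low, 1e-6) / nyquist, high / nyquist]
        b, a = butter(order, wn, btype="bandpass")
        out = filtfilt(b, a, bold.data, axis=1)
    else:
        raise ValueError(f"unknown band-pass method {method!r}")
    return replace(bold, data=out)


def detrend(bold: SurfaceBold, order: int = 2) -> SurfaceBold:
    """Remove polynomial trends up to ``order`` (default linear + quadratic).

    Projects each vertex series onto the orthogonal complement of the
    polynomial basis {1, t, ..., t^order}; the residual is orthogonal to
    every basis function (and therefore zero-mean).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n = bold.n_frames
    if n <= order + 1:
        raise ValueError(f"need more than {order + 1} frames to detrend at order {order}")
    t = np.linspace(-1.0, 1.0, n)
    basis = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    out = bold.data - (bold.data @ q) @ q.T
    return replace(bold, data=out)


def compute_rmsfd(motion: np.ndarray, head_radius: float = 50.0) -> float:
    """Root-mean-square framewise displacement (mm) of a 6-parameter trace.

    FD_t = sum |Delta translation| + head_radius * sum |Delta rotation|,
    rotations in radians; the RMS runs over frames 2..end.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (frames, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    diff = np.abs(np.diff(motion, axis=0))
    fd = diff[:, :3].sum(axis=1) + head_radius * diff[:, 3:].sum(axis=1)
    return float(np.sqrt(np.mean(fd**2)))


def framewise_displacement(motion: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Per-transition FD series (length frames - 1)."""
    motion = np.asarray(motion, dtype=np.float64)
    diff = np.abs(np.diff(motion, axis=0))
    return diff[:, :3].sum(axis=1) + head_radius * diff[:, 3:].sum(axis=1)


def vol_to_surf(volume: VolumeBold, mesh) -> SurfaceBold:
    """Sample a 4-D volume at mesh vertices by trilinear interpolation.

    Vertex world coordinates are mapped through the inverse affine into
    voxel space; every vertex must fall inside the field of view.
    """
    inv = np.linalg.inv(volume.affine)
    world = np.column_stack([mesh.vertices, np.ones(mesh.n_vertices)])
    vox = (inv @ world.T)[:3]
    dims = np.array(volume.data.shape[:3], dtype=float)
    outside = np.any((vox < -1e-9) | (vox > (dims - 1)[:, None] + 1e-9), axis=0)
    if outside.any():
        bad = np.flatnonzero(outside)
        raise ValueError(
            f"{bad.size} vertices map outside the volume field of view "
            f"(first offenders: {bad[:10].tolist()})"
        )
    vox = np.clip(vox, 0, (dims - 1)[:, None])
    n_frames = volume.data.shape[3]
    out = np.empty((mesh.n_vertices, n_frames))
    for t in range(n_frames):
        out[:, t] = map_coordinates(volume.data[..., t], vox, order=1, mode="nearest")
    return SurfaceBold(out, volume.tr)


# ---------------------------------------------------------------------------
# chain

DEFAULT_ORDER = ("drop", "normalize", "nuisance", "bandpass", "detrend")


@dataclass
class PreprocessParams:
    n_drop: int = 5
    normalize_target: float = 10000.0
    band: tuple = (0.01, 0.1)
    detrend_order: int = 2
    head_radius: float = 50.0
    bandpass_method: str = "butterworth"
    order: tuple = DEFAULT_ORDER


def preprocess_surface(
    bold: SurfaceBold,
    motion: np.ndarray | None = None,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    params: PreprocessParams | None = None,
) -> tuple[SurfaceBold, dict]:
    """Run the configurable preprocessing chain on one subject.

    Motion and nuisance traces are trimmed in step with dropped frames.
    Nuisance regressors are additionally passed through the temporal
    operations that follow the regression in the chain (band-pass,
    detrending), so that the chain's final residuals stay orthogonal to the
    raw regressors despite the later filtering.  Returns the processed
    series and an info dict recording the executed step order and the rmsFD
    computed from the (trimmed) motion trace.
    """
    params = params or PreprocessParams()
    info: dict = {"order": list(params.order)}
    for step_idx, step in enumerate(params.order):
        if step == "drop":
            bold = drop_initial_volumes(bold, params.n_drop)
            if motion is not None:
                motion = np.asarray(motion)[params.n_drop:]
            if wm is not None:
                wm = np.asarray(wm)[params.n_drop:]
            if csf is not None:
                csf = np.asarray(csf)[params.n_drop:]
        elif step == "normalize":
            bold = intensity_normalize(bold, params.normalize_target)
        elif step == "nuisance":
            blocks = []
            if wm is not None and csf is not None:
                blocks.append(RegressorMatrix(np.column_stack([wm, csf]), ["wm", "csf"]))
            if motion is not None:
                blocks.append(friston24(motion))
            reg = hstack_regressors(*blocks) if blocks else None
            if reg is not None:
                reg = _filter_like_chain(reg, params, params.order[step_idx + 1:], bold.tr)
            bold = nuisance_regress(bold, reg)
        elif step == "bandpass":
            bold = bandpass(bold, *params.band, method=params.bandpass_method)
        elif step == "detrend":
            bold = detrend(bold, params.detrend_order)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    if motion is not None:
        info["rmsfd"] = compute_rmsfd(motion, params.head_radius)
    return bold, info


def _filter_like_chain(
    reg: RegressorMatrix, params: PreprocessParams, later_steps, tr: float
) -> RegressorMatrix:
    """Condition nuisance regressors on the chain's later temporal steps.

    Let O be the composition of the temporal operations applied to the data
    after the regression (band-pass, detrending).  Regressing on O^T x
    instead of x makes the chain's final series O r exactly orthogonal to
    the raw regressors x, since <O r, x> = <r, O^T x> = 0.  O^T is obtained
    by pushing the identity matrix through the same steps (each series
    operation acts on rows, so the result of applying O rowwise to I is
    O^T).  Without later temporal steps this is the identity.
    """
    temporal = [s for s in later_steps if s in ("bandpass", "detrend")]
    if not temporal:
        return reg
    n = reg.values.shape[0]
    carrier = SurfaceBold(np.eye(n), tr)
    for step in temporal:
        if step == "bandpass":
            carrier = bandpass(carrier, *params.band, method=params.bandpass_method)
        else:
            carrier = detrend(carrier, params.detrend_order)
    filtered = carrier.data @ reg.values  # carrier.data is O^T
    keep = filtered.std(axis=0) > 1e-12  # near-constant columns vanish
    return RegressorMatrix(filtered[:, keep], [l for l, k in zip(reg.labels, keep) if k])
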