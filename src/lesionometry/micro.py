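"""Per-voxel microstructure maps.

Tensor metrics (FA/MD/RD) are fitted to the low b-value shell by iteratively
weighted least squares on the log-signal; RISH features (per-order
spherical-harmonic signal energy) come from the high shell; total apparent
fibre density (AFD) and the number of fibre orientations (NuFO) come from
fibre-ODF spherical-harmonic coefficients, which are consumed (or phantom
generated), never deconvolved here.

Spherical harmonics use a real, even-order, orthonormal basis; the convention
is recorded on every coefficient map. RISH and AFD are invariant to the choice
among orthonormal real bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "GradientTable",
    "TensorMap",
    "ShCoeffMap",
    "sh_degrees",
    "n_coeffs",
    "real_sh_basis",
    "fibonacci_sphere",
    "hardi_scheme",
    "fit_tensor_wls",
    "tensor_scalars",
    "fit_sh",
    "synthesize_sh",
    "rish_features",
    "afd_total",
    "nufo",
]

B0_THRESHOLD = 50.0  # s/mm^2


@dataclass(frozen=True)
class GradientTable:
    """Acquisition scheme: one b-value (s/mm^2) and unit direction per volume."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(f"bvecs must be ({bvals.size}, 3), got {bvecs.shape}")
        if (bvals < 0).any():
            raise ValueError("negative b-values")
        dwi = bvals > B0_THRESHOLD
        if not (~dwi).any():
            raise ValueError("gradient table needs at least one b=0 volume")
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if norms.size and np.abs(norms - 1.0).max() > 1e-6:
            raise ValueError("gradient directions must be unit-norm where b > 0")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0s_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    def shells(self) -> np.ndarray:
        return np.unique(np.round(self.bvals[~self.b0s_mask], -1))

    def shell_mask(self, b: float, tol: float = 60.0) -> np.ndarray:
        return np.abs(self.bvals - b) <= tol


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def hardi_scheme(
    n_b0: int = 14, n_low: int = 30, n_high: int = 60,
    b_low: float = 1200.0, b_high: float = 2400.0,
) -> GradientTable:
    """Two-shell HARDI scheme (defaults: 14 b=0, 30 @ b=1200, 60 @ b=2400)."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_low, b_low), np.full(n_high, b_high)])
    bvecs = np.concatenate(
        [np.zeros((n_b0, 3)), fibonacci_sphere(n_low), fibonacci_sphere(n_high)]
    )
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# diffusion tensor


@dataclass
class TensorMap:
    """Per-voxel symmetric diffusion tensor and S0, with a QC mask flagging
    voxels whose non-positive signals were clamped before the log-fit."""

    tensors: np.ndarray  # (..., 3, 3) mm^2/s
    s0: np.ndarray
    mask: np.ndarray
    qc_clamped: np.ndarray

    @property
    def evals(self) -> np.ndarray:
        """Eigenvalues in non-increasing order, shape (..., 3)."""
        vals = np.linalg.eigvalsh(self.tensors)
        return vals[..., ::-1]

    @property
    def negative_eval_mask(self) -> np.ndarray:
        return (self.evals < 0).any(axis=-1) & self.mask


_DT_ORDER = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _tensor_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    cols = [np.ones_like(bvals)]
    for k, (i, j) in enumerate(_DT_ORDER):
        fac = 1.0 if i == j else 2.0
        cols.append(-bvals * fac * g[:, i] * g[:, j])
    return np.column_stack(cols)


def _coeffs_to_tensors(beta: np.ndarray) -> np.ndarray:
    out = np.zeros(beta.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_DT_ORDER):
        out[..., i, j] = beta[..., k + 1]
        out[..., j, i] = beta[..., k + 1]
    return out


def fit_tensor_wls(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    shell: float | None = None,
    n_iter: int = 2,
    tol: float = 1e-10,
) -> TensorMap:
    """Iteratively weighted least-squares tensor fit on the log-signal.

    An ordinary log-linear fit initializes the coefficients; each reweighting
    pass uses the squared predicted signal as weights (the variance model of
    log-transformed Rician-free data) and stops early when the largest
    coefficient change drops below ``tol``.

    Parameters
    ----------
    dwi : (..., n_volumes) signal
    shell : fit only volumes on this shell (plus b=0); default lowest shell.
    n_iter : reweighting passes after the initial OLS fit.
    """
    dwi = np.asarray(dwi, dtype=float)
    if shell is None:
        shells = gtab.shells()
        shell = float(shells[0]) if shells.size else 0.0
    use = gtab.b0s_mask | gtab.shell_mask(shell)
    bvals, bvecs = gtab.bvals[use], gtab.bvecs[use]
    if use.sum() < 7:
        raise ValueError("need >= 7 usable volumes (b=0 + shell) for a tensor fit")
    X = _tensor_design(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient tensor design (directions too degenerate)")

    spatial = dwi.shape[:-1]
    mask = np.ones(spatial, bool) if mask is None else np.asarray(mask, bool)
    S = dwi[..., use][mask]  # (nvox, m)
    floor = 1e-10
    clamped_vox = (S <= 0).any(axis=1)
    if clamped_vox.any():
        warnings.warn(
            f"{int(clamped_vox.sum())} voxels had non-positive signals clamped to {floor}",
            stacklevel=2,
        )
    y = np.log(np.clip(S, floor, None))

    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # OLS init, (nvox, 7)
    for _ in range(n_iter):
        w = np.exp(X @ beta.T).T ** 2  # (nvox, m) predicted-signal^2 weights
        A = np.einsum("mi,vm,mj->vij", X, w, X)
        b = np.einsum("mi,vm->vi", X, w * y)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new - beta).max()
        beta = new
        if delta < tol:
            break

    tensors = np.zeros(spatial + (3, 3))
    s0 = np.zeros(spatial)
    qc = np.zeros(spatial, bool)
    tensors[mask] = _coeffs_to_tensors(beta)
    s0[mask] = np.exp(beta[:, 0])
    qc[mask] = clamped_vox
    return TensorMap(tensors=tensors, s0=s0, mask=mask, qc_clamped=qc)


def tensor_scalars(tmap: TensorMap) -> dict:
    """FA, MD and RD maps from the tensor eigenvalues.

    MD = (l1+l2+l3)/3, RD = (l2+l3)/2,
    FA = sqrt(3/2) * ||l - MD|| / ||l||, defined as 0 for an all-zero tensor.
    Voxels outside the fit mask are NaN.
    """
    ev = tmap.evals
    md = ev.mean(axis=-1)
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    norm2 = (ev**2).sum(axis=-1)
    dev2 = ((ev - md[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    out = {"fa": fa, "md": md, "rd": rd}
    for key, vol in out.items():
        vol = vol.astype(float)
        vol[~tmap.mask] = np.nan
        out[key] = vol
    return out


# ---------------------------------------------------------------------------
# spherical harmonics


def sh_degrees(order: int) -> list[tuple[int, int]]:
    """(l, m) pairs of the real even-order basis up to ``order``."""
    if order < 0 or order % 2:
        raise ValueError("SH order must be even and non-negative")
    return [(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)]


def n_coeffs(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def _to_angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dirs = np.asarray(dirs, dtype=float)
    dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
    theta = np.arccos(np.clip(dirs[..., 2], -1.0, 1.0))
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    return theta, phi


def real_sh_basis(order: int, dirs: np.ndarray, convention: str = "descoteaux07") -> np.ndarray:
    """Real, even-order, orthonormal SH design matrix, shape (n_dirs, n_coeffs).

    m < 0 rows use sqrt(2) * (-1)^m Im(Y_l^|m|), m = 0 uses Y_l^0, m > 0 uses
    sqrt(2) * (-1)^m Re(Y_l^m). Any orthonormal real basis yields identical
    RISH energies and AFD; the convention flag is carried so files written by
    other tools can be matched.
    """
    if convention != "descoteaux07":
        raise ValueError(f"unsupported SH convention {convention!r}")
    theta, phi = _to_angles(dirs)
    cols = []
    for l, m in sh_degrees(order):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * (-1) ** m * y.imag)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1) ** m * y.real)
    return np.column_stack(cols)


@dataclass
class ShCoeffMap:
    """Real even-order SH coefficients, last axis ordered as ``sh_degrees``."""

    coeffs: np.ndarray  # (..., n_coeffs)
    order: int
    convention: str = "descoteaux07"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        expected = n_coeffs(self.order)
        if self.coeffs.shape[-1] != expected:
            raise ValueError(
                f"order {self.order} needs {expected} coefficients, got "
                f"{self.coeffs.shape[-1]}"
            )

    def degree_index(self, ell: int) -> np.ndarray:
        return np.array([i for i, (l, _) in enumerate(sh_degrees(self.order)) if l == ell])


def fit_sh(signal: np.ndarray, dirs: np.ndarray, order: int) -> ShCoeffMap:
    """Least-squares projection of per-direction signal onto the real even basis."""
    signal = np.asarray(signal, dtype=float)
    B = real_sh_basis(order, dirs)
    if B.shape[0] < B.shape[1]:
        raise ValueError(
            f"under-determined SH fit: {B.shape[0]} directions for {B.shape[1]} coefficients"
        )
    flat = signal.reshape(-1, B.shape[0])
    coeffs = np.linalg.lstsq(B, flat.T, rcond=None)[0].T
    return ShCoeffMap(coeffs.reshape(signal.shape[:-1] + (B.shape[1],)), order)


def synthesize_sh(shmap: ShCoeffMap, dirs: np.ndarray) -> np.ndarray:
    B = real_sh_basis(shmap.order, dirs, shmap.convention)
    return shmap.coeffs @ B.T


def rish_features(shmap: ShCoeffMap, ell: int) -> np.ndarray:
    """RISH_l = sum_m c_lm^2 — the rotation-invariant signal energy at order l."""
    if ell % 2:
        raise ValueError("RISH features are defined for even orders only")
    if ell > shmap.order:
        raise ValueError(f"order {ell} exceeds fitted order {shmap.order}")
    idx = shmap.degree_index(ell)
    return (shmap.coeffs[..., idx] ** 2).sum(axis=-1)


def afd_total(fodf: ShCoeffMap) -> np.ndarray:
    """Total apparent fibre density: the fODF integral over the sphere,
    which for an orthonormal real basis is c00 * sqrt(4*pi)."""
    return fodf.coeffs[..., 0] * np.sqrt(4.0 * np.pi)


# ---------------------------------------------------------------------------
# fODF peaks


def _default_sphere() -> tuple[np.ndarray, list[np.ndarray]]:
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=3)  # 642 vertices
    verts = np.asarray(mesh.vertices, dtype=float)
    neighbors: list[set] = [set() for _ in range(len(verts))]
    for a, b, c in np.asarray(mesh.faces):
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    return verts, [np.fromiter(s, dtype=int) for s in neighbors]


_SPHERE_CACHE: tuple | None = None


def nufo(
    fodf: ShCoeffMap,
    relative_threshold: float = 0.1,
    min_separation_deg: float = 25.0,
    sphere: tuple | None = None,
) -> np.ndarray:
    """Number of distinct fODF peaks per voxel.

    Peaks are local maxima of the fODF on an icosphere tessellation with
    amplitude at least ``relative_threshold`` times the voxel's maximum,
    greedily merged when closer than ``min_separation_deg`` (antipodal
    directions count as one orientation). An all-zero or non-positive fODF
    has zero peaks.
    """
    if not 0 < relative_threshold < 1:
        raise ValueError("relative peak threshold must lie in (0, 1)")
    if not np.isfinite(fodf.coeffs).all():
        raise ValueError("non-finite fODF coefficients")
    global _SPHERE_CACHE
    if sphere is None:
        if _SPHERE_CACHE is None:
            _SPHERE_CACHE = _default_sphere()
        sphere = _SPHERE_CACHE
    verts, neighbors = sphere
    if len(verts) < 362:
        raise ValueError("sphere tessellation must have >= 362 vertices")
    B = real_sh_basis(fodf.order, verts, fodf.convention)
    flat = fodf.coeffs.reshape(-1, fodf.coeffs.shape[-1])
    amp = flat @ B.T  # (nvox, nverts)
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    counts = np.zeros(flat.shape[0], dtype=int)
    for v in range(flat.shape[0]):
        f = amp[v]
        fmax = f.max()
        if fmax <= 0:
            continue
        is_peak = np.array(
            [f[i] >= f[nb].max() and f[i] >= relative_threshold * fmax
             for i, nb in enumerate(neighbors)]
        )
        order = np.argsort(f[is_peak])[::-1]
        cand = verts[is_peak][order]
        kept: list[np.ndarray] = []
        for d in cand:
            if all(abs(d @ k) < cos_sep for k in kept):
                kept.append(d)
        counts[v] = len(kept)
    return counts.reshape(fodf.coeffs.shape[:-1])
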