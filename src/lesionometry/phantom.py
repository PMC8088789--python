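"""Synthetic subjects with known ground truth.

Generates voxel grids, streamline bundles, focal lesions, diffusion-weighted
signals, scalar microstructure maps and cohort tables so that every downstream
stage — lesion-interaction measures, factor reduction, screening statistics —
can be tested against analytically known answers.

Every generator is a pure function of its spec and seed: the same inputs give
bit-identical outputs. Cohort generation uses one RNG stream per subject,
derived from ``(seed, subject index)``, so per-subject data do not depend on
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Bundle, VoxelGrid

__all__ = [
    "BundleDescriptor",
    "LesionDescriptor",
    "TissueParams",
    "PhantomSpec",
    "Coupling",
    "MeasureSim",
    "CohortSpec",
    "make_bundle",
    "make_lesion_mask",
    "make_brain_mask",
    "make_scalar_maps",
    "make_dwi",
    "make_cohort",
    "make_synthetic_measures",
    "default_phantom_spec",
]

# The seven per-voxel metrics carried by scalar maps, in reporting order.
METRICS = ("fa", "md", "rd", "afd", "rish0", "rish2", "nufo")


@dataclass(frozen=True)
class BundleDescriptor:
    """Geometry of one synthetic tract.

    control_points : (k, 3) world-mm polyline the tube follows
    radius : tube radius in mm (per-streamline lateral offsets are clipped to it)
    n_streamlines : streamlines generated for the bundle
    dispersion : sd (mm) of the Gaussian lateral offset; 0 collapses the
        bundle onto the centerline
    """

    control_points: tuple
    radius: float = 4.0
    n_streamlines: int = 2000
    dispersion: float = 1.0


@dataclass(frozen=True)
class LesionDescriptor:
    """Ellipsoidal focal lesion: centre (mm) and per-axis radii (mm)."""

    center: tuple
    radii: tuple

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"lesion radii must be positive, got {self.radii}")


@dataclass(frozen=True)
class TissueParams:
    """Lesion-free metric baselines and multiplicative lesion effects.

    Lesions depress FA, AFD and the RISH energies and elevate MD/RD,
    mirroring the demyelination-like contrast of white-matter lesions.
    Diffusivities are in mm^2/s.
    """

    baseline: dict = field(
        default_factory=lambda: {
            "fa": 0.70,
            "md": 0.80e-3,
            "rd": 0.45e-3,
            "afd": 0.60,
            "rish0": 6.0,
            "rish2": 2.0,
            "nufo": 1.0,
        }
    )
    lesion_multiplier: dict = field(
        default_factory=lambda: {
            "fa": 0.60,
            "md": 1.60,
            "rd": 1.80,
            "afd": 0.55,
            "rish0": 0.70,
            "rish2": 0.50,
            "nufo": 0.80,
        }
    )
    # single-tensor forward model for DWI
    axial_diffusivity: float = 1.7e-3
    radial_diffusivity: float = 0.3e-3
    isotropic_diffusivity: float = 0.8e-3
    s0: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject."""

    shape: tuple = (40, 40, 40)
    voxel_size: float = 2.0
    bundles: dict = field(default_factory=dict)  # name -> BundleDescriptor
    lesions: tuple = ()
    tissue: TissueParams = field(default_factory=TissueParams)
    noise_sd: float = 0.0
    seed: int = 0

    def grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.shape, self.voxel_size)


def default_phantom_spec(seed: int = 0, n_streamlines: int = 2000) -> PhantomSpec:
    """A study-like subject: 2 mm isotropic grid, paired and commissural
    bundles of 2000 streamlines, and focal ellipsoidal lesions."""
    shape = (40, 40, 40)
    vs = 2.0
    hi = (np.array(shape) - 1) * vs  # world extent
    mid = hi / 2
    bundles = {
        "genu": BundleDescriptor(
            control_points=((10.0, mid[1] + 20, mid[2]), (hi[0] - 10, mid[1] + 20, mid[2])),
            n_streamlines=n_streamlines,
        ),
        "slf1_left": BundleDescriptor(
            control_points=((mid[0] - 20, 10.0, mid[2]), (mid[0] - 20, hi[1] - 10, mid[2])),
            n_streamlines=n_streamlines,
        ),
        "slf1_right": BundleDescriptor(
            control_points=((mid[0] + 20, 10.0, mid[2]), (mid[0] + 20, hi[1] - 10, mid[2])),
            n_streamlines=n_streamlines,
        ),
    }
    lesions = (
        LesionDescriptor(center=(mid[0] - 20, mid[1], mid[2]), radii=(6.0, 6.0, 6.0)),
        LesionDescriptor(center=(mid[0], mid[1] + 20, mid[2]), radii=(5.0, 4.0, 4.0)),
        LesionDescriptor(center=(mid[0] + 20, mid[1] - 10, mid[2]), radii=(4.0, 4.0, 4.0)),
    )
    return PhantomSpec(shape=shape, voxel_size=vs, bundles=bundles, lesions=lesions, seed=seed)


# ---------------------------------------------------------------------------
# geometry helpers


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to (at most) ``step`` mm spacing, keeping endpoints."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) centerline")
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, arc, points[:, k]) for k in range(3)])


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def make_bundle(spec: PhantomSpec, name: str) -> Bundle:
    """Generate the streamlines of one bundle.

    Each streamline is the resampled centerline translated by a constant
    lateral offset drawn from an isotropic Gaussian (sd = dispersion) in the
    plane perpendicular to the bundle axis, with its norm clipped to the tube
    radius. All points therefore lie within ``radius`` of the centerline, and
    a zero dispersion collapses every streamline onto the centerline exactly.
    """
    if name not in spec.bundles:
        raise KeyError(f"unknown bundle name {name!r}; have {sorted(spec.bundles)}")
    desc = spec.bundles[name]
    if desc.n_streamlines <= 0:
        raise ValueError("streamline count must be positive")
    center = _resample_polyline(
        np.asarray(desc.control_points, dtype=float), spec.voxel_size / 2.0
    )
    axis = center[-1] - center[0]
    if np.linalg.norm(axis) == 0:
        axis = center[1] - center[0]
    e1, e2 = _perp_basis(axis)
    idx = sorted(spec.bundles).index(name)
    rng = np.random.default_rng([spec.seed, idx])
    ab = rng.normal(0.0, desc.dispersion, size=(desc.n_streamlines, 2))
    norms = np.linalg.norm(ab, axis=1)
    over = norms > desc.radius
    if over.any():
        ab[over] *= (desc.radius / norms[over])[:, None]
    offsets = ab[:, :1] * e1 + ab[:, 1:] * e2
    side = "left" if name.endswith("_left") else ("right" if name.endswith("_right") else "commissural")
    return Bundle(name=name, streamlines=[center + off for off in offsets], side=side)


def make_lesion_mask(spec: PhantomSpec, grid: VoxelGrid | None = None) -> np.ndarray:
    """Binary mask: voxel is 1 iff its centre lies inside any lesion ellipsoid."""
    grid = grid or spec.grid()
    centers = grid.voxel_centers()
    lo, hi = centers.reshape(-1, 3).min(0), centers.reshape(-1, 3).max(0)
    mask = np.zeros(grid.shape, dtype=bool)
    for les in spec.lesions:
        c = np.asarray(les.center, dtype=float)
        if ((c < lo - grid.voxel_size) | (c > hi + grid.voxel_size)).any():
            raise ValueError(f"lesion centre {tuple(c)} lies outside the grid")
        r = np.asarray(les.radii, dtype=float)
        mask |= (((centers - c) / r) ** 2).sum(-1) <= 1.0
    return mask


def make_brain_mask(spec: PhantomSpec, grid: VoxelGrid | None = None) -> np.ndarray:
    """Whole-box brain mask (the phantom has no background compartment)."""
    grid = grid or spec.grid()
    return np.ones(grid.shape, dtype=bool)


def make_scalar_maps(
    spec: PhantomSpec,
    lesion_mask: np.ndarray,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-voxel metric maps: baseline outside lesions, baseline x multiplier
    inside, plus optional additive Gaussian noise with sd equal to
    ``spec.noise_sd`` times the metric's baseline (relative noise, so metrics
    spanning four orders of magnitude are perturbed comparably).

    FA is clipped to [0, 1] and all non-negative metrics to [0, inf) after
    noise, preserving the metric ranges the statistics assume.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != tuple(spec.shape):
        raise ValueError("lesion mask is not on the phantom grid")
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 10_000])
    maps = {}
    for metric in METRICS:
        base = spec.tissue.baseline[metric]
        mult = spec.tissue.lesion_multiplier[metric]
        vol = np.full(spec.shape, base, dtype=float)
        vol[lesion_mask] = base * mult
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd * base, size=spec.shape)
        if metric == "fa":
            vol = np.clip(vol, 0.0, 1.0)
        else:
            vol = np.clip(vol, 0.0, None)
        maps[metric] = vol
    return maps


def _tangent_field(spec: PhantomSpec, grid: VoxelGrid, bundles) -> np.ndarray:
    """Unit tangent per voxel for voxels traversed by any bundle, else zero."""
    tangents = np.zeros(grid.shape + (3,))
    for bundle in bundles:
        for sl in bundle.streamlines:
            tang = np.gradient(sl, axis=0)
            tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
            idx = grid.nearest_voxel(sl)
            ok = grid.in_bounds(idx)
            i, j, k = idx[ok].T
            tangents[i, j, k] = tang[ok]
    return tangents


def make_dwi(
    spec: PhantomSpec,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    bundles=None,
    noise_model: str = "rician",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-tensor forward model: S = S0 * exp(-b g^T D g) per voxel.

    Inside bundle voxels the tensor is cylindrically symmetric about the local
    streamline tangent (axial/radial diffusivities from the tissue params);
    elsewhere it is isotropic. Noise is Rician (magnitude of complex Gaussian)
    by default, with a plain Gaussian option for analytic checks.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if (bvals < 0).any():
        raise ValueError("negative b-values")
    if not (bvals < 50).any():
        raise ValueError("gradient table needs at least one b=0 volume")
    grid = spec.grid()
    ts = spec.tissue
    if bundles is None:
        bundles = [make_bundle(spec, name) for name in spec.bundles]
    tangents = _tangent_field(spec, grid, bundles)
    has_fiber = np.linalg.norm(tangents, axis=-1) > 0.5

    # quadratic form b * g^T D g for both tensor families, vectorized
    g = bvecs
    dot = tangents.reshape(-1, 3) @ g.T  # (nvox, nvol)
    aniso = ts.radial_diffusivity + (ts.axial_diffusivity - ts.radial_diffusivity) * dot**2
    iso = np.full_like(aniso, ts.isotropic_diffusivity)
    adc = np.where(has_fiber.reshape(-1, 1), aniso, iso)
    signal = ts.s0 * np.exp(-bvals[None, :] * adc)
    signal = signal.reshape(grid.shape + (len(bvals),))

    if spec.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng([spec.seed, 20_000])
        n1 = rng.normal(0.0, spec.noise_sd, signal.shape)
        if noise_model == "rician":
            n2 = rng.normal(0.0, spec.noise_sd, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        elif noise_model == "gaussian":
            signal = signal + n1
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return signal


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class Coupling:
    """Linear link from one tract measure (plus covariates) to one score:
    score = beta0 + beta * measure + beta_iq * IQ + beta_edu * edu + N(0, sd^2)."""

    measure: str
    beta: float
    beta0: float = 0.0
    beta_iq: float = 0.0
    beta_edu: float = 0.0
    resid_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("residual sd must be >= 0")


@dataclass(frozen=True)
class MeasureSim:
    """Marginal model for one synthetic measure column: mean, sd and the shift
    added for impaired-group subjects (lesion-burden-like group contrast)."""

    mean: float = 0.0
    sd: float = 1.0
    group_delta: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort design (defaults mirror a 24 impaired / 16 unimpaired
    sample with IQ ~ N(110, 11) and education ~ N(14, 3))."""

    n_impaired: int = 24
    n_unimpaired: int = 16
    couplings: dict = field(default_factory=dict)  # score name -> Coupling
    iq_mean: float = 110.0
    iq_sd: float = 11.0
    edu_mean: float = 14.0
    edu_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_impaired < 2 or self.n_unimpaired < 2:
            raise ValueError("group sizes must be >= 2")

    @property
    def n(self) -> int:
        return self.n_impaired + self.n_unimpaired

    def groups(self) -> np.ndarray:
        return np.array(
            ["impaired"] * self.n_impaired + ["unimpaired"] * self.n_unimpaired
        )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index)])


def make_synthetic_measures(cohort: CohortSpec, measures: dict) -> pd.DataFrame:
    """Subject x measure table drawn from independent Gaussians per
    :class:`MeasureSim`, one RNG stream per subject."""
    groups = cohort.groups()
    names = list(measures)
    rows = np.empty((cohort.n, len(names)))
    for i in range(cohort.n):
        rng = _subject_rng(cohort.seed, i)
        for j, name in enumerate(names):
            sim = measures[name]
            shift = sim.group_delta if groups[i] == "impaired" else 0.0
            rows[i, j] = sim.mean + shift + rng.normal(0.0, sim.sd)
    idx = pd.Index([f"sub-{i:03d}" for i in range(cohort.n)], name="subject_id")
    df = pd.DataFrame(rows, columns=names, index=idx)
    df.insert(0, "group", groups)
    return df


def make_cohort(cohort: CohortSpec, measure_table: pd.DataFrame) -> pd.DataFrame:
    """Append covariates (IQ, education), group labels and coupled cognitive
    scores to a per-subject measure table.

    Each score follows the linear model of its :class:`Coupling`; covariates
    and residuals are drawn from one RNG stream per subject so the cohort is
    reproducible row by row.
    """
    if len(measure_table) != cohort.n:
        raise ValueError(
            f"measure table has {len(measure_table)} rows, cohort expects {cohort.n}"
        )
    for coupling in cohort.couplings.values():
        if coupling.measure not in measure_table.columns:
            raise KeyError(f"coupling references missing column {coupling.measure!r}")
    out = measure_table.copy()
    groups = (
        out["group"].to_numpy() if "group" in out.columns else cohort.groups()
    )
    out["group"] = groups
    n = cohort.n
    iq = np.empty(n)
    edu = np.empty(n)
    eps = {name: np.empty(n) for name in cohort.couplings}
    for i in range(n):
        rng = _subject_rng(cohort.seed + 1, i)
        iq[i] = rng.normal(cohort.iq_mean, cohort.iq_sd)
        edu[i] = rng.normal(cohort.edu_mean, cohort.edu_sd)
        for name, coupling in cohort.couplings.items():
            eps[name][i] = rng.normal(0.0, coupling.resid_sd) if coupling.resid_sd > 0 else 0.0
    out["iq"] = iq
    out["edu"] = edu
    for name, c in cohort.couplings.items():
        out[name] = (
            c.beta0
            + c.beta * out[c.measure].to_numpy(dtype=float)
            + c.beta_iq * iq
            + c.beta_edu * edu
            + eps[name]
        )
    return out
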