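"""Parameter-map quantification: SUVR (PET), rCBF (pCASL) and age-corrected FA (DTI).

The three maps are dimensionless or near-dimensionless analysis currencies:

* SUVR — activity normalized to injected dose and body weight (SUV), then to
  the whole-brain mean, so the in-mask mean is exactly 1.
* rCBF — perfusion from the single-compartment pCASL model, normalized to the
  whole-brain mean per post-labeling delay (PLD), then averaged across PLDs.
* FA — fractional anisotropy of a log-linear least-squares tensor fit, with
  a global linear age correction estimated from the control-analogue group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, QuantificationError
from .volumes import BinaryMask, GridSpec, ScalarVolume, masked_mean

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PET

def compute_suv(activity: ScalarVolume, dose_MBq: float, weight_kg: float) -> ScalarVolume:
    """Standardized uptake value: activity divided by (dose / body weight)."""
    if dose_MBq <= 0 or weight_kg <= 0:
        raise InvalidParameterError("dose and weight must be positive")
    return ScalarVolume(activity.grid, activity.values / (dose_MBq / weight_kg))


def compute_suvr(suv: ScalarVolume, mask: BinaryMask) -> ScalarVolume:
    """SUV ratio: SUV normalized to the mean whole-brain uptake."""
    ref = masked_mean(suv, mask)
    if ref <= 0:
        raise QuantificationError(f"whole-brain reference mean must be positive, got {ref}")
    return ScalarVolume(suv.grid, suv.values / ref)


# ---------------------------------------------------------------------------
# ASL

@dataclass(frozen=True)
class ASLQuantParams:
    """Constants of the single-compartment pCASL quantification model.

    ``labeling_duration_s`` is the RF labeling-train duration; the remaining
    parameters are the standard consensus-model constants (labeling
    efficiency, longitudinal relaxation time of arterial blood, blood-brain
    partition coefficient) and an optional background-suppression scaling.
    """

    labeling_duration_s: float = 1.5
    labeling_efficiency: float = 0.85
    t1_blood_s: float = 1.65
    partition_coefficient: float = 0.9     # mL/g
    background_suppression_factor: float = 1.0

    def __post_init__(self):
        if min(self.labeling_duration_s, self.t1_blood_s, self.partition_coefficient,
               self.background_suppression_factor) <= 0:
            raise InvalidParameterError("ASL quantification constants must be positive")
        if not 0 < self.labeling_efficiency <= 1:
            raise InvalidParameterError("labeling_efficiency must be in (0, 1]")


#: PLDs of the reference acquisition protocol, seconds
DEFAULT_PLDS = (1.5, 1.8, 2.0)


def quantify_cbf(label_mean: ScalarVolume, control_mean: ScalarVolume, m0: ScalarVolume,
                 pld_s: float, params: ASLQuantParams = ASLQuantParams()) -> ScalarVolume:
    """CBF in mL/100g/min from averaged label/control pairs at one PLD.

    CBF = 6000 * lambda * dM * exp(PLD / T1b)
          / (2 * alpha * T1b * M0 * (1 - exp(-tau / T1b)))

    with dM = control - label. Voxels with non-positive M0 become NaN
    (count logged) rather than failing the whole volume.
    """
    label_mean.grid.require_compatible(control_mean.grid)
    label_mean.grid.require_compatible(m0.grid)
    if pld_s <= 0:
        raise InvalidParameterError("pld_s must be positive")
    dm = control_mean.values - label_mean.values
    t1b = params.t1_blood_s
    denom_const = (2.0 * params.labeling_efficiency * t1b
                   * (1.0 - np.exp(-params.labeling_duration_s / t1b))
                   * params.background_suppression_factor)
    good = m0.values > 0
    n_bad = int(np.size(good) - np.count_nonzero(good))
    if n_bad:
        log.info("quantify_cbf: %d voxels with non-positive M0 set to NaN", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        cbf = np.where(
            good,
            6000.0 * params.partition_coefficient * dm * np.exp(pld_s / t1b)
            / (denom_const * np.where(good, m0.values, 1.0)),
            np.nan,
        )
    return ScalarVolume(label_mean.grid, cbf)


def relative_cbf(cbf: ScalarVolume, mask: BinaryMask) -> ScalarVolume:
    """CBF normalized to the whole-brain mean (masked mean of output is 1)."""
    ref = masked_mean(cbf, mask)
    if ref <= 0:
        raise QuantificationError(f"whole-brain CBF reference must be positive, got {ref}")
    return ScalarVolume(cbf.grid, cbf.values / ref)


def average_plds(rcbf_maps) -> ScalarVolume:
    """Unweighted voxelwise mean across the per-PLD rCBF maps.

    Equal weighting reflects the acquisition's equal pair count per PLD.
    """
    maps = list(rcbf_maps)
    if not maps:
        raise InvalidParameterError("need at least one rCBF map")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_compatible(m.grid)
    return ScalarVolume(grid, np.mean([m.values for m in maps], axis=0))


# ---------------------------------------------------------------------------
# DTI

@dataclass(frozen=True)
class DiffusionScheme:
    """Gradient table: per volume one b-value (s/mm^2) and one unit direction."""

    b_values: np.ndarray
    directions: np.ndarray     # (n, 3), unit norm for b > 0

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if g.shape != (b.size, 3):
            raise InvalidParameterError("directions must be (n, 3) matching b_values")
        norms = np.linalg.norm(g, axis=1)
        dwi = b > 0
        bad = dwi & (np.abs(norms - 1.0) > 1e-6)
        if bad.any():
            log.warning("DiffusionScheme: normalizing %d non-unit directions", int(bad.sum()))
            g = g.copy()
            g[bad] = g[bad] / norms[bad, None]
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        if not dwi.any() or (~dwi).sum() < 1:
            raise InvalidParameterError("scheme needs >=1 b=0 volume and >=1 b>0 volume")
        if np.linalg.matrix_rank(_design_matrix(b[dwi], g[dwi])[:, 1:]) < 6:
            raise InvalidParameterError(
                "scheme is underdetermined: need >=6 non-collinear b>0 directions")

    @property
    def n_volumes(self) -> int:
        return int(self.b_values.size)

    def save_fsl(self, bvals_path, bvecs_path) -> None:
        np.savetxt(bvals_path, self.b_values[None, :], fmt="%.1f")
        np.savetxt(bvecs_path, self.directions.T, fmt="%.8f")

    @classmethod
    def load_fsl(cls, bvals_path, bvecs_path) -> "DiffusionScheme":
        b = np.loadtxt(bvals_path).reshape(-1)
        g = np.loadtxt(bvecs_path)
        if g.shape[0] == 3:
            g = g.T
        return cls(b, g)


def _design_matrix(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Rows map (ln s0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S."""
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor, stored as the 6 unique components
    (xx, yy, zz, xy, xz, yz) in mm^2/s."""

    grid: GridSpec
    components: np.ndarray   # shape grid.shape + (6,)

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != self.grid.shape + (6,):
            raise InvalidParameterError("components must have shape grid.shape + (6,)")

    def full_tensors(self) -> np.ndarray:
        t = np.zeros(self.grid.shape + (3, 3))
        for k, (i, j) in enumerate(_TENSOR_IDX):
            t[..., i, j] = self.components[..., k]
            t[..., j, i] = self.components[..., k]
        return t

    def eigenvalues(self, clamp_negative: bool = True) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3).

        Negative eigenvalues (noise artifacts of the log-linear fit) are
        clamped to 0 so the FA in [0, 1] guarantee holds; the clamp count is
        logged.
        """
        finite = np.isfinite(self.components).all(axis=-1)
        t = self.full_tensors()
        t[~finite] = np.eye(3)  # placeholder, restored to NaN below
        ev = np.linalg.eigvalsh(t)[..., ::-1]
        ev[~finite] = np.nan
        if clamp_negative:
            n_clamped = int((ev < 0).sum())
            if n_clamped:
                log.info("TensorVolume: clamped %d negative eigenvalues to 0", n_clamped)
            ev = np.maximum(ev, 0.0)
        return ev

    def fa_map(self) -> ScalarVolume:
        ev = self.eigenvalues()
        return ScalarVolume(self.grid, fractional_anisotropy(ev[..., 0], ev[..., 1], ev[..., 2]))


def fit_diffusion_tensor(dwi_volumes, scheme: DiffusionScheme) -> TensorVolume:
    """Log-linear least-squares tensor fit, vectorized over voxels.

    Solves ln S = ln s0 - b g^T D g per voxel. Voxels with any non-positive
    signal among the scheme's volumes are skipped (NaN components).
    """
    vols = list(dwi_volumes)
    if len(vols) != scheme.n_volumes:
        raise InvalidParameterError(
            f"{len(vols)} volumes but scheme has {scheme.n_volumes} entries")
    grid = vols[0].grid
    for v in vols[1:]:
        grid.require_compatible(v.grid)
    signals = np.stack([v.values.reshape(-1) for v in vols])      # (n_vol, n_vox)
    usable = np.all(signals > 0, axis=0) & np.all(np.isfinite(signals), axis=0)
    n_skipped = int(usable.size - usable.sum())
    if n_skipped:
        log.info("fit_diffusion_tensor: skipped %d voxels with non-positive signal", n_skipped)
    X = _design_matrix(scheme.b_values, scheme.directions)
    coef = np.full((7, signals.shape[1]), np.nan)
    if usable.any():
        coef[:, usable] = np.linalg.pinv(X) @ np.log(signals[:, usable])
    comps = coef[1:].T.reshape(grid.shape + (6,))
    return TensorVolume(grid, comps)


def fractional_anisotropy(l1, l2, l3):
    """FA from eigenvalues: sqrt(3/2) * ||lambda - mean|| / ||lambda||, in [0, 1].

    All-zero eigenvalue triples return 0 by convention.
    """
    l1, l2, l3 = np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    if np.any(np.stack([l1, l2, l3]) < -1e-12):
        raise InvalidParameterError("eigenvalues must be non-negative (clamp first)")
    norm2 = l1 ** 2 + l2 ** 2 + l3 ** 2
    mean = (l1 + l2 + l3) / 3.0
    dev2 = (l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / np.where(norm2 > 0, norm2, 1.0))
    fa = np.where(norm2 > 0, fa, 0.0)
    n_zero = int(np.sum((norm2 == 0) & np.isfinite(norm2)))
    if n_zero and np.ndim(fa):
        log.debug("fractional_anisotropy: %d all-zero triples -> FA 0", n_zero)
    fa = np.clip(fa, 0.0, 1.0)
    return float(fa) if np.ndim(fa) == 0 else np.where(np.isfinite(norm2), fa, np.nan)


# ---------------------------------------------------------------------------
# Age correction

@dataclass(frozen=True)
class AgeModel:
    """Global linear FA-vs-age model: FA_corr = FA + slope * (age - reference)."""

    slope_per_year: float
    reference_age_years: float

    def __post_init__(self):
        if not np.isfinite(self.slope_per_year) or not np.isfinite(self.reference_age_years):
            raise InvalidParameterError("AgeModel parameters must be finite")


def estimate_age_model(fa_maps, ages, mask: BinaryMask, min_t: float = 2.0) -> AgeModel:
    """Fit the global age slope by regressing in-mask mean FA on age.

    Intended for the control-analogue (SCD) group, where no disease effect
    confounds the age trend. The correction *adds back* the fitted decline,
    so slope_per_year is the negated regression slope.

    With only a handful of controls the estimated slope is dominated by
    noise, and — because age and diagnosis are confounded in dementia
    cohorts — applying a noise slope injects a spurious group signal into
    every FA feature. The slope is therefore only applied when it is
    statistically stable (|slope| >= ``min_t`` standard errors); otherwise
    the model degrades gracefully to the identity correction.
    """
    means = np.array([masked_mean(m, mask) for m in fa_maps])
    ages = np.asarray(ages, dtype=float)
    if ages.size != means.size or ages.size < 3:
        raise InvalidParameterError("need >=3 (fa_map, age) pairs")
    slope, intercept = np.polyfit(ages, means, 1)
    resid = means - (slope * ages + intercept)
    ssx = np.sum((ages - ages.mean()) ** 2)
    dof = ages.size - 2
    se = np.sqrt(resid @ resid / dof / ssx) if (dof > 0 and ssx > 0) else np.inf
    if se == 0 or (np.isfinite(se) and abs(slope) >= min_t * se):
        applied = -float(slope)
    else:
        log.info("estimate_age_model: slope %.2e (SE %.2e) not stable, "
                 "using identity correction", slope, se)
        applied = 0.0
    return AgeModel(slope_per_year=applied, reference_age_years=float(ages.mean()))


def age_correct_fa(fa: ScalarVolume, age_years: float, model: AgeModel) -> ScalarVolume:
    """Apply the global linear age correction; output clipped to [0, 1]."""
    if not np.isfinite(age_years):
        raise InvalidParameterError("age must be finite")
    corrected = fa.values + model.slope_per_year * (age_years - model.reference_age_years)
    out = np.clip(corrected, 0.0, 1.0)
    out[~np.isfinite(fa.values)] = np.nan
    return ScalarVolume(fa.grid, out)
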