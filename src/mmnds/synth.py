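"""Synthetic multimodal cohort generator.

Emulates the study conditions of a PET/MRI dementia cohort: six diagnostic
groups (SCD controls-analogue plus five syndromes), raw PET activity, pCASL
label/control series at three post-labeling delays, and a 64-direction DWI
series — all on a common MNI-style grid, already co-registered and
artifact-free (acquisition physics and registration are out of scope).

The generative model, per subject and modality::

    truth(x) = baseline(x) + sum_rois  beta_roi * bump_roi(x)

``bump_roi`` is a Gaussian profile at the ROI's catalog locus, normalized so
its *mean over the ROI sphere* is 1; ``beta_roi`` combines a per-subject
heterogeneity draw N(0, sd_mod) — present in every group, at every catalog
locus — and, for subjects of a lesioned group, a deterministic reduction of
``effect_size_sd * sd_mod`` scaled by a per-subject severity factor.
Heterogeneity is injected locally (not as a global scalar) because
whole-brain intensity normalization would cancel any global component
exactly. Severity links lesion magnitude to MMSE, giving the correlation
stage a known sign.

Raw data are then simulated with the exact forward models that the
quantification stage inverts, so noiseless round-trips are identities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CatalogError, InvalidParameterError
from .quantify import ASLQuantParams, DEFAULT_PLDS, DiffusionScheme, TensorVolume
from .rois import ENTITIES, GROUPS, ROICatalog, builtin_catalog, spherical_mask
from .volumes import FWHM_TO_SIGMA, GridSpec, ScalarVolume, mni_grid

log = logging.getLogger(__name__)

# Reference-cohort demographics (mean, SD) per group; sizes and MMSE
# completion fractions mirror the study sample of 76 subjects.
GROUP_SIZES = {"SCD": 10, "AD": 28, "bvFTD": 10, "svPPA": 8, "nfvPPA": 11, "lvPPA": 9}
AGE_YEARS = {"SCD": (52.2, 15.8), "AD": (65.7, 7.3), "bvFTD": (61.5, 10.3),
             "svPPA": (71.1, 6.7), "lvPPA": (65.3, 5.4), "nfvPPA": (69.6, 7.6)}
MMSE_SCORE = {"SCD": (28.2, 1.6), "AD": (23.5, 3.7), "bvFTD": (20.3, 9.8),
              "svPPA": (23.5, 5.5), "lvPPA": (18.4, 9.3), "nfvPPA": (28.4, 0.9)}
MALE_FRACTION = {"SCD": 5 / 10, "AD": 17 / 28, "bvFTD": 6 / 10,
                 "svPPA": 5 / 8, "lvPPA": 5 / 9, "nfvPPA": 7 / 11}
MMSE_COMPLETION = {"SCD": 5 / 10, "AD": 20 / 28, "bvFTD": 7 / 10,
                   "svPPA": 8 / 8, "nfvPPA": 8 / 11, "lvPPA": 7 / 9}
DOSE_PER_KG_MBQ = 3.0

AGE_RANGE = (35.0, 90.0)


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str
    age: float
    sex: str                      # "m" or "f"
    mmse: int | None
    injected_dose_MBq: float
    body_weight_kg: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if self.sex not in ("m", "f"):
            raise InvalidParameterError("sex must be 'm' or 'f'")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise InvalidParameterError("mmse must be in [0, 30]")
        if self.injected_dose_MBq <= 0 or self.body_weight_kg <= 0:
            raise InvalidParameterError("dose and weight must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """A group-specific lesion: mean ROI-sphere reduction of the modality
    parameter at the named catalog loci, in units of the between-subject SD,
    with a Gaussian spatial profile of the stated FWHM."""

    entity: str
    target_rois: tuple[str, ...]
    effect_size_sd: float = 2.0
    spatial_fwhm_mm: float = 40.0

    def __post_init__(self):
        if self.effect_size_sd < 0:
            raise InvalidParameterError("effect_size_sd must be >= 0")
        if self.spatial_fwhm_mm <= 0:
            raise InvalidParameterError("spatial_fwhm_mm must be positive")


@dataclass(frozen=True)
class CohortSpec:
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    grid: GridSpec = field(default_factory=lambda: mni_grid(3.0))
    effects: tuple[EffectSpec, ...] | None = None   # None -> default per entity
    noise_sd: dict = field(default_factory=lambda: {"pet": 0.05, "asl": 1.0, "dwi": 5.0})
    between_subject_sd: dict = field(
        default_factory=lambda: {"suvr": 0.05, "cbf": 2.5, "fa": 0.03})
    severity_sd: float = 0.4
    mmse_effect_slope: float = 6.0
    n_pairs_per_pld: int = 12
    plds: tuple[float, ...] = DEFAULT_PLDS
    n_dwi_directions: int = 64
    b_value: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in GROUPS or n < 0:
                raise InvalidParameterError(f"bad group_sizes entry {g}: {n}")
        if not any(n > 0 for n in self.group_sizes.values()):
            raise InvalidParameterError("at least one group count must be positive")
        if any(v < 0 for v in self.noise_sd.values()):
            raise InvalidParameterError("noise_sd must be >= 0")


def default_effects(effect_size_sd: float = 2.0, spatial_fwhm_mm: float = 40.0,
                    catalog: ROICatalog | None = None) -> tuple[EffectSpec, ...]:
    """One lesion per entity, targeting all of that entity's catalog loci."""
    catalog = catalog or builtin_catalog()
    return tuple(
        EffectSpec(entity=e,
                   target_rois=tuple(r.name for r in catalog.for_entity(e)),
                   effect_size_sd=effect_size_sd,
                   spatial_fwhm_mm=spatial_fwhm_mm)
        for e in ENTITIES
    )


@dataclass
class RawModalityBundle:
    """Raw (pre-quantification) data for one subject on one grid."""

    grid: GridSpec
    pet_activity: ScalarVolume | None = None
    asl_pairs: dict | None = None            # pld -> list of (label, control)
    m0: ScalarVolume | None = None
    dwi: list | None = None                  # ScalarVolume per scheme entry
    scheme: DiffusionScheme | None = None


# ---------------------------------------------------------------------------
# Anatomy-like baseline fields (smooth phantoms, not anatomical atlases)

_BRAIN_CENTER = np.array([0.0, -18.0, 18.0])
_BRAIN_SEMI_AXES = np.array([70.0, 86.0, 75.0])
_WM_SCALE = 0.85
_EDGE_SOFTNESS = 0.05


def _soft_ellipsoid(grid: GridSpec, scale: float) -> np.ndarray:
    cx, cy, cz = grid.world_coordinates()
    ax, ay, az = _BRAIN_SEMI_AXES * scale
    r2 = (((cx - _BRAIN_CENTER[0]) / ax) ** 2)[:, None, None] \
        + (((cy - _BRAIN_CENTER[1]) / ay) ** 2)[None, :, None] \
        + (((cz - _BRAIN_CENTER[2]) / az) ** 2)[None, None, :]
    rho = np.sqrt(r2)
    return 1.0 / (1.0 + np.exp((rho - 1.0) / _EDGE_SOFTNESS))


def baseline_fields(grid: GridSpec) -> dict:
    """Smooth phantom baselines: brain indicator, SUVR-, CBF-, FA-like maps."""
    brain = _soft_ellipsoid(grid, 1.0)
    wm = _soft_ellipsoid(grid, _WM_SCALE)
    return {
        "brain": brain,
        "suvr": 0.05 + 1.2 * brain,
        "cbf": 2.0 + 54.0 * brain,            # mL/100g/min
        "fa": 0.12 * brain + 0.33 * wm,
        "s0": 200.0 + 800.0 * brain,          # DWI non-weighted signal
    }


# ---------------------------------------------------------------------------
# Gradient scheme

def make_scheme(n_directions: int = 64, b_value: float = 1000.0, seed: int = 0,
                n_b0: int = 1, n_iter: int = 200) -> DiffusionScheme:
    """Seeded electrostatic-repulsion direction set plus b=0 entries.

    Points repel along the sphere (antipodally symmetrized force, since a
    diffusion gradient and its negation are equivalent), which spreads the
    stated number of directions near-uniformly without a published table.
    """
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_directions, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    for it in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            d2 = np.sum(diff ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            d2[d2 < 1e-12] = np.inf
            force += np.sum(diff / (d2 ** 1.5)[..., None], axis=1)
        # tangent-plane projection with a unit-normalized, annealed step keeps
        # the update stable regardless of the Coulomb-force magnitude
        force -= np.sum(force * pts, axis=1, keepdims=True) * pts
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        step = 0.05 * (1.0 - it / n_iter)
        pts = pts + step * force / np.maximum(norm, 1e-12)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    b = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    g = np.vstack([np.zeros((n_b0, 3)), pts])
    return DiffusionScheme(b, g)


# ---------------------------------------------------------------------------
# Axially symmetric tensors from FA / MD targets

def tensor_field_from_fa(fa: ScalarVolume, md_mm2_s: float = 0.75e-3,
                         axis=(0.0, 0.0, 1.0)) -> TensorVolume:
    """Axially symmetric SPD tensor field with prescribed FA and mean diffusivity.

    For an axially symmetric tensor with eigenvalues md(1+2d), md(1-d),
    md(1-d): FA = 3d / sqrt(3 + 6 d^2), inverted as
    d = FA sqrt(3 / (9 - 6 FA^2)); requires FA <= 3/sqrt(15) ~ 0.775 for SPD.
    """
    f = np.clip(np.nan_to_num(fa.values, nan=0.0), 0.0, 0.77)
    delta = f * np.sqrt(3.0 / (9.0 - 6.0 * f ** 2))
    lam_par = md_mm2_s * (1.0 + 2.0 * delta)
    lam_perp = md_mm2_s * (1.0 - delta)
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    # D = lam_perp I + (lam_par - lam_perp) n n^T
    comps = np.empty(fa.grid.shape + (6,))
    outer = np.array([n[0] * n[0], n[1] * n[1], n[2] * n[2],
                      n[0] * n[1], n[0] * n[2], n[1] * n[2]])
    diff = lam_par - lam_perp
    for k in range(3):
        comps[..., k] = lam_perp + diff * outer[k]
    for k in range(3, 6):
        comps[..., k] = diff * outer[k]
    return TensorVolume(fa.grid, comps)


# ---------------------------------------------------------------------------
# Forward simulators (exact inverses of the quantification stage)

def simulate_pet_activity(truth_suvr: ScalarVolume, subject: SubjectRecord,
                          noise_sd: float, seed) -> ScalarVolume:
    """Raw activity whose SUV equals the truth map up to additive noise.

    scale = dose / weight, so SUV normalization cancels it exactly;
    ``noise_sd`` is stated in SUV units.
    """
    if float(np.nanmean(truth_suvr.values)) <= 0:
        raise InvalidParameterError("truth SUVR must have positive mean")
    scale = subject.injected_dose_MBq / subject.body_weight_kg
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(truth_suvr.grid.shape) * noise_sd if noise_sd > 0 else 0.0
    return ScalarVolume(truth_suvr.grid, (truth_suvr.values + noise) * scale)


def simulate_asl_series(truth_cbf: ScalarVolume, params: ASLQuantParams = ASLQuantParams(),
                        plds=DEFAULT_PLDS, n_pairs: int = 12, noise_sd: float = 0.0,
                        seed=0, m0: ScalarVolume | None = None):
    """Label/control pairs per PLD from the single-compartment model.

    The difference signal dM is the exact algebraic inverse of
    :func:`mmnds.quantify.quantify_cbf`, so a noiseless series quantifies
    back to the truth to machine precision.

    Returns ``(asl_pairs, m0)`` with ``asl_pairs[pld] = [(label, control), ...]``.
    """
    if np.nanmin(truth_cbf.values) < 0:
        raise InvalidParameterError("truth CBF must be >= 0")
    grid = truth_cbf.grid
    if m0 is None:
        m0 = ScalarVolume(grid, 100.0 + 10.0 * truth_cbf.values)
    grid.require_compatible(m0.grid)
    t1b = params.t1_blood_s
    denom_const = (2.0 * params.labeling_efficiency * t1b
                   * (1.0 - np.exp(-params.labeling_duration_s / t1b))
                   * params.background_suppression_factor)
    static = 0.5 * m0.values
    rng = np.random.default_rng(seed)
    known = set(DEFAULT_PLDS)
    pairs = {}
    for pld in plds:
        if round(float(pld), 6) not in {round(p, 6) for p in known}:
            log.info("simulate_asl_series: non-protocol PLD %.3f s", pld)
        dm = (truth_cbf.values * denom_const * m0.values
              / (6000.0 * params.partition_coefficient * np.exp(pld / t1b)))
        plist = []
        for _ in range(n_pairs):
            nl = rng.standard_normal(grid.shape) * noise_sd if noise_sd > 0 else 0.0
            nc = rng.standard_normal(grid.shape) * noise_sd if noise_sd > 0 else 0.0
            label = ScalarVolume(grid, static - dm / 2.0 + nl)
            control = ScalarVolume(grid, static + dm / 2.0 + nc)
            plist.append((label, control))
        pairs[float(pld)] = plist
    return pairs, m0


def simulate_dwi_series(truth_tensor: TensorVolume, scheme: DiffusionScheme,
                        s0, noise_sd: float = 0.0, seed=0, rician: bool = False):
    """DWI volumes S(g, b) = s0 exp(-b g^T D g) with additive Gaussian noise
    (or Rician when requested)."""
    grid = truth_tensor.grid
    s0_arr = s0.values if isinstance(s0, ScalarVolume) else np.full(grid.shape, float(s0))
    d = truth_tensor.components
    rng = np.random.default_rng(seed)
    vols = []
    for b, g in zip(scheme.b_values, scheme.directions):
        gdg = (d[..., 0] * g[0] * g[0] + d[..., 1] * g[1] * g[1] + d[..., 2] * g[2] * g[2]
               + 2 * d[..., 3] * g[0] * g[1] + 2 * d[..., 4] * g[0] * g[2]
               + 2 * d[..., 5] * g[1] * g[2])
        signal = s0_arr * np.exp(-b * gdg)
        if noise_sd > 0:
            if rician:
                n1 = rng.standard_normal(grid.shape) * noise_sd
                n2 = rng.standard_normal(grid.shape) * noise_sd
                signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
            else:
                signal = signal + rng.standard_normal(grid.shape) * noise_sd
        vols.append(ScalarVolume(grid, signal))
    return vols


# ---------------------------------------------------------------------------
# Cohort model

class CohortModel:
    """Deterministic cohort factory: demographics, latent lesion fields, and
    raw-data simulation, all derived from one master seed.

    Per-subject randomness comes from ``SeedSequence(seed).spawn`` children
    keyed by subject index, so any subject can be regenerated in isolation.
    """

    def __init__(self, spec: CohortSpec, catalog: ROICatalog | None = None):
        self.spec = spec
        self.catalog = catalog or builtin_catalog()
        self.effects = spec.effects if spec.effects is not None else default_effects(
            catalog=self.catalog)
        for eff in self.effects:
            for name in eff.target_rois:
                self.catalog.get(name)    # raises CatalogError for unknown names
            if eff.entity not in ENTITIES:
                raise CatalogError(f"effect entity {eff.entity!r} unknown")
        self._effect_by_group = {}
        for eff in self.effects:
            self._effect_by_group.setdefault(eff.entity, []).append(eff)
        self.base = baseline_fields(spec.grid)
        self._bumps: dict = {}
        self.scheme = make_scheme(spec.n_dwi_directions, spec.b_value,
                                  seed=_child_seed(spec.seed, "scheme"))
        self._records: list[SubjectRecord] | None = None
        self._latents: dict | None = None

    # -- latent structure ---------------------------------------------------

    def _bump(self, roi_name: str, fwhm_mm: float) -> np.ndarray:
        """Gaussian profile at the ROI locus, normalized to sphere-mean 1."""
        key = (roi_name, round(fwhm_mm, 6))
        if key not in self._bumps:
            roi = self.catalog.get(roi_name)
            grid = self.spec.grid
            cx, cy, cz = grid.world_coordinates()
            c = roi.center_mni_mm
            d2 = ((cx - c[0]) ** 2)[:, None, None] + ((cy - c[1]) ** 2)[None, :, None] \
                + ((cz - c[2]) ** 2)[None, None, :]
            sigma = fwhm_mm * FWHM_TO_SIGMA
            prof = np.exp(-d2 / (2.0 * sigma ** 2))
            sphere = spherical_mask(grid, roi.center_mni_mm, roi.radius_mm)
            prof = prof / prof[sphere.values].mean()
            self._bumps[key] = prof
        return self._bumps[key]

    def records(self) -> list[SubjectRecord]:
        if self._records is None:
            self._build_subjects()
        return list(self._records)

    def latents(self) -> dict:
        if self._latents is None:
            self._build_subjects()
        return dict(self._latents)

    def _build_subjects(self) -> None:
        records, latents = [], {}
        idx = 0
        sd = self.spec.between_subject_sd
        mod_sd = {"PET": sd["suvr"], "ASL": sd["cbf"], "DTI": sd["fa"]}
        for group in GROUPS:
            n = self.spec.group_sizes.get(group, 0)
            for k in range(n):
                rng = np.random.default_rng(_child_seed(self.spec.seed, "subject", idx))
                sid = f"sub-{idx:03d}"
                age = float(np.clip(rng.normal(*AGE_YEARS[group]), *AGE_RANGE))
                sex = "m" if rng.random() < MALE_FRACTION[group] else "f"
                weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 120.0))
                dose = DOSE_PER_KG_MBQ * weight * float(1.0 + 0.03 * rng.standard_normal())
                severity = float(1.0 + self.spec.severity_sd * rng.standard_normal())
                # heterogeneity draw per catalog locus per modality, all groups
                bumps = {}
                for roi in self.catalog:
                    for modality in roi.modalities:
                        bumps[(roi.name, modality)] = float(
                            rng.normal(0.0, mod_sd[modality]))
                effect_total = sum(e.effect_size_sd for e in self._effect_by_group.get(group, []))
                mean_mmse, sd_mmse = MMSE_SCORE[group]
                mmse_val = (mean_mmse
                            - self.spec.mmse_effect_slope * effect_total * (severity - 1.0)
                            + sd_mmse * rng.standard_normal())
                has_mmse = rng.random() < MMSE_COMPLETION[group]
                mmse = int(np.clip(round(mmse_val), 0, 30)) if has_mmse else None
                records.append(SubjectRecord(sid, group, age, sex, mmse, dose, weight))
                latents[sid] = {"severity": severity, "bumps": bumps, "index": idx}
                idx += 1
        self._records = records
        self._latents = latents

    # -- truth maps ---------------------------------------------------------

    def truth_maps(self, record: SubjectRecord) -> dict:
        """Ground-truth SUVR/CBF/FA maps for one subject (pre-noise)."""
        lat = self.latents()[record.id]
        sd = self.spec.between_subject_sd
        fields = {"suvr": self.base["suvr"].copy(),
                  "cbf": self.base["cbf"].copy(),
                  "fa": self.base["fa"].copy()}
        mod_field = {"PET": "suvr", "ASL": "cbf", "DTI": "fa"}
        mod_sd = {"PET": sd["suvr"], "ASL": sd["cbf"], "DTI": sd["fa"]}
        lesioned = {}
        for eff in self._effect_by_group.get(record.group, []):
            for name in eff.target_rois:
                roi = self.catalog.get(name)
                for modality in roi.modalities:
                    lesioned[(name, modality)] = (
                        eff.effect_size_sd * mod_sd[modality] * lat["severity"],
                        eff.spatial_fwhm_mm)
        default_fwhm = self.effects[0].spatial_fwhm_mm if self.effects else 40.0
        for roi in self.catalog:
            for modality in roi.modalities:
                beta = lat["bumps"][(roi.name, modality)]
                lesion_amp, fwhm = lesioned.get((roi.name, modality), (0.0, default_fwhm))
                total = beta - lesion_amp
                if total != 0.0:
                    fields[mod_field[modality]] += total * self._bump(roi.name, fwhm)
        grid = self.spec.grid
        return {
            "suvr": ScalarVolume(grid, np.maximum(fields["suvr"], 0.01)),
            "cbf": ScalarVolume(grid, np.maximum(fields["cbf"], 0.1)),
            "fa": ScalarVolume(grid, np.clip(fields["fa"], 0.0, 0.95)),
        }

    # -- raw bundles --------------------------------------------------------

    def raw_bundle(self, record: SubjectRecord,
                   modalities=("PET", "ASL", "DTI")) -> RawModalityBundle:
        truth = self.truth_maps(record)
        idx = self.latents()[record.id]["index"]
        spec = self.spec
        bundle = RawModalityBundle(grid=spec.grid)
        if "PET" in modalities:
            bundle.pet_activity = simulate_pet_activity(
                truth["suvr"], record, spec.noise_sd["pet"],
                _child_seed(spec.seed, "pet", idx))
        if "ASL" in modalities:
            bundle.asl_pairs, bundle.m0 = simulate_asl_series(
                truth["cbf"], ASLQuantParams(), spec.plds, spec.n_pairs_per_pld,
                spec.noise_sd["asl"], _child_seed(spec.seed, "asl", idx))
        if "DTI" in modalities:
            tensors = tensor_field_from_fa(truth["fa"])
            bundle.dwi = simulate_dwi_series(
                tensors, self.scheme, ScalarVolume(spec.grid, self.base["s0"]),
                spec.noise_sd["dwi"], _child_seed(spec.seed, "dwi", idx))
            bundle.scheme = self.scheme
        return bundle

    def iter_cohort(self, modalities=("PET", "ASL", "DTI")):
        """Yield (record, bundle) lazily; bundles are large, discard promptly."""
        for record in self.records():
            yield record, self.raw_bundle(record, modalities)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [dict(subject_id=r.id, group=r.group, age=r.age, sex=r.sex,
                     mmse="" if r.mmse is None else r.mmse,
                     injected_dose_MBq=r.injected_dose_MBq,
                     body_weight_kg=r.body_weight_kg)
                for r in self.records()]
        return pd.DataFrame(rows).set_index("subject_id")


def _child_seed(master_seed: int, *key) -> np.random.SeedSequence:
    """Stable per-stage / per-subject seed derivation from the master seed."""
    tokens = [int(master_seed)]
    for k in key:
        tokens.append(sum(ord(c) for c in k) if isinstance(k, str) else int(k))
    return np.random.SeedSequence(tokens)


def generate_cohort(spec: CohortSpec, catalog: ROICatalog | None = None,
                    modalities=("PET", "ASL", "DTI")):
    """Materialize the whole cohort: (records, {subject_id: RawModalityBundle}).

    Convenience for small grids/cohorts; for full-size cohorts prefer
    ``CohortModel(spec).iter_cohort()`` which streams subject by subject.
    """
    model = CohortModel(spec, catalog)
    records = model.records()
    bundles = {r.id: model.raw_bundle(r, modalities) for r in records}
    return records, bundles
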