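"""Spherical ROI catalog, mask construction, and feature assembly.

Each dementia syndrome (AD, bvFTD, svPPA, nfvPPA, lvPPA) has one or two
gray-matter loci (read out in PET-SUVR and/or ASL-rCBF) and one or two
white-matter loci (read out in DTI-FA), given as sphere centers in MNI
millimeters with a 30 mm radius by default (20 mm for the svPPA
white-matter pair). Averaging the parameter maps inside these spheres
yields the 3- to 5-dimensional feature vectors fed to the classifiers.

FA averages honor the standard white-matter restriction: only voxels with
FA strictly greater than 0.2 contribute; SUVR and rCBF are unthresholded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CatalogError, EmptyMaskError, InvalidParameterError, MissingValueError
from .volumes import BinaryMask, GridSpec, ScalarVolume

ENTITIES = ("AD", "bvFTD", "svPPA", "nfvPPA", "lvPPA")
GROUPS = ("SCD",) + ENTITIES
MODALITIES = ("PET", "ASL", "DTI")

#: strict lower bound for voxels entering a white-matter FA average
FA_THRESHOLD = 0.2


@dataclass(frozen=True)
class ROISpec:
    name: str
    entity: str
    tissue: str                      # "GM" or "WM"
    modalities: tuple[str, ...]
    center_mni_mm: tuple[float, float, float]
    radius_mm: float = 30.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise InvalidParameterError("radius_mm must be positive")
        if not self.modalities:
            raise InvalidParameterError("modalities must be non-empty")
        for m in self.modalities:
            if m not in MODALITIES:
                raise InvalidParameterError(f"unknown modality {m!r}")
        if self.tissue not in ("GM", "WM"):
            raise InvalidParameterError(f"tissue must be GM or WM, got {self.tissue!r}")


@dataclass
class ROICatalog:
    rois: tuple[ROISpec, ...]
    _by_name: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.rois = tuple(self.rois)
        object.__setattr__(self, "_by_name", {r.name: r for r in self.rois})
        if len(self._by_name) != len(self.rois):
            raise CatalogError("duplicate ROI names in catalog")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def get(self, name: str) -> ROISpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise CatalogError(f"ROI {name!r} not in catalog") from None

    def for_entity(self, entity: str) -> tuple[ROISpec, ...]:
        if entity not in ENTITIES:
            raise CatalogError(f"unknown entity {entity!r}")
        return tuple(r for r in self.rois if r.entity == entity)

    def feature_index(self, entity: str) -> tuple[tuple[str, str], ...]:
        """Ordered (roi name, modality) pairs defining the entity's feature
        vector: PET ROIs first, then ASL, then DTI; left before right
        (catalog order within a modality)."""
        rois = self.for_entity(entity)
        pairs = []
        for modality in MODALITIES:
            for roi in rois:
                if modality in roi.modalities:
                    pairs.append((roi.name, modality))
        return tuple(pairs)

    def dimensionality(self, entity: str) -> int:
        return len(self.feature_index(entity))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(name=r.name, entity=r.entity, tissue=r.tissue,
                 modalities="+".join(r.modalities),
                 x=r.center_mni_mm[0], y=r.center_mni_mm[1], z=r.center_mni_mm[2],
                 radius_mm=r.radius_mm)
            for r in self.rois
        ]
        return pd.DataFrame(rows)


def _gm(name, entity, mods, xyz, r=30.0):
    return ROISpec(name, entity, "GM", tuple(mods), tuple(float(c) for c in xyz), r)


def _wm(name, entity, xyz, r=30.0):
    return ROISpec(name, entity, "WM", ("DTI",), tuple(float(c) for c in xyz), r)


def builtin_catalog() -> ROICatalog:
    """The published spherical ROI catalog for the five syndromes.

    Centers are MNI mm; radius 30 mm except the svPPA white-matter pair
    (20 mm). Bilateral pairs stay separate features (left listed first),
    which is what puts the per-entity feature dimensionality in the 3-5
    range: AD 5, bvFTD 5, svPPA 5, nfvPPA 3, lvPPA 3.
    """
    rois = [
        # AD — parietal metabolism, inferior-parietal perfusion and WM
        _gm("AD_parietal_PET", "AD", ("PET",), (0, -70, 36)),
        _gm("AD_infpar_ASL_L", "AD", ("ASL",), (-40, -56, 46)),
        _gm("AD_infpar_ASL_R", "AD", ("ASL",), (40, -56, 46)),
        _wm("AD_infpar_WM_L", "AD", (-22, -43, 37)),
        _wm("AD_infpar_WM_R", "AD", (22, -43, 37)),
        # bvFTD — medial frontal metabolism, inferior frontal perfusion/WM
        _gm("bvFTD_medfrontal_PET", "bvFTD", ("PET",), (0, 32, 35)),
        _gm("bvFTD_inffrontal_ASL_L", "bvFTD", ("ASL",), (-41, 19, -1)),
        _gm("bvFTD_inffrontal_ASL_R", "bvFTD", ("ASL",), (41, 19, -1)),
        _wm("bvFTD_inffrontal_WM_L", "bvFTD", (-24, 33, 3)),
        _wm("bvFTD_inffrontal_WM_R", "bvFTD", (24, 33, 3)),
        # svPPA — superior temporal; note the ASL locus is left-only in the
        # published table and is taken verbatim (no symmetrization)
        _gm("svPPA_suptemporal_PET_L", "svPPA", ("PET",), (-41, 11, -21)),
        _gm("svPPA_suptemporal_PET_R", "svPPA", ("PET",), (41, 11, -21)),
        _gm("svPPA_suptemporal_ASL_L", "svPPA", ("ASL",), (-46, 11, -19)),
        _wm("svPPA_suptemporal_WM_L", "svPPA", (-40, -7, -19), r=20.0),
        _wm("svPPA_suptemporal_WM_R", "svPPA", (40, -7, -19), r=20.0),
        # nfvPPA — one shared GM locus for PET and ASL, one WM locus
        _gm("nfvPPA_callosal_GM", "nfvPPA", ("PET", "ASL"), (-4, 13, 16)),
        _wm("nfvPPA_cingulate_WM", "nfvPPA", (-25, -15, 40)),
        # lvPPA — one shared GM locus, one WM locus
        _gm("lvPPA_infpar_GM", "lvPPA", ("PET", "ASL"), (-40, -60, 43)),
        _wm("lvPPA_ba40_WM", "lvPPA", (25, -55, 32)),
    ]
    return ROICatalog(tuple(rois))


def spherical_mask(grid: GridSpec, center_mni_mm, radius_mm: float) -> BinaryMask:
    """Voxels whose centers lie within ``radius_mm`` (inclusive) of the center."""
    if radius_mm <= 0:
        raise InvalidParameterError("radius_mm must be positive")
    center = np.asarray(center_mni_mm, dtype=float)
    cx, cy, cz = grid.world_coordinates()
    d2 = ((cx - center[0]) ** 2)[:, None, None] \
        + ((cy - center[1]) ** 2)[None, :, None] \
        + ((cz - center[2]) ** 2)[None, None, :]
    inside = d2 <= radius_mm ** 2 + 1e-9
    if not inside.any():
        raise EmptyMaskError(f"sphere at {tuple(center)} r={radius_mm} misses the grid")
    return BinaryMask(grid, inside)


def roi_mean(vol: ScalarVolume, mask: BinaryMask, modality: str) -> float:
    """Arithmetic ROI average; for DTI restricted to voxels with FA > 0.2.

    Raises :class:`MissingValueError` when no voxel qualifies, so an
    un-computable FA feature is an explicit missing value, never a silent 0.
    """
    vol.grid.require_compatible(mask.grid)
    if modality not in MODALITIES:
        raise InvalidParameterError(f"unknown modality {modality!r}")
    if mask.n_voxels == 0:
        raise EmptyMaskError("ROI mask is empty")
    vals = vol.values[mask.values]
    vals = vals[np.isfinite(vals)]
    if modality == "DTI":
        vals = vals[vals > FA_THRESHOLD]
    if vals.size == 0:
        raise MissingValueError(f"no usable voxels for modality {modality} in ROI")
    return float(vals.mean())


@dataclass
class FeatureVector:
    subject_id: str
    entity: str
    names: tuple[tuple[str, str], ...]   # (roi name, modality) in canonical order
    values: np.ndarray                   # NaN where missing
    missing: tuple[bool, ...]

    @property
    def complete(self) -> bool:
        return not any(self.missing)


_MODALITY_MAP = {"PET": "suvr", "ASL": "rcbf", "DTI": "fa"}


def assemble_entity_features(subject_id: str, maps: dict, entity: str,
                             catalog: ROICatalog,
                             _mask_cache: dict | None = None) -> FeatureVector:
    """Build one subject's feature vector for one entity's ROI definition.

    ``maps`` holds the subject's parameter volumes keyed ``suvr``/``rcbf``/``fa``.
    Every subject, whatever their diagnosis, is measured with the same
    entity-specific ROI set so the vectors are comparable across groups.
    """
    pairs = catalog.feature_index(entity)
    values, missing = [], []
    for roi_name, modality in pairs:
        roi = catalog.get(roi_name)
        vol = maps[_MODALITY_MAP[modality]]
        key = (roi_name, vol.grid)
        if _mask_cache is not None and key in _mask_cache:
            mask = _mask_cache[key]
        else:
            mask = spherical_mask(vol.grid, roi.center_mni_mm, roi.radius_mm)
            if _mask_cache is not None:
                _mask_cache[key] = mask
        try:
            values.append(roi_mean(vol, mask, modality))
            missing.append(False)
        except MissingValueError:
            values.append(np.nan)
            missing.append(True)
    return FeatureVector(subject_id, entity, pairs, np.asarray(values, float), tuple(missing))


def feature_table(subject_maps: dict, catalog: ROICatalog | None = None) -> pd.DataFrame:
    """Feature matrix over all subjects and all entities.

    ``subject_maps`` maps subject id -> {"suvr": vol, "rcbf": vol, "fa": vol}.
    Columns are named ``entity|roi|modality``; one row per subject.
    """
    catalog = catalog or builtin_catalog()
    cache: dict = {}
    rows = {}
    for sid, maps in subject_maps.items():
        row = {}
        for entity in ENTITIES:
            fv = assemble_entity_features(sid, maps, entity, catalog, _mask_cache=cache)
            for (roi, modality), val in zip(fv.names, fv.values):
                row[f"{entity}|{roi}|{modality}"] = val
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def entity_columns(df: pd.DataFrame, entity: str, modality_set: str = "ALL") -> list[str]:
    """Columns of a feature table belonging to one entity/modality selection.

    ``modality_set``: "PET" (SUVR only), "MRI" (ASL + DTI) or "ALL".
    """
    wanted = {"PET": {"PET"}, "MRI": {"ASL", "DTI"}, "ALL": {"PET", "ASL", "DTI"}}[modality_set]
    cols = [c for c in df.columns
            if c.split("|")[0] == entity and c.split("|")[2] in wanted]
    if not cols:
        raise CatalogError(f"no feature columns for entity {entity!r} / {modality_set}")
    return cols
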