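"""Whole brain-based spatial statistics (WBSS).

Voxel-wise two-sample comparison between a syndrome group and the SCD
control-analogue, Benjamini-Hochberg FDR correction over the tested voxels,
and removal of surviving components smaller than 256 mm^3 (the cluster
threshold stated in voxels on a 1-mm grid; here converted through the voxel
volume so the criterion is grid independent). Cross-modality overlap masks
reproduce the red/blue/yellow partition of the overlap figures.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyMaskError, InsufficientDataError, InvalidParameterError
from .volumes import BinaryMask, ScalarVolume

#: cluster threshold in mm^3 (equals 256 voxels on the 1-mm analysis grid)
CLUSTER_THRESHOLD_MM3 = 256.0


@dataclass(frozen=True)
class WBSSConfig:
    test: str = "student_t"            # or "welch_t"
    alpha: float = 0.05
    min_cluster_mm3: float = CLUSTER_THRESHOLD_MM3
    connectivity: int = 6              # 6, 18 or 26
    tail: str = "two_sided"            # "two_sided", "lower", "upper"
    fdr_method: str = "fdr_bh"         # "fdr_by" available for dependence robustness

    def __post_init__(self):
        if self.test not in ("student_t", "welch_t"):
            raise InvalidParameterError(f"unknown test {self.test!r}")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise InvalidParameterError("connectivity must be 6, 18 or 26")
        if self.tail not in ("two_sided", "lower", "upper"):
            raise InvalidParameterError(f"unknown tail {self.tail!r}")
        if self.fdr_method not in ("fdr_bh", "fdr_by"):
            raise InvalidParameterError(f"unknown fdr_method {self.fdr_method!r}")

    def min_cluster_voxels(self, voxel_volume_mm3: float) -> int:
        """Smallest surviving component size in voxels on the given grid."""
        return int(np.ceil(self.min_cluster_mm3 / voxel_volume_mm3 - 1e-9))


@dataclass
class StatMaps:
    statistic: ScalarVolume
    p: ScalarVolume
    fdr_reject: BinaryMask | None = None
    surviving: BinaryMask | None = None
    clusters: pd.DataFrame | None = None
    config: WBSSConfig | None = None


def voxelwise_group_test(group_a, group_b, cfg: WBSSConfig = WBSSConfig(),
                         mask: BinaryMask | None = None) -> StatMaps:
    """Per-voxel two-sample t statistic and p value (A minus B orientation).

    Voxels with zero variance in both groups get t = 0, p = 1 when the means
    agree (and +-inf, p = 0 when they differ); voxels non-finite in any
    subject are excluded (NaN), and do not count toward the FDR family.
    """
    a = [v for v in group_a]
    b = [v for v in group_b]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >=2 subjects per group")
    grid = a[0].grid
    for v in a[1:] + b:
        grid.require_compatible(v.grid)
    xa = np.stack([v.values.reshape(-1) for v in a])
    xb = np.stack([v.values.reshape(-1) for v in b])
    na, nb = xa.shape[0], xb.shape[0]
    valid = np.isfinite(xa).all(axis=0) & np.isfinite(xb).all(axis=0)
    if mask is not None:
        grid.require_compatible(mask.grid)
        valid &= mask.values.reshape(-1)
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    diff = ma - mb
    with np.errstate(invalid="ignore", divide="ignore"):
        if cfg.test == "student_t":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full(se.shape, float(na + nb - 2))
        else:
            se = np.sqrt(va / na + vb / nb)
            num = (va / na + vb / nb) ** 2
            den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            df = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
        t = diff / se
    # degenerate voxels: zero pooled variance
    degen = valid & ~np.isfinite(t)
    t[degen & (diff == 0)] = 0.0
    t[degen & (diff > 0)] = np.inf
    t[degen & (diff < 0)] = -np.inf
    if cfg.tail == "two_sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif cfg.tail == "upper":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    p = np.where(np.isfinite(t) | np.isinf(t), p, np.nan)
    p[degen & (diff == 0)] = 1.0
    t[~valid] = np.nan
    p[~valid] = np.nan
    shape = grid.shape
    return StatMaps(statistic=ScalarVolume(grid, t.reshape(shape)),
                    p=ScalarVolume(grid, p.reshape(shape)), config=cfg)


def fdr_threshold(p: ScalarVolume, mask: BinaryMask, alpha: float = 0.05,
                  method: str = "fdr_bh") -> BinaryMask:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) rejection mask over the
    finite in-mask p values; the family size m counts tested voxels only."""
    p.grid.require_compatible(mask.grid)
    if mask.n_voxels == 0:
        raise EmptyMaskError("FDR mask is empty")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    flat_p = p.values[mask.values]
    tested = np.isfinite(flat_p)
    if (flat_p[tested] < -1e-12).any() or (flat_p[tested] > 1 + 1e-12).any():
        raise InvalidParameterError("p values must lie in [0, 1]")
    reject_flat = np.zeros(flat_p.shape, dtype=bool)
    if tested.any():
        reject_flat[tested] = multipletests(flat_p[tested], alpha=alpha, method=method)[0]
    out = np.zeros(p.grid.shape, dtype=bool)
    out[mask.values] = reject_flat
    return BinaryMask(p.grid, out)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def cluster_filter(mask: BinaryMask, cfg: WBSSConfig = WBSSConfig(),
                   statistic: ScalarVolume | None = None):
    """Drop connected components smaller than the mm^3 threshold.

    Returns (surviving mask, cluster table sorted by size descending, with
    peak |statistic| voxel and its MNI mm coordinate when a statistic map is
    supplied).
    """
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[cfg.connectivity])
    labels, n_comp = ndimage.label(mask.values, structure=structure)
    voxvol = mask.grid.voxel_volume_mm3
    min_vox = cfg.min_cluster_voxels(voxvol)
    surviving = np.zeros(mask.grid.shape, dtype=bool)
    rows = []
    if n_comp:
        sizes = np.bincount(labels.reshape(-1))[1:]        # component 1..n
        for comp in np.nonzero(sizes >= min_vox)[0] + 1:
            comp_mask = labels == comp
            surviving |= comp_mask
            size = int(sizes[comp - 1])
            row = dict(label=int(comp), size_voxels=size, size_mm3=size * voxvol,
                       peak_statistic=np.nan, peak_x_mm=np.nan, peak_y_mm=np.nan,
                       peak_z_mm=np.nan)
            if statistic is not None:
                vals = np.where(comp_mask, np.abs(statistic.values), -np.inf)
                peak = np.unravel_index(int(np.argmax(vals)), mask.grid.shape)
                row["peak_statistic"] = float(statistic.values[peak])
                row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"] = (
                    float(c) for c in mask.grid.world_of(peak))
            rows.append(row)
    table = pd.DataFrame(rows, columns=["label", "size_voxels", "size_mm3",
                                        "peak_statistic", "peak_x_mm", "peak_y_mm",
                                        "peak_z_mm"])
    table = table.sort_values("size_voxels", ascending=False).reset_index(drop=True)
    return BinaryMask(mask.grid, surviving), table


def run_wbss(group_a, group_b, mask: BinaryMask,
             cfg: WBSSConfig = WBSSConfig()) -> StatMaps:
    """Full chain: voxel-wise test -> FDR -> cluster-size filtering."""
    sm = voxelwise_group_test(group_a, group_b, cfg, mask=mask)
    sm.fdr_reject = fdr_threshold(sm.p, mask, cfg.alpha, cfg.fdr_method)
    sm.surviving, sm.clusters = cluster_filter(sm.fdr_reject, cfg, statistic=sm.statistic)
    return sm


def modality_overlap(mask_a: BinaryMask, mask_b: BinaryMask):
    """Partition of A union B into (A only, B only, intersection)."""
    mask_a.grid.require_compatible(mask_b.grid)
    a, b = mask_a.values, mask_b.values
    return (BinaryMask(mask_a.grid, a & ~b),
            BinaryMask(mask_a.grid, b & ~a),
            BinaryMask(mask_a.grid, a & b))
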