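"""Published reference operating points for the five dementia syndromes.

The reference cohort's classification results are printed as rounded
percentages (sensitivity / specificity / accuracy) per syndrome, per
modality set, for both evaluation protocols. Because the underlying
confusion counts are integers, each printed accuracy cell is an arithmetic
consequence of its printed sensitivity/specificity and the group sizes —
tp = round(sens * n_pos), tn = round(spec * n_neg),
acc = (tp + tn) / (n_pos + n_neg) — and each caption "average accuracy" is
the unweighted mean of its five syndrome cells. This module ships those
printed values and the reconstruction helpers so the identities can be
recomputed rather than trusted.

Modality sets: "PET" (SUVR features only), "MRI" (rCBF + FA), "PET/MRI"
(all three parameters).
"""
from __future__ import annotations

import numpy as np

from .classify import ConfusionSummary

#: reference cohort sizes (76 subjects in total)
REFERENCE_GROUP_SIZES = {"SCD": 10, "AD": 28, "bvFTD": 10, "svPPA": 8,
                         "nfvPPA": 11, "lvPPA": 9}

MODALITY_SETS = ("PET/MRI", "PET", "MRI")

# A1 protocol: (sensitivity %, specificity %, accuracy %) per syndrome,
# per modality set, for the training comparison vs SCD and for the frozen
# hyperplane applied vs all remaining subjects.
A1_REFERENCE = {
    "PET/MRI": {
        "AD":     {"vs_scd": (82.1, 100.0, 86.8), "vs_all": (82.1, 79.2, 80.3)},
        "bvFTD":  {"vs_scd": (100.0, 100.0, 100.0), "vs_all": (100.0, 80.3, 82.9)},
        "svPPA":  {"vs_scd": (87.5, 100.0, 94.4), "vs_all": (87.5, 91.2, 90.8)},
        "nfvPPA": {"vs_scd": (63.6, 100.0, 81.0), "vs_all": (63.6, 61.5, 61.8)},
        "lvPPA":  {"vs_scd": (88.9, 100.0, 94.7), "vs_all": (88.9, 73.2, 75.0)},
    },
    "PET": {
        "AD":     {"vs_scd": (85.7, 100.0, 89.5), "vs_all": (85.7, 83.3, 84.2)},
        "bvFTD":  {"vs_scd": (100.0, 100.0, 100.0), "vs_all": (100.0, 80.3, 82.9)},
        "svPPA":  {"vs_scd": (100.0, 100.0, 100.0), "vs_all": (100.0, 89.7, 90.8)},
        "nfvPPA": {"vs_scd": (72.7, 90.0, 81.0), "vs_all": (72.7, 50.8, 53.9)},
        "lvPPA":  {"vs_scd": (77.8, 100.0, 89.5), "vs_all": (77.8, 79.1, 78.9)},
    },
    "MRI": {
        "AD":     {"vs_scd": (67.9, 100.0, 76.3), "vs_all": (67.9, 62.5, 64.5)},
        "bvFTD":  {"vs_scd": (90.0, 100.0, 95.0), "vs_all": (90.0, 78.8, 80.3)},
        "svPPA":  {"vs_scd": (75.0, 100.0, 88.9), "vs_all": (75.0, 86.8, 85.5)},
        "nfvPPA": {"vs_scd": (63.6, 100.0, 81.0), "vs_all": (63.6, 64.6, 64.5)},
        "lvPPA":  {"vs_scd": (88.9, 100.0, 94.7), "vs_all": (88.9, 55.2, 59.2)},
    },
}

#: printed caption averages for A1: modality set -> (vs SCD, vs all)
A1_REFERENCE_AVERAGES = {"PET/MRI": (91.4, 78.2), "PET": (92.0, 78.1),
                         "MRI": (87.1, 70.8)}

# A2 protocol "summary" rows: accuracy % per syndrome and the printed
# across-syndrome average accuracy per modality set.
A2_REFERENCE_SUMMARY_ACCURACY = {
    "PET/MRI": {"AD": 75.1, "bvFTD": 82.6, "svPPA": 95.7, "nfvPPA": 55.4, "lvPPA": 74.8},
    "PET":     {"AD": 84.2, "bvFTD": 92.2, "svPPA": 96.1, "nfvPPA": 50.9, "lvPPA": 77.1},
    "MRI":     {"AD": 68.3, "bvFTD": 78.2, "svPPA": 82.9, "nfvPPA": 57.1, "lvPPA": 58.7},
}

A2_REFERENCE_AVERAGES = {"PET/MRI": 76.7, "PET": 80.1, "MRI": 69.0}

#: printed composite categorization percentage over the 76 subjects
REFERENCE_COMPOSITE_PERCENT = 95.0


def comparison_group_sizes(entity: str, comparison: str) -> tuple[int, int]:
    """(n_pos, n_neg) for one reference comparison: negatives are the SCD
    group (vs_scd) or all remaining subjects including SCD (vs_all)."""
    n_pos = REFERENCE_GROUP_SIZES[entity]
    total = sum(REFERENCE_GROUP_SIZES.values())
    n_neg = REFERENCE_GROUP_SIZES["SCD"] if comparison == "vs_scd" else total - n_pos
    return n_pos, n_neg


def reconstruct_a1_confusions() -> dict:
    """Integer confusion matrices implied by the printed A1 rates.

    Returns {modality_set: {entity: {comparison: ConfusionSummary}}}; the
    accuracies of these reconstructions are the quantities compared against
    the printed accuracy cells.
    """
    out: dict = {}
    for mset, per_entity in A1_REFERENCE.items():
        out[mset] = {}
        for entity, comparisons in per_entity.items():
            out[mset][entity] = {}
            for comparison, (sens, spec, _acc) in comparisons.items():
                n_pos, n_neg = comparison_group_sizes(entity, comparison)
                out[mset][entity][comparison] = ConfusionSummary.from_rates(
                    sens, spec, n_pos, n_neg)
    return out


def reconstructed_a1_accuracies() -> dict:
    """Accuracy (%) of every reconstructed A1 cell, keyed like A1_REFERENCE."""
    recon = reconstruct_a1_confusions()
    return {mset: {entity: {cmp_: 100.0 * cs.accuracy
                            for cmp_, cs in per_cmp.items()}
                   for entity, per_cmp in per_entity.items()}
            for mset, per_entity in recon.items()}


def caption_average_accuracies() -> dict:
    """Unweighted five-syndrome means of the reconstructed A1 accuracies and
    of the printed A2 summary accuracies, rounded as printed (one decimal)."""
    a1 = reconstructed_a1_accuracies()
    out = {}
    for mset in MODALITY_SETS:
        for comparison in ("vs_scd", "vs_all"):
            cells = [a1[mset][e][comparison] for e in A1_REFERENCE[mset]]
            out[f"a1_{comparison}_{mset}"] = float(np.mean(cells))
        out[f"a2_summary_{mset}"] = float(
            np.mean(list(A2_REFERENCE_SUMMARY_ACCURACY[mset].values())))
    return out
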