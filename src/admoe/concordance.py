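"""Matching subtype solutions across modalities and Dice concordance.

Two independent subtype solutions (one per morphological measure) label the
same patients with arbitrary cluster indices, so comparing them requires a
one-to-one pairing of subtypes first.  The pairing maximizes total subject
overlap via optimal bipartite assignment on the K x K contingency table;
agreement of each matched pair is then the Dice score of its member sets,

    Dice(A, B) = 2 |A ∩ B| / (|A| + |B|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .moe import SubtypeSolution
from .simulate import SyntheticTruth


@dataclass
class MatchResult:
    """Optimal pairing of two K-subtype solutions on their common subjects.

    ``mapping[k]`` (1-based) is the modality-B subtype paired with modality-A
    subtype ``k``; ``dice`` holds the per-pair Dice scores in A-subtype
    order; ``contingency[i, j]`` counts common subjects with A-label i+1 and
    B-label j+1; ``row_proportions`` normalizes contingency rows.
    """

    mapping: dict[int, int]
    dice: np.ndarray
    contingency: np.ndarray
    row_proportions: np.ndarray
    common_subjects: list[str]

    @property
    def K(self) -> int:
        return self.contingency.shape[0]

    @property
    def total_overlap(self) -> int:
        return int(
            sum(self.contingency[a - 1, b - 1] for a, b in self.mapping.items())
        )


def dice_score(set_a: set, set_b: set) -> float:
    """2 |A ∩ B| / (|A| + |B|); two empty sets give 0 with a warning."""
    a, b = set(set_a), set(set_b)
    denom = len(a) + len(b)
    if denom == 0:
        warnings.warn("Dice of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(a & b) / denom


def match_subtypes(sol_a: SubtypeSolution, sol_b: SubtypeSolution) -> MatchResult:
    """Pair subtypes of two solutions by maximum total subject overlap.

    Restricted to subjects present in both solutions (subjects seen by only
    one modality are excluded).  The assignment maximizes the summed
    contingency counts; per-pair Dice is computed on the matched member
    sets over the common subjects.
    """
    if sol_a.K != sol_b.K:
        raise ValueError(f"solutions have different K: {sol_a.K} vs {sol_b.K}")
    K = sol_a.K
    labels_a = dict(zip(sol_a.subject_ids, sol_a.labels))
    labels_b = dict(zip(sol_b.subject_ids, sol_b.labels))
    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValueError("no common subjects between the two solutions")
    contingency = np.zeros((K, K), dtype=int)
    for s in common:
        contingency[labels_a[s] - 1, labels_b[s] - 1] += 1
    row_ind, col_ind = linear_sum_assignment(-contingency)
    mapping = {int(a) + 1: int(b) + 1 for a, b in zip(row_ind, col_ind)}

    dice = np.zeros(K)
    common_set = set(common)
    for a_label, b_label in mapping.items():
        members_a = {s for s in common_set if labels_a[s] == a_label}
        members_b = {s for s in common_set if labels_b[s] == b_label}
        if members_a or members_b:
            dice[a_label - 1] = dice_score(members_a, members_b)
        else:
            dice[a_label - 1] = 0.0

    row_sums = contingency.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_props = np.where(row_sums > 0, contingency / row_sums, 0.0)
    return MatchResult(
        mapping=mapping,
        dice=dice,
        contingency=contingency,
        row_proportions=row_props,
        common_subjects=common,
    )


def concordance_report(
    match: MatchResult,
    sol_a: SubtypeSolution | None = None,
    sol_b: SubtypeSolution | None = None,
    truth: SyntheticTruth | None = None,
) -> dict:
    """Summarize a match: per-pair Dice, range, proportions, optional ARI.

    When ground truth from a synthetic cohort is supplied (and the two
    solutions are passed), the report adds the adjusted Rand index of each
    solution against its modality's effective latent subtype.  A solution
    that collapses all subjects into one subtype is flagged as imbalanced.
    """
    report: dict = {
        "mapping": dict(match.mapping),
        "dice_per_pair": match.dice.tolist(),
        "dice_min": float(match.dice.min()),
        "dice_max": float(match.dice.max()),
        "dice_mean": float(match.dice.mean()),
        "contingency": match.contingency.tolist(),
        "row_proportions": match.row_proportions.tolist(),
        "n_common": len(match.common_subjects),
    }
    occupied_rows = int((match.contingency.sum(axis=1) > 0).sum())
    occupied_cols = int((match.contingency.sum(axis=0) > 0).sum())
    report["imbalanced"] = occupied_rows == 1 or occupied_cols == 1
    if truth is not None:
        truth_ids = list(truth.subject_ids)
        for sol, key in ((sol_a, "ari_a"), (sol_b, "ari_b")):
            if sol is None:
                continue
            z = dict(zip(truth_ids, truth.labels(sol.modality)))
            keep = [i for i, s in enumerate(sol.subject_ids) if s in z]
            pred = [sol.labels[i] for i in keep]
            true = [z[sol.subject_ids[i]] for i in keep]
            report[key] = float(adjusted_rand_score(true, pred))
    return report
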