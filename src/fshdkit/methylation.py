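"""4q genotyping logic and the four-CpG methylation decision-tree classifier.

Bisulfite methylation at two D4Z4 regions feeds a published decision tree
that separates FSHD-consistent hypomethylation from control-range profiles
using four CpG sites, tested in a fixed order of relevance:
DUX4-PAS CpG 6, DUX4-PAS CpG 3, DR1 CpG 1, DR1 CpG 22.  All comparisons
are inclusive (a value exactly at a threshold takes the <= branch), and
the leaves carry the decision-node indices used in diagnostic reports:

* node 3  — PAS CpG6 <= 0.78                                  -> FSHD
* node 7  — CpG6 > 0.78, PAS CpG3 <= 0.34, DR1 CpG1 <= 0.53   -> FSHD
* node 8  — CpG6 > 0.78, PAS CpG3 <= 0.34, DR1 CpG1 > 0.53    -> CTRL
* node 10 — CpG6 > 0.78, PAS CpG3 > 0.34, DR1 CpG22 <= 0.99   -> CTRL
* node 11 — CpG6 > 0.78, PAS CpG3 > 0.34, DR1 CpG22 > 0.99    -> CTRL

Subjects without DUX4-PAS data (4qB/4qB genotypes, from which the PAS
region cannot be amplified) are assigned node 10 with label
``unclassifiable``.

One branch combination (CpG3 > 0.34 with DR1 CpG1 <= 0.53) is never
exercised by any labelled subject in the reference data; by default it
falls through to the CpG22 test, but the behaviour is configurable
(:attr:`ClassifierConfig.unobserved_branch_policy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import MethylationProfile, Subject

__all__ = [
    "FSHD",
    "CTRL",
    "UNCLASSIFIABLE",
    "FEATURE_NAMES",
    "ClassifierConfig",
    "ClassifierResult",
    "AmplificationResult",
    "ConcordanceSummary",
    "genotype_4q",
    "extract_features",
    "classify",
    "classify_subject",
    "validate_against_labels",
    "recover_thresholds",
]

FSHD = "FSHD"
CTRL = "CTRL"
UNCLASSIFIABLE = "unclassifiable"

#: Classifier features in the tree's order of relevance.
FEATURE_NAMES = ("pas_cpg6", "pas_cpg3", "dr1_cpg1", "dr1_cpg22")

#: Node used when the required features are unavailable.
MISSING_DATA_NODE = 10

FSHD_NODES = frozenset({3, 7})
CTRL_NODES = frozenset({8, 10, 11})


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds (fractions) and the unobserved-branch policy."""

    t_pas_cpg6: float = 0.78
    t_pas_cpg3: float = 0.34
    t_dr1_cpg1: float = 0.53
    t_dr1_cpg22: float = 0.99
    unobserved_branch_policy: str = "fall_through_to_cpg22"

    def __post_init__(self):
        for name in ("t_pas_cpg6", "t_pas_cpg3", "t_dr1_cpg1", "t_dr1_cpg22"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.unobserved_branch_policy not in {
            "fall_through_to_cpg22",
            "report_unclassifiable",
        }:
            raise ValueError(f"bad policy {self.unobserved_branch_policy!r}")

    @property
    def thresholds(self) -> tuple[float, float, float, float]:
        return (self.t_pas_cpg6, self.t_pas_cpg3, self.t_dr1_cpg1, self.t_dr1_cpg22)


@dataclass(frozen=True)
class ClassifierResult:
    node: int
    label: str
    features_used: tuple[float, float, float, float] | None


@dataclass(frozen=True)
class AmplificationResult:
    """PCR amplification status of the 4qA-specific PAS region and 4qB primers."""

    pas_amplified: bool
    b_amplified: bool


def genotype_4q(amp: AmplificationResult) -> str:
    """Derive the 4q configuration from the qualitative PCR result.

    Amplification of the DUX4-PAS region indicates at least one 4qA allele;
    the 4qB allele is detected by its own primer pair.
    """
    if amp.pas_amplified and amp.b_amplified:
        return "4qA/4qB"
    if amp.pas_amplified:
        return "4qA/4qA"
    if amp.b_amplified:
        return "4qB/4qB"
    raise ValueError("failed genotyping: neither 4qA nor 4qB amplified")


def extract_features(profile: MethylationProfile) -> tuple[float, float, float, float] | None:
    """The four classifier features, or None if any required site is absent.

    Site indices are 1-based within each region (PAS CpG 6, PAS CpG 3,
    DR1 CpG 1, DR1 CpG 22).
    """
    values = (
        profile.pas_site(6),
        profile.pas_site(3),
        profile.dr1_site(1),
        profile.dr1_site(22),
    )
    if any(v is None for v in values):
        return None
    return values  # type: ignore[return-value]


def classify(
    features: Sequence[float] | None,
    config: ClassifierConfig | None = None,
) -> ClassifierResult:
    """Run the decision tree on a feature tuple (pas6, pas3, dr1_1, dr1_22)."""
    config = config or ClassifierConfig()
    if features is None:
        return ClassifierResult(MISSING_DATA_NODE, UNCLASSIFIABLE, None)
    feats = tuple(float(f) for f in features)
    if len(feats) != 4:
        raise ValueError(f"expected 4 features, got {len(feats)}")
    for name, value in zip(FEATURE_NAMES, feats):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"feature {name}={value} outside [0, 1]")
    cpg6, cpg3, cpg1, cpg22 = feats

    if cpg6 <= config.t_pas_cpg6:
        return ClassifierResult(3, FSHD, feats)
    if cpg3 <= config.t_pas_cpg3:
        if cpg1 <= config.t_dr1_cpg1:
            return ClassifierResult(7, FSHD, feats)
        return ClassifierResult(8, CTRL, feats)
    # cpg3 above threshold: the cpg1 <= threshold combination here is never
    # observed in labelled data, so its handling is explicit policy
    if cpg1 <= config.t_dr1_cpg1 and config.unobserved_branch_policy == "report_unclassifiable":
        return ClassifierResult(MISSING_DATA_NODE, UNCLASSIFIABLE, feats)
    if cpg22 <= config.t_dr1_cpg22:
        return ClassifierResult(10, CTRL, feats)
    return ClassifierResult(11, CTRL, feats)


def classify_subject(subject: Subject, config: ClassifierConfig | None = None) -> ClassifierResult:
    return classify(extract_features(subject.methylation), config)


@dataclass(frozen=True)
class ConcordanceSummary:
    n_total: int
    n_match_node: int
    n_match_label: int
    mismatches: tuple[tuple[str, int | None, int, str | None, str], ...] = ()
    # each mismatch: (subject_id, recorded_node, predicted_node,
    #                 recorded_label, predicted_label)

    @property
    def all_concordant(self) -> bool:
        return self.n_match_node == self.n_total and self.n_match_label == self.n_total


def validate_against_labels(
    cohort: Iterable[Subject],
    config: ClassifierConfig | None = None,
) -> ConcordanceSummary:
    """Compare classifier output with the (node, label) recorded per subject.

    Subjects without a recorded node or label are skipped — only labelled
    rows enter the concordance counts.
    """
    n_total = n_node = n_label = 0
    mismatches = []
    for subject in cohort:
        if subject.recorded_node is None or subject.recorded_label is None:
            continue
        result = classify_subject(subject, config)
        n_total += 1
        node_ok = result.node == subject.recorded_node
        label_ok = result.label == subject.recorded_label
        n_node += node_ok
        n_label += label_ok
        if not (node_ok and label_ok):
            mismatches.append(
                (subject.subject_id, subject.recorded_node, result.node,
                 subject.recorded_label, result.label)
            )
    return ConcordanceSummary(n_total, n_node, n_label, tuple(mismatches))


# ---------------------------------------------------------------------------
# Threshold recovery (parameter-recovery oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveredThresholds:
    t_pas_cpg6: float | None = None
    t_pas_cpg3: float | None = None
    t_dr1_cpg1: float | None = None
    t_dr1_cpg22: float | None = None

    def as_tuple(self):
        return (self.t_pas_cpg6, self.t_pas_cpg3, self.t_dr1_cpg1, self.t_dr1_cpg22)


def _best_split(values: np.ndarray, is_left_class: np.ndarray) -> float | None:
    """Gini-optimal 1-D split; None when either class is empty.

    Candidates are midpoints between consecutive distinct values, so the
    result is invariant to row duplication.
    """
    order = np.argsort(values, kind="stable")
    v, y = values[order], is_left_class[order]
    if y.all() or not y.any():
        return None
    uniq = np.unique(v)
    if uniq.size < 2:
        return None
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_score = None, np.inf
    n = v.size
    for t in candidates:
        left = v <= t
        n_l = left.sum()
        n_r = n - n_l
        if n_l == 0 or n_r == 0:
            continue
        p_l = y[left].mean()
        p_r = y[~left].mean()
        gini = (n_l / n) * 2 * p_l * (1 - p_l) + (n_r / n) * 2 * p_r * (1 - p_r)
        # prefer the candidate with the widest margin on ties (stable for
        # perfectly separated data); gini ties broken by first occurrence
        if gini < best_score - 1e-12:
            best_score, best_t = gini, float(t)
    return best_t


def recover_thresholds(
    cohort: Sequence[Subject],
    max_depth: int = 4,
) -> RecoveredThresholds:
    """Estimate the four decision thresholds from labelled subjects.

    Two modes:

    * node-annotated — when every classifiable subject carries a recorded
      decision node, each threshold is recovered by a best-split search on
      the subjects whose decision path reaches that test (CpG6 on all,
      CpG3 on non-node-3, CpG1 on nodes {7, 8}, CpG22 on nodes {10, 11});
    * label-only — with only FSHD/CTRL labels the tree is rebuilt greedily
      in the stated feature order.  The CpG22 split separates two
      control-side leaves and is unidentifiable from class labels; it is
      returned as None in this mode.

    Raises ``ValueError("cannot fit")`` when the input carries a single
    class (or is empty).
    """
    rows = []
    for s in cohort:
        feats = extract_features(s.methylation)
        if feats is None:
            continue
        rows.append((feats, s.recorded_node, s.recorded_label))
    if not rows:
        raise ValueError("cannot fit: no classifiable subjects")
    X = np.array([r[0] for r in rows], dtype=float)
    labels = [r[2] for r in rows]
    if len({l for l in labels if l is not None}) < 2:
        raise ValueError("cannot fit: single-class input")

    nodes = [r[1] for r in rows]
    if all(n is not None for n in nodes):
        node_arr = np.array(nodes)
        t6 = _best_split(X[:, 0], node_arr == 3)
        rest = node_arr != 3
        t3 = _best_split(X[rest, 1], np.isin(node_arr[rest], (7, 8)))
        at_cpg1 = np.isin(node_arr, (7, 8))
        t1 = _best_split(X[at_cpg1, 2], node_arr[at_cpg1] == 7)
        at_cpg22 = np.isin(node_arr, (10, 11))
        t22 = _best_split(X[at_cpg22, 3], node_arr[at_cpg22] == 10)
        return RecoveredThresholds(t6, t3, t1, t22)

    # label-only greedy reconstruction in the stated feature order
    y_fshd = np.array([l == FSHD for l in labels])
    t6 = _best_split(X[:, 0], y_fshd)
    t3 = t1 = None
    if t6 is not None and max_depth >= 2:
        right = X[:, 0] > t6
        t3 = _best_split(X[right, 1], y_fshd[right])
        if t3 is not None and max_depth >= 3:
            at_cpg1 = right & (X[:, 1] <= t3)
            t1 = _best_split(X[at_cpg1, 2], y_fshd[at_cpg1])
    return RecoveredThresholds(t6, t3, t1, None)
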