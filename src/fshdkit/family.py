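"""Segregation analysis, permissive-allele reporting and genetic categorization.

FSHD genetics distinguishes subjects by the size of their shortest
disease-permissive (4qA) D4Z4 allele and by pathogenic variants in
chromatin-modifier genes:

* 1-10 RU              -> FSHD1 (contraction-driven); with a modifier
                          variant on top -> compound FSHD1 + modifier;
* 11-20 RU + variant   -> FSHD2 (modifier-driven hypomethylation);
* > 20 RU + variant with FSHD-consistent hypomethylation
                        -> atypical presentation;
* anything else        -> unexplained by these rules.

Variant origin is traced through the pedigree: de novo requires both
parents genotyped negative; a carrier parent establishes inheritance; an
untested parent otherwise leaves the origin undetermined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import OVER_20, Genotype4q, Pedigree, Subject
from .methylation import (
    FEATURE_NAMES,
    ClassifierConfig,
    classify_subject,
    extract_features,
)

__all__ = [
    "SegregationCall",
    "CategoryRules",
    "FSHD1",
    "FSHD1_PLUS_MODIFIER",
    "FSHD2",
    "ATYPICAL_OVER20",
    "UNEXPLAINED",
    "segregate",
    "report_permissive_alleles",
    "categorize",
    "family_summary",
]

FSHD1 = "FSHD1"
FSHD1_PLUS_MODIFIER = "FSHD1_plus_modifier"
FSHD2 = "FSHD2"
ATYPICAL_OVER20 = "atypical_over20_with_variant"
UNEXPLAINED = "unexplained"

ORIGINS = ("inherited_maternal", "inherited_paternal", "de_novo", "undetermined")


@dataclass(frozen=True)
class SegregationCall:
    variant_key: str
    subject_id: str
    origin: str

    def __post_init__(self):
        if self.origin not in ORIGINS:
            raise ValueError(f"bad origin {self.origin!r}")


def segregate(
    pedigree: Pedigree,
    carrier_status: Mapping[str, bool | None],
    variant_key: str,
) -> list[SegregationCall]:
    """Assign a variant origin to every carrier in a family.

    ``carrier_status`` maps subject ids to True (carrier), False (tested
    negative) or None/absent (untested).  A confirmed carrier parent
    establishes the origin even when the other parent is untested; de novo
    requires both parents present in the pedigree and genotyped negative;
    otherwise the origin is ``undetermined`` (including the ambiguous
    both-parents-carrier case).
    """
    calls = []
    for member in pedigree.members:
        if carrier_status.get(member.subject_id) is not True:
            continue
        father, mother = member.father_id, member.mother_id
        f_status = carrier_status.get(father) if father is not None else None
        m_status = carrier_status.get(mother) if mother is not None else None
        if f_status is True and m_status is True:
            origin = "undetermined"  # transmitting parent ambiguous
        elif m_status is True:
            origin = "inherited_maternal"
        elif f_status is True:
            origin = "inherited_paternal"
        elif f_status is False and m_status is False:
            origin = "de_novo"
        else:
            origin = "undetermined"
        calls.append(SegregationCall(variant_key, member.subject_id, origin))
    return calls


@dataclass(frozen=True)
class CategoryRules:
    """RU intervals defining the genetic categories (all bounds inclusive)."""

    fshd1_range: tuple[int, int] = (1, 10)
    borderline_range: tuple[int, int] = (8, 10)
    fshd2_range: tuple[int, int] = (11, 20)
    #: both alleles of a double-4qA genotype are reported when each is <= this
    both_reported_max_ru: int = 20

    def __post_init__(self):
        lo, hi = self.borderline_range
        f_lo, f_hi = self.fshd1_range
        if not (f_lo <= lo and hi <= f_hi):
            raise ValueError("borderline_range must lie within fshd1_range")


def report_permissive_alleles(
    genotype: Genotype4q,
    rules: CategoryRules | None = None,
) -> list:
    """The reportable disease-permissive (4qA) allele sizes, ascending.

    4qA/4qB genotypes report the single 4qA allele; 4qA/4qA genotypes
    report the shortest allele, or both when both are within the
    FSHD-compatible range (<= 20 RU); 4qB/4qB genotypes report nothing.
    """
    rules = rules or CategoryRules()
    permissive = genotype.permissive_alleles()
    if not permissive:
        return []
    if len(permissive) == 1:
        return [permissive[0].size_ru]
    sizes = [a.size_ru for a in permissive]
    numeric = [a.numeric_size for a in permissive]
    if all(n is not None and n <= rules.both_reported_max_ru for n in numeric):
        return sizes
    return [sizes[0]]


def _shortest_permissive_ru(genotype: Genotype4q | None) -> float | None:
    """Numeric size of the shortest 4qA allele (inf for >20), None if no 4qA."""
    if genotype is None:
        return None
    permissive = genotype.permissive_alleles()
    if not permissive:
        return None
    sizes = [a.numeric_size for a in permissive if a.numeric_size is not None]
    return min(sizes) if sizes else None


def categorize(
    subject: Subject,
    has_pathogenic_modifier_variant: bool,
    methylation_label: str | None = None,
    rules: CategoryRules | None = None,
) -> str:
    """Assign the single genetic category for a subject.

    ``has_pathogenic_modifier_variant`` is expected to reflect an ACMG
    label of pathogenic/likely-pathogenic for a carried panel variant
    (callers may widen to VUS for exploratory use);
    ``methylation_label`` is the decision-tree class (FSHD/CTRL/...).
    """
    rules = rules or CategoryRules()
    shortest = _shortest_permissive_ru(subject.genotype)
    f_lo, f_hi = rules.fshd1_range
    f2_lo, f2_hi = rules.fshd2_range
    if shortest is not None and f_lo <= shortest <= f_hi:
        return FSHD1_PLUS_MODIFIER if has_pathogenic_modifier_variant else FSHD1
    if shortest is not None and f2_lo <= shortest <= f2_hi:
        return FSHD2 if has_pathogenic_modifier_variant else UNEXPLAINED
    # no permissive allele, unknown size, or > 20 RU
    if has_pathogenic_modifier_variant and methylation_label == "FSHD":
        return ATYPICAL_OVER20
    return UNEXPLAINED


@dataclass(frozen=True)
class FamilyMemberSummary:
    subject_id: str
    relation: str
    affected: str
    configuration: str | None
    reported_alleles: tuple
    variants: tuple[str, ...]
    origins: tuple[str, ...]
    node: int
    label: str
    category: str
    features: tuple | None


@dataclass(frozen=True)
class FamilySummary:
    family_id: str
    members: tuple[FamilyMemberSummary, ...]
    #: per classifier feature, the subject id(s) holding the family minimum
    feature_minima: dict

    def minimum_holder(self, feature: str) -> tuple[str, ...]:
        return self.feature_minima[feature]


def family_summary(
    subjects: Sequence[Subject],
    pedigree: Pedigree | None = None,
    segregations: Mapping[str, Mapping[str, str]] | None = None,
    modifier_carriers: Mapping[str, bool] | None = None,
    config: ClassifierConfig | None = None,
    rules: CategoryRules | None = None,
) -> FamilySummary:
    """Integrate genotype, variants, methylation and category for one family.

    ``segregations`` maps subject_id -> {variant_key: origin};
    ``modifier_carriers`` maps subject_id -> carries a pathogenic or
    likely-pathogenic panel variant (defaults to "carries any variant").
    Also reports, per classifier feature, which member(s) hold the family
    minimum — hypomethylation extremes within a family flag the subjects
    in whom multiple molecular events concur.
    """
    family_ids = {s.family_id for s in subjects}
    if len(family_ids) != 1:
        raise ValueError(f"family_summary expects one family, got {sorted(family_ids)}")
    rows = []
    for s in subjects:
        result = classify_subject(s, config)
        has_modifier = (
            modifier_carriers.get(s.subject_id, False)
            if modifier_carriers is not None
            else bool(s.variants)
        )
        origins = tuple(
            (segregations or {}).get(s.subject_id, {}).get(v, "undetermined")
            for v in s.variants
        )
        rows.append(
            FamilyMemberSummary(
                subject_id=s.subject_id,
                relation=s.relation,
                affected=s.affected,
                configuration=None if s.genotype is None else s.genotype.configuration,
                reported_alleles=tuple(
                    report_permissive_alleles(s.genotype, rules) if s.genotype else ()
                ),
                variants=s.variants,
                origins=origins,
                node=result.node,
                label=result.label,
                category=categorize(s, has_modifier, result.label, rules),
                features=extract_features(s.methylation),
            )
        )
    minima: dict[str, tuple[str, ...]] = {}
    for i, feature in enumerate(FEATURE_NAMES):
        values = [(r.features[i], r.subject_id) for r in rows if r.features is not None]
        if not values:
            minima[feature] = ()
            continue
        low = min(v for v, _ in values)
        minima[feature] = tuple(sid for v, sid in values if math.isclose(v, low))
    return FamilySummary(
        family_id=next(iter(family_ids)),
        members=tuple(rows),
        feature_minima=minima,
    )
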