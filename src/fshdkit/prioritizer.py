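"""Variant-prioritization cascade for exome variants in the FSHD gene panel.

Annotated variants pass through a fixed sequence of filters — read coverage,
gene panel membership, consequence class, gnomAD minor-allele frequency, and
absence from the internal reference group — and every failed filter is
recorded, not just the first.  In-silico pathogenicity verdicts never gate
retention (benign-predicted variants are legitimately retained when rare);
they only feed the downstream evidence assignment, as does the
``exceeds_benign_cutoff`` flag raised when a retained variant's population
frequency exceeds its gene's benign cut-off frequency.

Consequence classes are derived from HGVS nomenclature with deterministic
precedence frameshift > nonsense > splicing > inframe_indel > missense;
a missense call annotated as lying in a splicing region keeps its missense
class but is tallied under splicing in type counts.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .core import KNOWN_GENES, AnnotatedVariant, GeneConstraint

__all__ = [
    "DEFAULT_PANEL",
    "VariantClass",
    "PrioritizerConfig",
    "PrioritizationDecision",
    "PrioritizationSummary",
    "classify_variant_type",
    "apply_filters",
    "prioritize_cohort",
]

#: The eight panel genes named in the reference variant inventories:
#: established FSHD genes plus candidate chromatin regulators of D4Z4.
DEFAULT_PANEL = frozenset(
    {"SMCHD1", "DNMT3B", "LRIF1", "CTCF", "DNMT1", "DNMT3A", "EZH2", "SUV39H1"}
)

RETAINED_TYPES = frozenset({"nonsense", "frameshift", "missense", "splicing", "inframe_indel"})


@dataclass(frozen=True)
class VariantClass:
    value: str  # missense | nonsense | frameshift | splicing | inframe_indel | synonymous | other
    in_splicing_region: bool = False

    _VALUES = {"missense", "nonsense", "frameshift", "splicing", "inframe_indel",
               "synonymous", "other"}

    def __post_init__(self):
        if self.value not in self._VALUES:
            raise ValueError(f"bad variant class {self.value!r}")

    @property
    def tally_class(self) -> str:
        """Class used in type tallies: missense-in-splicing-region counts as splicing."""
        if self.value == "missense" and self.in_splicing_region:
            return "splicing"
        return self.value


@dataclass(frozen=True)
class PrioritizerConfig:
    min_coverage: int = 20
    maf_threshold: float = 0.001
    panel: frozenset[str] = DEFAULT_PANEL
    retained_types: frozenset[str] = RETAINED_TYPES
    require_internal_absent: bool = True

    def __post_init__(self):
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError("maf_threshold must lie in (0, 1)")
        object.__setattr__(self, "panel", frozenset(self.panel))
        object.__setattr__(self, "retained_types", frozenset(self.retained_types))


# intronic offset in the coding position, e.g. c.3801+1dup, c.3802-8C>A,
# c.1131+2_1131+5del
_INTRONIC = re.compile(r"c\.[*-]?\d+[+-]\d+")
# single-residue substitution, e.g. p.Val237Ile / p.V237I
_MISSENSE_P = re.compile(
    r"p\.\(?([A-Z][a-z]{2}|[A-Z])\d+([A-Z][a-z]{2}|[A-Z])\)?$"
)


def _label_has(label: str | None, token: str) -> bool:
    return label is not None and token in label.lower()


def classify_variant_type(
    coding_hgvs: str,
    protein_hgvs: str | None = None,
    type_label: str | None = None,
) -> VariantClass:
    """Derive the consequence class from HGVS strings and the annotator label.

    Unparseable nomenclature degrades to class ``other`` with a warning —
    never an exception.
    """
    if not coding_hgvs:
        raise ValueError("coding_hgvs must be non-empty")
    c = coding_hgvs.replace(" ", "")
    p = (protein_hgvs or "").replace(" ", "")
    in_splicing = _label_has(type_label, "splicing") and _label_has(type_label, "missense")

    # frameshift: protein-level fs designation, or the annotator says so
    if "fs" in p or _label_has(type_label, "frameshift"):
        return VariantClass("frameshift", in_splicing)
    # nonsense: direct stop gain without frameshift
    if _label_has(type_label, "nonsense") or _label_has(type_label, "stop_gained"):
        return VariantClass("nonsense", in_splicing)
    if p and re.search(r"(Ter|\*)\)?$", p):
        return VariantClass("nonsense", in_splicing)
    # splicing: intronic offset in the coding position, or a pure splicing label
    if _INTRONIC.search(c) or (_label_has(type_label, "splic") and not in_splicing):
        return VariantClass("splicing", in_splicing)
    # in-frame dup/del/ins with a stated in-frame protein change
    if _label_has(type_label, "inframe"):
        return VariantClass("inframe_indel", in_splicing)
    if re.search(r"(dup|del|ins)", c) and p and "fs" not in p and re.search(r"(dup|del|ins)", p):
        return VariantClass("inframe_indel", in_splicing)
    if _label_has(type_label, "synonymous") or p.endswith("=") or p.endswith("=)"):
        return VariantClass("synonymous", in_splicing)
    if _label_has(type_label, "missense") or _MISSENSE_P.match(p):
        return VariantClass("missense", in_splicing)
    warnings.warn(
        f"unparseable variant nomenclature {coding_hgvs!r} / {protein_hgvs!r}; "
        "classing as 'other'",
        stacklevel=2,
    )
    return VariantClass("other", in_splicing)


def classify_variant(variant: AnnotatedVariant) -> VariantClass:
    return classify_variant_type(variant.coding_hgvs, variant.protein_hgvs, variant.type_label)


@dataclass(frozen=True)
class PrioritizationDecision:
    variant: AnnotatedVariant
    variant_class: VariantClass
    retained: bool
    failed_filters: frozenset[str]
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        assert self.retained == (not self.failed_filters)


def apply_filters(
    variant: AnnotatedVariant,
    config: PrioritizerConfig | None = None,
    constraints: dict[str, GeneConstraint] | None = None,
    variant_class: VariantClass | None = None,
) -> PrioritizationDecision:
    """Run the filter cascade on one variant, recording every failure.

    Filter order: coverage, panel, type, gnomAD MAF (strict ``<``; an
    absent frequency passes), internal-reference absence.  A variant whose
    gnomAD frequency exceeds its gene's benign cut-off frequency receives
    the ``exceeds_benign_cutoff`` flag (consumed by BS1 downstream).
    """
    config = config or PrioritizerConfig()
    vclass = variant_class or classify_variant(variant)
    failed = []
    if variant.coverage < config.min_coverage:
        failed.append("coverage")
    if variant.gene not in config.panel:
        failed.append("panel")
    if vclass.value not in config.retained_types:
        failed.append("type")
    if variant.gnomad_af is not None and variant.gnomad_af >= config.maf_threshold:
        failed.append("maf")
    if config.require_internal_absent and variant.internal_ref_count > 0:
        failed.append("internal_reference")

    flags = set()
    constraint = (constraints or {}).get(variant.gene)
    if constraint is None:
        if constraints is not None and variant.gene in config.panel:
            warnings.warn(f"no constraint row for gene {variant.gene!r}", stacklevel=2)
    elif variant.gnomad_af is not None and variant.gnomad_af > constraint.benign_cutoff_freq:
        flags.add("exceeds_benign_cutoff")

    return PrioritizationDecision(
        variant=variant,
        variant_class=vclass,
        retained=not failed,
        failed_filters=frozenset(failed),
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class PrioritizationSummary:
    decisions: tuple[PrioritizationDecision, ...]
    retained: tuple[PrioritizationDecision, ...]
    per_gene: dict
    per_type: dict
    n_known_gene: int
    n_candidate_gene: int
    n_distinct_patients: int

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def prioritize_cohort(
    variants,
    config: PrioritizerConfig | None = None,
    constraints: dict[str, GeneConstraint] | None = None,
) -> PrioritizationSummary:
    """Filter a variant table and tally the retained set.

    Tallies: per gene; known ({SMCHD1, DNMT3B, LRIF1}) vs candidate genes;
    per consequence class with the missense-in-splicing-region rule; and
    the number of distinct carrier subjects over retained variants.
    """
    config = config or PrioritizerConfig()
    decisions = tuple(apply_filters(v, config, constraints) for v in variants)
    retained = tuple(d for d in decisions if d.retained)
    per_gene = Counter(d.variant.gene for d in retained)
    per_type = Counter(d.variant_class.tally_class for d in retained)
    patients = {sid for d in retained for sid in d.variant.carriers}
    n_known = sum(1 for d in retained if d.variant.gene in KNOWN_GENES)
    return PrioritizationSummary(
        decisions=decisions,
        retained=retained,
        per_gene=dict(per_gene),
        per_type=dict(per_type),
        n_known_gene=n_known,
        n_candidate_gene=len(retained) - n_known,
        n_distinct_patients=len(patients),
    )
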