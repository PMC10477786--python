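"""Computational ACMG evidence assignment and the five-tier combiner.

Evidence codes are assigned from the annotations the pipeline already
carries — no external database is queried:

* PVS1 — null variant (frameshift, nonsense, canonical +/-1,2 splice) in a
  gene under significant loss-of-function constraint (LoF Z >= threshold);
* PS2 — confirmed de novo occurrence (both parents genotyped negative);
* PM1 — located in an annotated functional domain or regulatory region;
* PM2 — absent from gnomAD or below the rarity threshold;
* PP2 — missense variant in a gene under significant missense constraint;
* PP3 / BP4 — mapped from the consumed in-silico verdict, with strength
  scaled by verdict confidence (strong/moderate pathogenic -> PP3 at that
  strength; supporting-benign -> BP4);
* BS1 — population frequency above the gene's benign cut-off frequency.

The combiner encodes the 2015 rule-based evidence-combination table as
data: each tier is a list of minimal requirement profiles over strength
counts, so alternative tables can be swapped in.  A criteria set matching
both a pathogenic-side and a benign-side combination is conflicting and
yields VUS, as does insufficient evidence.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import AnnotatedVariant, GeneConstraint
from .prioritizer import PrioritizationDecision, VariantClass, classify_variant

__all__ = [
    "PATHOGENIC",
    "LIKELY_PATHOGENIC",
    "VUS",
    "LIKELY_BENIGN",
    "BENIGN",
    "Criterion",
    "CriteriaSet",
    "AcmgConfig",
    "AcmgResult",
    "assign_criteria",
    "combine",
    "classify_all",
]

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
VUS = "vus"
LIKELY_BENIGN = "likely_benign"
BENIGN = "benign"

STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")

#: Default strength per code prefix; individual criteria may be overridden.
_DEFAULT_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)\d$")


def default_strength(code: str) -> str:
    m = _CODE_RE.match(code)
    if m is None:
        raise ValueError(f"unknown ACMG code {code!r}")
    return _DEFAULT_STRENGTH[m.group(1)]


@dataclass(frozen=True)
class Criterion:
    code: str
    strength: str | None = None  # None -> default for the code

    def __post_init__(self):
        if _CODE_RE.match(self.code) is None:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        if self.strength is not None and self.strength not in STRENGTHS:
            raise ValueError(f"bad strength {self.strength!r}")

    @property
    def effective_strength(self) -> str:
        return self.strength or default_strength(self.code)

    @property
    def is_benign_side(self) -> bool:
        return self.code.startswith("B")


@dataclass(frozen=True)
class CriteriaSet:
    variant_key: str
    criteria: frozenset[Criterion]

    def __post_init__(self):
        codes = [c.code for c in self.criteria]
        if len(codes) != len(set(codes)):
            raise ValueError(f"duplicate ACMG codes for {self.variant_key}")
        object.__setattr__(self, "criteria", frozenset(self.criteria))

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(c.code for c in self.criteria)


@dataclass(frozen=True)
class AcmgConfig:
    """Thresholds and maps driving computational evidence assignment."""

    #: in-silico verdict -> (code, strength); verdicts absent here assign nothing
    insilico_map: tuple = (
        ("strong_pathogenic", ("PP3", "strong")),
        ("moderate_pathogenic", ("PP3", "moderate")),
        ("supporting_benign", ("BP4", "supporting")),
    )
    pp2_z_threshold: float = 3.09
    pvs1_z_lof_threshold: float = 3.09
    pm2_max_af: float = 0.001
    pm1_requires_domain: bool = True

    def __post_init__(self):
        if self.pp2_z_threshold <= 0 or self.pvs1_z_lof_threshold <= 0:
            raise ValueError("Z-score thresholds must be positive")

    def verdict_criterion(self, verdict: str) -> Criterion | None:
        for key, (code, strength) in self.insilico_map:
            if key == verdict:
                return Criterion(code, strength)
        return None


_CANONICAL_SPLICE = re.compile(r"c\.[*-]?\d+([+-])([12])(?:_\d+[+-]\d+)?")


def _is_canonical_splice(coding_hgvs: str) -> bool:
    """True when the variant touches the +/-1 or +/-2 intronic positions."""
    m = _CANONICAL_SPLICE.search(coding_hgvs.replace(" ", ""))
    return m is not None


def assign_criteria(
    variant: AnnotatedVariant,
    variant_class: VariantClass | None = None,
    segregation: str | None = None,
    constraints: Mapping[str, GeneConstraint] | None = None,
    config: AcmgConfig | None = None,
    flags: frozenset[str] = frozenset(),
) -> CriteriaSet:
    """Assign computational evidence for one prioritized variant.

    ``segregation`` is the origin call from the family module
    ("de_novo", "inherited_maternal", ...); only a confirmed de novo
    (both parents genotyped negative) triggers PS2.
    """
    config = config or AcmgConfig()
    vclass = variant_class or classify_variant(variant)
    constraint = (constraints or {}).get(variant.gene)
    if constraint is None and constraints is not None:
        warnings.warn(
            f"no constraint row for {variant.gene!r}; PVS1/PP2/BS1 not assessable",
            stacklevel=2,
        )
    criteria: list[Criterion] = []

    is_null = vclass.value in {"nonsense", "frameshift"} or (
        vclass.value == "splicing" and _is_canonical_splice(variant.coding_hgvs)
    )
    if is_null and constraint is not None and constraint.z_lof >= config.pvs1_z_lof_threshold:
        criteria.append(Criterion("PVS1"))

    if segregation == "de_novo":
        criteria.append(Criterion("PS2"))

    if variant.in_domain and config.pm1_requires_domain:
        criteria.append(Criterion("PM1"))

    if variant.gnomad_af is None or variant.gnomad_af < config.pm2_max_af:
        criteria.append(Criterion("PM2"))

    if (
        vclass.value == "missense"
        and constraint is not None
        and constraint.z_missense >= config.pp2_z_threshold
    ):
        criteria.append(Criterion("PP2"))

    verdict_crit = config.verdict_criterion(variant.insilico_verdict)
    if verdict_crit is not None:
        criteria.append(verdict_crit)

    if "exceeds_benign_cutoff" in flags and constraint is not None:
        criteria.append(Criterion("BS1"))

    return CriteriaSet(variant_key=variant.key, criteria=frozenset(criteria))


# ---------------------------------------------------------------------------
# Five-tier combiner — the 2015 combining rules encoded as data
# ---------------------------------------------------------------------------

# each profile: minimum counts of (very_strong, strong, moderate, supporting)
# on the pathogenic side; "m_max" bounds moderates where the rule says 1-2
PATHOGENIC_PROFILES = (
    {"vs": 1, "s": 1},
    {"vs": 1, "m": 2},
    {"vs": 1, "m": 1, "p": 1},
    {"vs": 1, "p": 2},
    {"s": 2},
    {"s": 1, "m": 3},
    {"s": 1, "m": 2, "p": 2},
    {"s": 1, "m": 1, "p": 4},
)

LIKELY_PATHOGENIC_PROFILES = (
    {"vs": 1, "m": 1},
    {"s": 1, "m": 1},  # covers the 1 strong + 1-2 moderate rule
    {"s": 1, "p": 2},
    {"m": 3},
    {"m": 2, "p": 2},
    {"m": 1, "p": 4},
)

BENIGN_PROFILES = ({"sa": 1}, {"bs": 2})
LIKELY_BENIGN_PROFILES = ({"bs": 1, "bp": 1}, {"bp": 2})


def _counts(criteria: Iterable[Criterion]) -> tuple[Counter, Counter]:
    path, benign = Counter(), Counter()
    short = {"very_strong": "vs", "strong": "s", "moderate": "m", "supporting": "p",
             "stand_alone": "sa"}
    for c in criteria:
        strength = c.effective_strength
        if c.is_benign_side:
            benign[{"stand_alone": "sa", "strong": "bs", "supporting": "bp",
                    "very_strong": "bs", "moderate": "bp"}[strength]] += 1
        else:
            path[short[strength]] += 1
    return path, benign


def _matches(counts: Counter, profiles: Sequence[dict]) -> bool:
    return any(all(counts[k] >= v for k, v in profile.items()) for profile in profiles)


def combine(criteria: CriteriaSet | Iterable[Criterion]) -> str:
    """Combine assigned evidence into one of the five tiers.

    Deterministic and total: any criteria set yields exactly one label.
    Sets satisfying both a pathogenic-side and a benign-side combination
    are conflicting and yield VUS.
    """
    items = criteria.criteria if isinstance(criteria, CriteriaSet) else frozenset(criteria)
    path_counts, benign_counts = _counts(items)

    pathogenic = _matches(path_counts, PATHOGENIC_PROFILES)
    likely_path = pathogenic or _matches(path_counts, LIKELY_PATHOGENIC_PROFILES)
    benign = _matches(benign_counts, BENIGN_PROFILES)
    likely_benign = benign or _matches(benign_counts, LIKELY_BENIGN_PROFILES)

    if likely_path and likely_benign:
        return VUS
    if pathogenic:
        return PATHOGENIC
    if likely_path:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return VUS


@dataclass(frozen=True)
class AcmgResult:
    variant: AnnotatedVariant
    criteria: CriteriaSet
    label: str

    @property
    def trace(self) -> str:
        """Human-readable evidence trace, stable across runs."""
        parts = sorted(
            f"{c.code}({c.effective_strength})" for c in self.criteria.criteria
        )
        return "+".join(parts) if parts else "no_evidence"


def classify_all(
    decisions: Sequence[PrioritizationDecision],
    segregations: Mapping[str, str] | None = None,
    constraints: Mapping[str, GeneConstraint] | None = None,
    config: AcmgConfig | None = None,
    overrides: Mapping[str, CriteriaSet] | None = None,
) -> tuple[list[AcmgResult], dict[str, int]]:
    """Assign criteria and a five-tier label to each prioritized variant.

    ``segregations`` maps variant keys ("GENE:c.xxx") to origin calls;
    ``overrides`` replaces the computed criteria set for specific variants
    (e.g. hand-curated evidence).  Returns the per-variant results and a
    tally of labels over the cohort.
    """
    results = []
    for d in decisions:
        key = d.variant.key
        if overrides is not None and key in overrides:
            crit = overrides[key]
        else:
            crit = assign_criteria(
                d.variant,
                variant_class=d.variant_class,
                segregation=(segregations or {}).get(key),
                constraints=constraints,
                config=config,
                flags=d.flags,
            )
        results.append(AcmgResult(variant=d.variant, criteria=crit, label=combine(crit)))
    tally = Counter(r.label for r in results)
    return results, dict(tally)
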