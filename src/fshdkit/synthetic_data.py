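"""Synthetic cohorts, variant tables and families for end-to-end testing.

Nothing in the reference study is deposited, so every pipeline stage is
exercised against generated data carrying the statistical structure the
analysis assumes:

* cohorts reproduce the study strata of D4Z4 allele sizes (15 subjects at
  1-3 RU, 80 at 4-7, 7 at 8-10, 2 at 11-20, 6 above 20, plus 16 with two
  permissive 4qA alleles in 3-20 RU — 126 in all), the 45:55 F:M ratio and
  the 52.5 +/- 17.7 year age distribution;
* methylation profiles are drawn per decision-tree leaf, with each of the
  four classifier CpGs placed a configurable margin on the correct side of
  its threshold plus Gaussian noise — the classifier only ever sees
  threshold relations, so leaf placement is the structure that matters;
  background CpGs are drawn independently per site (real per-CpG
  correlation along DR1 is not modelled);
* 4qB/4qB subjects always lack DUX4-PAS methylation (the region cannot be
  amplified without a 4qA allele); all generated patients carry at least
  one 4qA allele, as in the study cohort;
* decoy variants are constructed to fail at least one named prioritization
  filter, with the violation recorded as ground truth;
* families transmit alleles and heterozygous variants Mendelianly, with an
  optional forced de novo event in a named child.

All randomness flows from one integer seed; each operation derives its own
deterministic substream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    OVER_20,
    Allele4q,
    AnnotatedVariant,
    Genotype4q,
    MethylationProfile,
    Pedigree,
    Subject,
    N_DR1_CPGS,
    N_PAS_CPGS,
)
from .methylation import CTRL, FSHD, ClassifierConfig

__all__ = [
    "CohortSpec",
    "MethylationModel",
    "GeneratedFamily",
    "generate_cohort",
    "generate_labeled_cohort",
    "generate_variant_table",
    "generate_family",
]

# substream tags so different operations never share a stream
_STREAM_COHORT = 1
_STREAM_VARIANTS = 2
_STREAM_FAMILY = 3
_STREAM_LABELED = 4


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort strata: (lo RU, hi RU, count) plus the double-4qA group.

    Defaults reproduce the study cohort: 15+80+7+2+6 single-permissive
    subjects plus 16 double-4qA subjects = 126. ``None`` as the upper bound
    denotes the unresolved ">20 RU" stratum.
    """

    strata: tuple = (
        (1, 3, 15),
        (4, 7, 80),
        (8, 10, 7),
        (11, 20, 2),
        (21, None, 6),
    )
    double_4qa_count: int = 16
    double_4qa_range: tuple[int, int] = (3, 20)
    female_fraction: float = 0.45
    age_mean: float = 52.5
    age_sd: float = 17.7
    #: probability that the second (non-contracted) allele is 4qB rather than
    #: 4qA for single-permissive subjects
    second_allele_b_prob: float = 0.5

    def __post_init__(self):
        for lo, hi, count in self.strata:
            if count < 0:
                raise ValueError("stratum counts must be >= 0")
            if hi is not None and hi < lo:
                raise ValueError(f"bad stratum range ({lo}, {hi})")
        if self.double_4qa_count < 0:
            raise ValueError("double_4qa_count must be >= 0")

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.strata) + self.double_4qa_count


@dataclass(frozen=True)
class MethylationModel:
    """Leaf-conditional distributions for the four classifier CpGs.

    Each classifier feature is drawn uniformly on the correct side of its
    threshold, at least ``margin`` away (shrunk automatically near the
    [0, 1] boundary), then perturbed with N(0, noise_sd) and clipped.
    With the default margin 0.15 and noise 0.03 the classes are well
    separated and the classifier recovers the true class of essentially
    every classifiable subject.
    """

    thresholds: ClassifierConfig = field(default_factory=ClassifierConfig)
    margin: float = 0.15
    spread: float = 0.35
    noise_sd: float = 0.03
    #: leaf mixture per class
    fshd_node_weights: tuple = ((3, 0.75), (7, 0.25))
    ctrl_node_weights: tuple = ((8, 0.30), (10, 0.50), (11, 0.20))
    #: Beta(a, b) for background (non-classifier) CpGs per class
    background_fshd: tuple[float, float] = (4.0, 6.0)
    background_ctrl: tuple[float, float] = (8.0, 2.0)

    def __post_init__(self):
        if not 0 < self.margin < 0.5:
            raise ValueError("margin must lie in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # which side of each threshold each leaf requires, in feature order
    # (pas_cpg6, pas_cpg3, dr1_cpg1, dr1_cpg22); only features on the
    # leaf's decision path are constrained — the rest are "any", matching
    # the reference data where e.g. node-3 subjects span both sides of the
    # DR1 CpG1 threshold.  Control leaves keep cpg1 "above" so the branch
    # combination absent from labelled data is never generated.
    _NODE_SIDES = {
        3: ("below", "any", "any", "any"),
        7: ("above", "below", "below", "any"),
        8: ("above", "below", "above", "any"),
        10: ("above", "above", "above", "below"),
        11: ("above", "above", "above", "above"),
    }

    def _draw_feature(self, rng, threshold: float, side: str) -> float:
        # the gap around the threshold is symmetric, shrinking near the
        # [0, 1] boundary so every leaf keeps non-empty support (the CpG22
        # threshold of 0.99 leaves only a sliver above)
        if side == "any":
            return float(rng.uniform(0.0, 1.0))
        delta = min(self.margin, threshold / 2, (1 - threshold) / 2)
        if side == "below":
            lo = max(0.0, threshold - self.spread)
            hi = threshold - delta
        else:
            lo = threshold + delta
            hi = min(1.0, threshold + self.spread)
        value = rng.uniform(lo, hi) + rng.normal(0.0, self.noise_sd)
        # truncate to the leaf's side of the threshold
        return float(np.clip(value, lo, hi))

    def sample_node(self, rng, label: str) -> int:
        weights = self.fshd_node_weights if label == FSHD else self.ctrl_node_weights
        nodes = [n for n, _ in weights]
        probs = np.array([w for _, w in weights], dtype=float)
        return int(rng.choice(nodes, p=probs / probs.sum()))

    def sample_profile(self, rng, node: int, pas_absent: bool = False) -> MethylationProfile:
        sides = self._NODE_SIDES[node]
        thresholds = self.thresholds.thresholds
        features = [
            self._draw_feature(rng, t, side) for t, side in zip(thresholds, sides)
        ]
        bg_a, bg_b = self.background_fshd if node in (3, 7) else self.background_ctrl
        dr1 = rng.beta(bg_a, bg_b, size=N_DR1_CPGS)
        pas = rng.beta(bg_a, bg_b, size=N_PAS_CPGS)
        pas[5] = features[0]  # PAS CpG 6 (1-based)
        pas[2] = features[1]  # PAS CpG 3
        dr1[0] = features[2]  # DR1 CpG 1
        dr1[21] = features[3]  # DR1 CpG 22
        return MethylationProfile(dr1=dr1, dux4_pas=None if pas_absent else pas)


def _second_allele(rng, spec: CohortSpec) -> Allele4q:
    subtype = "B" if rng.random() < spec.second_allele_b_prob else "A"
    return Allele4q(OVER_20, subtype)


def _stratum_size(rng, lo: int, hi: int | None):
    if hi is None:
        return OVER_20
    return int(rng.integers(lo, hi + 1))


def generate_cohort(
    spec: CohortSpec | None = None,
    model: MethylationModel | None = None,
    seed: int = 0,
) -> list[Subject]:
    """Generate a cohort with the study's strata structure and ground truth.

    Each subject carries its true class in ``recorded_label`` and the
    methylation-model leaf it was drawn from in ``recorded_node``; subjects
    with a permissive allele of at most 20 RU are FSHD-like, the >20 RU
    stratum is control-like.  Reproducible given the seed.
    """
    spec = spec or CohortSpec()
    model = model or MethylationModel()
    rng = _rng(seed, _STREAM_COHORT)
    subjects = []
    counter = itertools.count(1)

    def build(genotype: Genotype4q, fshd_like: bool):
        idx = next(counter)
        label = FSHD if fshd_like else CTRL
        node = model.sample_node(rng, label)
        pas_absent = genotype.configuration == "4qB/4qB"
        profile = model.sample_profile(rng, node, pas_absent=pas_absent)
        sex = "F" if rng.random() < spec.female_fraction else "M"
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 95.0))
        subjects.append(
            Subject(
                subject_id=f"SYN{idx:04d}",
                family_id=f"SYNFAM{idx:04d}",
                relation="proband",
                affected="affected" if fshd_like else "unknown",
                genotype=genotype,
                methylation=profile,
                sex=sex,
                age=round(age, 1),
                recorded_node=node,
                recorded_label=label,
            )
        )

    for lo, hi, count in spec.strata:
        for _ in range(count):
            size = _stratum_size(rng, lo, hi)
            genotype = Genotype4q(Allele4q(size, "A"), _second_allele(rng, spec))
            fshd_like = size != OVER_20 and size <= 20
            build(genotype, fshd_like)
    d_lo, d_hi = spec.double_4qa_range
    for _ in range(spec.double_4qa_count):
        s1 = int(rng.integers(d_lo, d_hi + 1))
        s2 = int(rng.integers(d_lo, d_hi + 1))
        genotype = Genotype4q(Allele4q(s1, "A"), Allele4q(s2, "A"))
        build(genotype, True)
    return subjects


def generate_labeled_cohort(
    n: int,
    model: MethylationModel | None = None,
    seed: int = 0,
    fshd_fraction: float = 0.5,
) -> list[Subject]:
    """Balanced labelled cohort for classifier/threshold-recovery checks.

    FSHD-like subjects receive a contracted permissive allele, control-like
    subjects a normal-sized array; profiles are drawn from the same leaf
    mixtures as :func:`generate_cohort`.
    """
    model = model or MethylationModel()
    rng = _rng(seed, _STREAM_LABELED)
    subjects = []
    for i in range(n):
        fshd_like = rng.random() < fshd_fraction
        label = FSHD if fshd_like else CTRL
        node = model.sample_node(rng, label)
        if fshd_like:
            genotype = Genotype4q(Allele4q(int(rng.integers(1, 11)), "A"), Allele4q(OVER_20, "B"))
        else:
            genotype = Genotype4q(Allele4q(OVER_20, "A"), Allele4q(OVER_20, "B"))
        subjects.append(
            Subject(
                subject_id=f"LAB{i:05d}",
                family_id=f"LABFAM{i:05d}",
                relation="proband",
                affected="affected" if fshd_like else "unaffected",
                genotype=genotype,
                methylation=model.sample_profile(rng, node),
                recorded_node=node,
                recorded_label=label,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Decoy variant tables
# ---------------------------------------------------------------------------

_OFF_PANEL_GENES = ("TTN", "MYH7", "DMD", "NEB", "RYR1", "COL6A1")
_PANEL_FOR_DECOYS = ("SMCHD1", "DNMT3B", "CTCF", "EZH2", "DNMT1")
_VIOLATIONS = ("off_panel", "synonymous", "high_maf", "low_coverage")

_AA = ("Ala", "Arg", "Asp", "Gly", "Leu", "Lys", "Ser", "Thr", "Val")


def generate_variant_table(
    planted: Sequence[AnnotatedVariant],
    n_decoys: int,
    seed: int = 0,
) -> tuple[list[AnnotatedVariant], dict[str, str]]:
    """Planted variants plus decoys that each fail >= 1 named filter.

    Returns the combined table (planted first, then decoys) and the ground
    truth mapping each decoy's variant key to the filter it violates
    (one of off_panel, synonymous, high_maf, low_coverage).
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = _rng(seed, _STREAM_VARIANTS)
    variants = list(planted)
    truth: dict[str, str] = {}
    for i in range(n_decoys):
        violation = _VIOLATIONS[i % len(_VIOLATIONS)]
        pos = 1_000_000 + int(rng.integers(0, 9_000_000))
        codon = int(rng.integers(2, 900))
        ref_aa, alt_aa = rng.choice(_AA, size=2, replace=False)
        gene = (
            str(rng.choice(_OFF_PANEL_GENES))
            if violation == "off_panel"
            else str(rng.choice(_PANEL_FOR_DECOYS))
        )
        if violation == "synonymous":
            protein, label = f"p.{ref_aa}{codon}=", "synonymous"
        else:
            protein, label = f"p.{ref_aa}{codon}{alt_aa}", "missense"
        variant = AnnotatedVariant(
            gene=gene,
            chrom=str(int(rng.integers(1, 23))),
            position=pos,
            coding_hgvs=f"c.{codon * 3 - 1}A>G",
            protein_hgvs=protein,
            type_label=label,
            coverage=int(rng.integers(2, 20)) if violation == "low_coverage" else 100,
            gnomad_af=0.05 if violation == "high_maf" else None,
            insilico_verdict="na",
        )
        variants.append(variant)
        truth[variant.key] = violation
    return variants, truth


# ---------------------------------------------------------------------------
# Mendelian family generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratedFamily:
    pedigree: Pedigree
    genotypes: Mapping[str, Genotype4q]
    carriers: Mapping[str, bool]


def generate_family(
    pedigree: Pedigree,
    founder_genotypes: Mapping[str, Genotype4q],
    founder_carriers: Mapping[str, bool],
    seed: int = 0,
    force_de_novo: str | None = None,
) -> GeneratedFamily:
    """Transmit alleles and a heterozygous variant through a pedigree.

    Offspring draw one allele uniformly from each parent; a heterozygous
    carrier parent transmits the variant with probability 1/2.  Founders
    (members without parents) must appear in both founder maps.
    ``force_de_novo`` names a child made a carrier regardless of parental
    status.
    """
    from collections import deque

    rng = _rng(seed, _STREAM_FAMILY)
    genotypes: dict[str, Genotype4q] = {}
    carriers: dict[str, bool] = {}
    pending = deque(pedigree.members)
    stall = 0
    while pending:
        member = pending.popleft()
        sid = member.subject_id
        if member.father_id is None and member.mother_id is None:
            if sid not in founder_genotypes or sid not in founder_carriers:
                raise ValueError(f"founder {sid!r} missing genotype or carrier status")
            genotypes[sid] = founder_genotypes[sid]
            carriers[sid] = bool(founder_carriers[sid])
        else:
            parents = [p for p in (member.father_id, member.mother_id) if p is not None]
            if not all(p in genotypes for p in parents):
                pending.append(member)
                stall += 1
                if stall > len(pending):
                    raise ValueError("pedigree members with unresolvable parents")
                continue
            inherited = []
            carried = False
            for p in parents:
                alleles = genotypes[p].alleles
                inherited.append(alleles[int(rng.integers(0, 2))])
                if carriers[p] and rng.random() < 0.5:
                    carried = True
            while len(inherited) < 2:
                # untyped parent contributes a population-normal allele
                inherited.append(Allele4q(OVER_20, "B" if rng.random() < 0.5 else "A"))
            genotypes[sid] = Genotype4q(inherited[0], inherited[1])
            carriers[sid] = carried
        stall = 0
    if force_de_novo is not None:
        if force_de_novo not in carriers:
            raise ValueError(f"unknown subject {force_de_novo!r} for forced de novo")
        carriers[force_de_novo] = True
    return GeneratedFamily(pedigree=pedigree, genotypes=genotypes, carriers=carriers)
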