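"""ACMG evidence assignment and the five-tier combiner."""

import itertools
import random

import pytest

from fshdkit.acmg import (
    BENIGN,
    LIKELY_BENIGN,
    LIKELY_PATHOGENIC,
    PATHOGENIC,
    VUS,
    AcmgConfig,
    Criterion,
    CriteriaSet,
    assign_criteria,
    classify_all,
    combine,
)
from fshdkit.core import AnnotatedVariant
from fshdkit.prioritizer import prioritize_cohort

# fuzz/enumeration vocabulary: standard codes at their default strengths
# plus the strength-scaled PP3 used for strong in-silico verdicts
VOCABULARY = (
    Criterion("PVS1"),
    Criterion("PS1"), Criterion("PS2"),
    Criterion("PM1"), Criterion("PM2"), Criterion("PM3"),
    Criterion("PP1"), Criterion("PP2"),
    Criterion("PP3", "moderate"), Criterion("PP3", "strong"),
    Criterion("BA1"), Criterion("BS1"), Criterion("BS2"),
    Criterion("BP4"), Criterion("BP5"),
)


def oracle_combine(criteria):
    """Independent hand-written evaluation of the 2015 combining rules."""
    vs = sum(1 for c in criteria if not c.is_benign_side and c.effective_strength == "very_strong")
    s = sum(1 for c in criteria if not c.is_benign_side and c.effective_strength == "strong")
    m = sum(1 for c in criteria if not c.is_benign_side and c.effective_strength == "moderate")
    p = sum(1 for c in criteria if not c.is_benign_side and c.effective_strength == "supporting")
    sa = sum(1 for c in criteria if c.is_benign_side and c.effective_strength == "stand_alone")
    bs = sum(1 for c in criteria if c.is_benign_side and c.effective_strength == "strong")
    bp = sum(1 for c in criteria if c.is_benign_side and c.effective_strength == "supporting")

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely_pathogenic = pathogenic or (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = sa >= 1 or bs >= 2
    likely_benign = benign or (bs >= 1 and bp >= 1) or bp >= 2

    if likely_pathogenic and likely_benign:
        return VUS
    if pathogenic:
        return PATHOGENIC
    if likely_pathogenic:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return VUS


_RANK = {BENIGN: 0, LIKELY_BENIGN: 1, VUS: 2, LIKELY_PATHOGENIC: 3, PATHOGENIC: 4}


class TestCombine:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (("PVS1", "PS2"), PATHOGENIC),          # 1 very strong + 1 strong
            (("PVS1", "PS2", "PM2"), PATHOGENIC),
            (("PVS1", "PM2"), LIKELY_PATHOGENIC),   # 1 very strong + 1 moderate
            (("PM1", "PM2", "PP2"), VUS),           # 2 moderate + 1 supporting falls short
            (("BP4",), VUS),                        # one supporting-benign alone
            ((), VUS),
            (("BA1",), BENIGN),
            (("BS1", "BS2"), BENIGN),
            (("BS1", "BP4"), LIKELY_BENIGN),
            (("BP4", "BP5"), LIKELY_BENIGN),
        ],
    )
    def test_worked_examples(self, codes, expected):
        assert combine([Criterion(c) for c in codes]) == expected

    def test_three_moderates_are_likely_pathogenic(self):
        assert combine([Criterion("PM1"), Criterion("PM2"), Criterion("PM3")]) == LIKELY_PATHOGENIC

    def test_equivalent_to_oracle_on_all_sets_up_to_six(self):
        for size in range(7):
            for subset in itertools.combinations(VOCABULARY, size):
                codes = [c.code for c in subset]
                if len(set(codes)) != len(codes):  # both PP3 strengths
                    continue
                assert combine(subset) == oracle_combine(subset), subset

    def test_monotone_in_pathogenic_evidence(self):
        rng = random.Random(0)
        path_side = [c for c in VOCABULARY if not c.is_benign_side]
        for _ in range(500):
            base = rng.sample(VOCABULARY, rng.randint(0, 6))
            codes = {c.code for c in base}
            extra = rng.choice([c for c in path_side if c.code not in codes])
            before = _RANK[combine(base)]
            after = _RANK[combine(list(base) + [extra])]
            assert after >= before

    def test_monotone_in_benign_evidence(self):
        rng = random.Random(1)
        benign_side = [c for c in VOCABULARY if c.is_benign_side]
        for _ in range(500):
            base = rng.sample(VOCABULARY, rng.randint(0, 6))
            codes = {c.code for c in base}
            candidates = [c for c in benign_side if c.code not in codes]
            if not candidates:
                continue
            extra = rng.choice(candidates)
            assert _RANK[combine(list(base) + [extra])] <= _RANK[combine(base)]

    def test_conflicting_evidence_is_vus(self):
        conflicted = [Criterion("PVS1"), Criterion("PS2"), Criterion("BA1")]
        assert combine(conflicted) == VUS

    def test_every_random_set_gets_exactly_one_label(self):
        rng = random.Random(2)
        labels = {PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_BENIGN, BENIGN}
        for _ in range(500):
            subset = rng.sample(VOCABULARY, rng.randint(0, len(VOCABULARY)))
            dedup = {c.code: c for c in subset}.values()
            assert combine(list(dedup)) in labels


class TestAssignCriteria:
    def test_de_novo_frameshift_in_constrained_gene(self, ref_variants, ref_constraints):
        variant = next(v for v in ref_variants if v.coding_hgvs == "c.182_183dup")
        cs = assign_criteria(variant, segregation="de_novo", constraints=ref_constraints)
        assert cs.codes == {"PVS1", "PS2", "PM2"}
        assert combine(cs) == PATHOGENIC

    def test_rare_domain_missense_in_constrained_gene(self, ref_variants, ref_constraints):
        variant = next(v for v in ref_variants if v.gene == "CTCF")
        cs = assign_criteria(variant, constraints=ref_constraints)
        assert cs.codes == {"PM1", "PM2", "PP2", "PP3"}
        pp3 = next(c for c in cs.criteria if c.code == "PP3")
        assert pp3.effective_strength == "moderate"

    def test_no_qualifying_evidence(self, ref_constraints):
        variant = AnnotatedVariant(
            gene="SMCHD1", coding_hgvs="c.10A>G", protein_hgvs="p.Lys4Arg",
            coverage=100, gnomad_af=0.01, insilico_verdict="na",
        )
        config = AcmgConfig(pp2_z_threshold=99.0)
        cs = assign_criteria(variant, constraints=ref_constraints, config=config)
        assert cs.codes == set()

    def test_pvs1_requires_lof_constraint(self, ref_variants, ref_constraints):
        # LRIF1 frameshift: LoF Z of 2.77 sits below the 3.09 default
        variant = next(v for v in ref_variants if v.gene == "LRIF1")
        cs = assign_criteria(variant, constraints=ref_constraints)
        assert "PVS1" not in cs.codes

    def test_canonical_splice_is_pvs1_but_deep_intronic_is_not(self, ref_variants, ref_constraints):
        canonical = next(v for v in ref_variants if v.coding_hgvs == "c.3801+1dup")
        deep = next(v for v in ref_variants if v.coding_hgvs == "c.3802-8C>A")
        assert "PVS1" in assign_criteria(canonical, constraints=ref_constraints).codes
        assert "PVS1" not in assign_criteria(deep, constraints=ref_constraints).codes

    def test_bs1_from_benign_cutoff_flag(self, ref_variants, ref_constraints):
        variant = next(v for v in ref_variants if v.gene == "DNMT3B")
        cs = assign_criteria(
            variant, constraints=ref_constraints,
            flags=frozenset({"exceeds_benign_cutoff"}),
        )
        assert "BS1" in cs.codes

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CriteriaSet("x", frozenset()).__class__(
                "x", (Criterion("PM1"), Criterion("PM1", "strong"))
            )


class TestClassifyAll:
    def test_uniform_cohort(self, ref_variants, ref_constraints):
        summary = prioritize_cohort(ref_variants, constraints=ref_constraints)
        segregations = {d.variant.key: "de_novo" for d in summary.retained}
        # force every variant to the same de-novo-frameshift-like evidence
        overrides = {
            d.variant.key: CriteriaSet(d.variant.key, frozenset({Criterion("PVS1"), Criterion("PS2")}))
            for d in summary.retained
        }
        results, tally = classify_all(
            list(summary.retained), segregations, ref_constraints, overrides=overrides
        )
        assert tally == {PATHOGENIC: len(results)}

    def test_reference_tally_sums_to_twenty_with_full_traces(self, ref_variants, ref_constraints):
        summary = prioritize_cohort(ref_variants, constraints=ref_constraints)
        results, tally = classify_all(list(summary.retained), constraints=ref_constraints)
        assert sum(tally.values()) == 20
        assert len(results) == 20
        for r in results:
            assert r.trace  # evidence trace retained per variant
            assert r.label in {PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_BENIGN, BENIGN}

    def test_empty_criteria_single_variant_is_vus(self, ref_constraints):
        variant = AnnotatedVariant(
            gene="SMCHD1", coding_hgvs="c.10A>G", protein_hgvs="p.Lys4Arg", coverage=100
        )
        summary = prioritize_cohort([variant])
        overrides = {variant.key: CriteriaSet(variant.key, frozenset())}
        results, tally = classify_all(list(summary.retained), overrides=overrides)
        assert tally == {VUS: 1}
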