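"""Reference fixtures: the published family/variant inventories, transcribed.

The reference data comprise 19 FSHD families (44 subjects, 42 with
methylation data — the two 4qB/4qB relatives cannot be assayed at
DUX4-PAS), 20 panel variants detected in the 19 probands, and the per-gene
constraint statistics.  The subject table stores only the four classifier
CpG sites; the remaining DR1/DUX4-PAS sites were not published and are
left unmeasured (NaN) in the profiles.

Allele reporting convention of the source table: for 4qA/4qB subjects the
printed size is the single permissive 4qA allele; for 4qA/4qA subjects the
shortest allele is printed, or both when both are <= 20 RU.  Unprinted
second alleles are therefore transcribed as the ">20 RU" sentinel.
"""

from __future__ import annotations

import io
from importlib import resources

from .core import (
    COHORT_COLUMNS,
    COHORT_EXTRA_COLUMNS,
    AnnotatedVariant,
    GeneConstraint,
    Pedigree,
    Subject,
    read_cohort,
    read_constraints,
    read_ped,
    read_variants,
)

__all__ = [
    "reference_cohort",
    "reference_cohort_tsv",
    "reference_variants",
    "reference_constraints",
    "reference_pedigrees",
]

# (family_no, member, relation, affected, size_text, config, variants,
#  cpg6%, cpg3%, cpg1%, cpg22%, node, label, sex, age, css, fcs)
# methylation cells are None for subjects whose DUX4-PAS region could not
# be amplified (4qB/4qB)
_SUBJECTS = [
    (1, "A", "proband", "affected", "4", "A/A",
     "SMCHD1:c.5627T>C;LRIF1:c.748del", 57, 27, 48, 80, 3, "FSHD", "M", 39, 3.5, 9),
    (1, "B", "mother", "affected", "4", "A/A",
     "LRIF1:c.748del", 70, 31, 70, 95, 3, "FSHD", "F", 74, 3, None),
    (1, "C", "brother", "unaffected", ">20", "A/A",
     "SMCHD1:c.5627T>C;LRIF1:c.748del", 94, 34, 51, 92, 7, "FSHD", "M", 43, None, None),
    (1, "D", "father", "unaffected", ">20", "A/A",
     "SMCHD1:c.5627T>C", 91, 39, 71, 96, 10, "CTRL", "M", 78, None, None),
    (2, "A", "proband", "affected", "5 + 12", "A/A",
     "CTCF:c.1483T>G", 67, 24, 47, 85, 3, "FSHD", "F", 59, 3, 4),
    (2, "B", "son", "unaffected", "12", "A/B",
     "CTCF:c.1483T>G", 70, 21, 50, 80, 3, "FSHD", "M", 29, None, None),
    (2, "C", "son", "unaffected", "12", "A/B",
     "CTCF:c.1483T>G", 82, 28, 58, 90, 8, "CTRL", "M", 32, None, None),
    (2, "D", "son", "affected", "5", "A/B",
     None, 34, 18, 54, 78, 3, "FSHD", "M", 36, 1, 2),
    (2, "E", "husband", "unaffected", ">20", "B/B",
     None, None, None, None, None, 10, None, "M", 62, 0, 0),
    (3, "A", "proband", "affected", "5", "A/A",
     "EZH2:c.566_568dup", 78, 38, 75, 100, 3, "FSHD", "F", 58, 3.5, 8),
    (3, "B", "daughter", "unaffected", ">20", "A/A",
     "EZH2:c.566_568dup", 100, 41, 57, 91, 10, "CTRL", "F", 31, 0, 0),
    (3, "C", "daughter", "affected", "5", "A/A",
     "EZH2:c.566_568dup", 82, 45, 75, 100, 11, "CTRL", "F", 23, 1, 2),
    (3, "D", "husband", "unaffected", ">20", "A/A",
     None, 93, 41, 60, 89, 10, "CTRL", "M", 59, 0, 0),
    (4, "A", "proband", "affected", "8", "A/B",
     "EZH2:c.604G>A", 48, 15, 64, 64, 3, "FSHD", "M", 58, 3, 6),
    (4, "B", "son", "unknown", "8", "A/A",
     None, 92, 37, 72, 93, 10, "CTRL", "M", 28, None, None),
    (4, "C", "daughter", "unaffected", "14", "A/A",
     "EZH2:c.604G>A", 86, 18, 28, 47, 7, "FSHD", "F", 27, 0, 0),
    (5, "A", "proband", "affected", "5 + 16", "A/A",
     "DNMT3A:c.889T>G", 59, 12, 62, 100, 3, "FSHD", "M", 80, 4, 4),
    (5, "B", "daughter", "unaffected", "11 + 16", "A/A",
     None, 94, 32, 65, 94, 8, "CTRL", "F", 57, None, None),
    (6, "A", "proband", "affected", "6", "A/B",
     "SUV39H1:c.421C>T", 68, 10, 72, 98, 3, "FSHD", "F", 79, 4, 7),
    (6, "B", "son", "affected", "6", "A/B",
     None, 78, 21, 67, 96, 3, "FSHD", "M", 51, 1, 2),
    (6, "C", "daughter", "unaffected", "6", "A/B",
     "SUV39H1:c.421C>T", 39, 17, 42, 85, 3, "FSHD", "F", 48, 0, 0),
    (6, "D", "husband", "unaffected", ">20", "A/B",
     None, 95, 63, 69, 97, 10, "CTRL", "M", 76, None, None),
    (7, "A", "proband", "affected", "4", "A/B",
     "DNMT1:c.4001C>T", 56, 16, 45, 85, 3, "FSHD", "M", 64, 3.5, 7),
    (7, "B", "daughter", "unaffected", "17 + 17", "B/B",
     None, None, None, None, None, 10, None, "F", 37, None, None),
    (8, "A", "proband", "affected", "5", "A/B",
     "DNMT3B:c.1144C>T", 47, 16, 63, 93, 3, "FSHD", "F", 27, 1, 1),
    (9, "A", "proband", "affected", "7", "A/A",
     "SMCHD1:c.709G>A", 62, 22, 47, 85, 3, "FSHD", "F", 62, 4, 8),
    (10, "A", "proband", "affected", "5 + 10", "A/A",
     "SMCHD1:c.3514G>T", 32, 8, 31, 22, 3, "FSHD", "M", 20, 1.5, 3),
    (10, "B", "father", "unknown", "5", "A/B",
     None, 85, 28, 57, 93, 8, "CTRL", "M", 56, None, None),
    (10, "C", "mother", "unknown", "10", "A/B",
     "SMCHD1:c.3514G>T", 48, 9, 35, 64, 3, "FSHD", "F", 49, None, None),
    (11, "A", "proband", "affected", "13 + 20", "A/A",
     "SMCHD1:c.3801+1dup", 49, 29, 41, 84, 3, "FSHD", "F", 75, None, None),
    (12, "A", "proband", "affected", "6", "A/A",
     "SMCHD1:c.1561G>T", 43, 16, 19, 60, 3, "FSHD", "M", 35, 2.5, 6),
    (13, "A", "proband", "affected", "8 + 20", "A/A",
     "SMCHD1:c.1529C>T", 63, 31, 37, 57, 3, "FSHD", "F", 47, 3.5, None),
    (13, "B", "father", "unknown", "8", "A/B",
     None, 88, 38, 81, 97, 10, "CTRL", "M", 71, None, None),
    (13, "C", "mother", "unaffected", "20", "A/B",
     None, 94, 67, 76, 97, 10, "CTRL", "F", 68, None, None),
    (14, "A", "proband", "affected", "9", "A/A",
     "SMCHD1:c.2129dup", 68, 48, 47, 86, 3, "FSHD", "M", None, 3, 8),
    (14, "B", "father", "affected", None, "A/A",
     "SMCHD1:c.2129dup", 84, 34, 46, 89, 7, "FSHD", "M", 50, 0.5, 1),
    (15, "A", "proband", "affected", "10", "A/A",
     "SMCHD1:c.182_183dup", 51, 10, 24, 58, 3, "FSHD", "M", 34, 1, 2),
    (15, "B", "mother", "unaffected", "10", "A/A",
     None, 93, 32, 75, 98, 8, "CTRL", "F", 66, None, None),
    (15, "C", "father", "unaffected", ">20", "A/A",
     None, 100, 39, 73, 100, 11, "CTRL", "M", 66, None, None),
    (16, "A", "proband", "affected", ">20", "A/A",
     "SMCHD1:c.1131+2_1131+5del", 45, 15, 35, 66, 3, "FSHD", "F", None, 3, None),
    (17, "A", "proband", "affected", "8 + 6", "A/A",
     "SMCHD1:c.3841A>G", 59, 16, 35, 77, 3, "FSHD", "M", None, None, None),
    (18, "A", "proband", "affected", "7", "A/B",
     "SMCHD1:c.3649A>G", 44, 11, 54, 90, 3, "FSHD", "M", 56, 4, None),
    (19, "A", "proband", "affected", "6", "A/B",
     "SMCHD1:c.3802-8C>A", 54, 19, 39, 75, 3, "FSHD", "F", 54, 4, 7),
    (19, "B", "son", "affected", "6", "A/B",
     None, 59, 14, 73, 96, 3, "FSHD", "M", 23, 1.5, None),
]


def _alleles(size_text: str | None, config: str) -> list[tuple[str, str]]:
    """(size, subtype) pairs from the printed size and the 4q configuration."""
    t1, t2 = config.split("/")
    sizes = [] if size_text is None else [s.strip() for s in size_text.split("+")]
    if len(sizes) == 2:
        return [(sizes[0], t1), (sizes[1], t2)]
    if len(sizes) == 1:
        # the printed size is the (shortest) permissive allele when one is
        # 4qA; any unprinted allele is above the reporting range
        if t1 == "A":
            return [(sizes[0], "A"), (">20", t2)]
        return [(sizes[0], t1), (sizes[0], t2)] if t1 == t2 else [(sizes[0], t1), (">20", t2)]
    return [("—", t1), ("—", t2)]


def reference_cohort_tsv() -> str:
    """The reference subject table rendered in the documented TSV dialect."""
    header = COHORT_COLUMNS + COHORT_EXTRA_COLUMNS
    lines = ["\t".join(header)]
    for (fam, member, relation, affected, size_text, config, variants,
         cpg6, cpg3, cpg1, cpg22, node, label, sex, age, css, fcs) in _SUBJECTS:
        row = {c: "—" for c in header}
        row["family_id"] = f"FSHD{fam}"
        row["subject_id"] = f"FSHD{fam}{member}"
        row["relation"] = relation
        row["affected"] = affected
        (s1, t1), (s2, t2) = _alleles(size_text, config)
        row.update(allele1_ru=s1, allele1_type=t1, allele2_ru=s2, allele2_type=t2)
        for col, pct in (("pas_cpg6", cpg6), ("pas_cpg3", cpg3),
                         ("dr1_cpg1", cpg1), ("dr1_cpg22", cpg22)):
            if pct is not None:
                row[col] = f"{pct}%"
        row["sex"] = sex
        if age is not None:
            row["age"] = str(age)
        if css is not None:
            row["css"] = str(css)
        if fcs is not None:
            row["fcs"] = str(fcs)
        if variants:
            row["variants"] = variants
        row["recorded_node"] = str(node)
        if label is not None:
            row["recorded_label"] = label
        lines.append("\t".join(row[c] for c in header))
    return "\n".join(lines) + "\n"


def reference_cohort() -> list[Subject]:
    """The 44 reference subjects, parsed through the standard cohort reader."""
    return read_cohort(io.StringIO(reference_cohort_tsv()))


def _data_path(name: str):
    return resources.files("fshdkit.data").joinpath(name)


def reference_variants() -> list[AnnotatedVariant]:
    """The 20 panel variants detected in the 19 reference probands."""
    with resources.as_file(_data_path("reference_variants.tsv")) as path:
        return read_variants(path)


def reference_constraints() -> dict[str, GeneConstraint]:
    """Per-gene constraint Z scores and benign cut-off frequencies."""
    with resources.as_file(_data_path("gene_constraints.tsv")) as path:
        return read_constraints(path)


def reference_pedigrees() -> list[Pedigree]:
    """The 19 reference family pedigrees (standard PED)."""
    with resources.as_file(_data_path("reference_families.ped")) as path:
        return read_ped(path)
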