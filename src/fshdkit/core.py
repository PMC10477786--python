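"""Shared domain types and tabular I/O for the FSHD diagnostic pipeline.

The pipeline reasons about three kinds of molecular evidence per subject:

* the 4q35 D4Z4 macrosatellite genotype — two alleles, each a repeat-unit
  (RU) count and a subtelomeric subtype (4qA, the disease-permissive
  haplotype, or 4qB);
* CpG methylation fractions over two regions of the D4Z4 locus: DR1
  (29 CpG sites, within each repeat unit) and DUX4-PAS (10 CpG sites,
  amplifiable only when at least one 4qA allele is present);
* annotated exome variants in a panel of chromatin-modifier genes,
  together with per-gene constraint statistics.

All methylation values are stored internally as fractions in [0, 1];
input tables may print either "57%" or "0.57" and both normalise to the
same float.  Repeat-array sizes above 20 RU are never resolved by the
sizing assay and are carried as the :data:`OVER_20` sentinel, which
compares greater than any finite size.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OVER_20",
    "MISSING_MARKERS",
    "N_DR1_CPGS",
    "N_PAS_CPGS",
    "KNOWN_GENES",
    "CohortFormatError",
    "Allele4q",
    "Genotype4q",
    "MethylationProfile",
    "ClinicalRecord",
    "Subject",
    "AnnotatedVariant",
    "GeneConstraint",
    "PedigreeMember",
    "Pedigree",
    "parse_fraction",
    "format_fraction",
    "read_cohort",
    "read_variants",
    "read_constraints",
    "read_ped",
    "write_ped",
    "write_report",
    "cohort_frame",
    "variant_frame",
]

#: Sentinel for D4Z4 allele sizes reported only as "> 20 RU".
OVER_20 = "over_20"

#: Cell contents treated as absent on input (case-insensitive).
MISSING_MARKERS = {"", "—", "-", "na", "n/a", "not found", "none", "nan"}

N_DR1_CPGS = 29
N_PAS_CPGS = 10

#: Established FSHD2-causing / FSHD1-modifier genes; everything else on the
#: panel is a candidate gene.
KNOWN_GENES = frozenset({"SMCHD1", "DNMT3B", "LRIF1"})


class CohortFormatError(ValueError):
    """Raised for malformed tabular input; names the offending row/column."""


def _is_missing(text) -> bool:
    if text is None:
        return True
    if isinstance(text, float) and math.isnan(text):
        return True
    return str(text).strip().lower() in MISSING_MARKERS


def parse_fraction(text, *, row: str = "?", column: str = "?") -> float | None:
    """Parse a methylation/frequency cell into a fraction in [0, 1].

    Accepts percent notation ("57%"), plain decimals ("0.57"), and the
    missing markers ("—", "na", ...) which map to ``None`` — never to 0.
    """
    if _is_missing(text):
        return None
    raw = str(text).strip()
    try:
        if raw.endswith("%"):
            value = float(raw[:-1]) / 100.0
        else:
            value = float(raw)
    except ValueError as exc:
        raise CohortFormatError(
            f"row {row}, column {column}: cannot parse fraction {raw!r}"
        ) from exc
    if not 0.0 <= value <= 1.0:
        raise CohortFormatError(
            f"row {row}, column {column}: value {raw!r} outside [0, 100]%"
        )
    return value


def format_fraction(value: float | None) -> str:
    """Render a fraction for report output.

    Integer percents round-trip exactly ("57%" -> 0.57 -> "57%"); other
    values are written as plain decimals.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "—"
    pct = value * 100.0
    if abs(pct - round(pct)) < 1e-9:
        return f"{int(round(pct))}%"
    return repr(float(value))


def _parse_ru(text, *, row: str = "?", column: str = "?"):
    """Parse an allele-size cell: integer RU, '>20' -> OVER_20, missing -> None."""
    if _is_missing(text):
        return None
    raw = str(text).strip().replace(" ", "")
    if raw in {">20", "over_20", "over20"}:
        return OVER_20
    try:
        size = int(float(raw))
    except ValueError as exc:
        raise CohortFormatError(
            f"row {row}, column {column}: cannot parse RU size {raw!r}"
        ) from exc
    if size < 1:
        raise CohortFormatError(f"row {row}, column {column}: RU size must be >= 1")
    return OVER_20 if size > 20 else size


@dataclass(frozen=True)
class Allele4q:
    """One 4q35 allele: D4Z4 array size in repeat units plus 4qA/4qB subtype.

    ``size_ru`` is an int >= 1, the :data:`OVER_20` sentinel for unresolved
    sizes above 20 RU, or ``None`` when the assay did not report a size.
    """

    size_ru: int | str | None
    subtype: str

    def __post_init__(self):
        if self.subtype not in {"A", "B"}:
            raise ValueError(f"allele subtype must be A or B, got {self.subtype!r}")
        if self.size_ru is not None and self.size_ru != OVER_20:
            if not isinstance(self.size_ru, int) or self.size_ru < 1:
                raise ValueError(f"size_ru must be >= 1, got {self.size_ru!r}")

    @property
    def numeric_size(self) -> float | None:
        """Size usable in comparisons; OVER_20 compares above any finite size."""
        if self.size_ru is None:
            return None
        if self.size_ru == OVER_20:
            return math.inf
        return float(self.size_ru)

    def size_text(self) -> str:
        if self.size_ru is None:
            return "—"
        if self.size_ru == OVER_20:
            return ">20"
        return str(self.size_ru)


@dataclass(frozen=True)
class Genotype4q:
    """Unordered pair of 4q alleles."""

    allele1: Allele4q
    allele2: Allele4q

    @property
    def configuration(self) -> str:
        subtypes = sorted((self.allele1.subtype, self.allele2.subtype))
        return f"4q{subtypes[0]}/4q{subtypes[1]}"

    @property
    def alleles(self) -> tuple[Allele4q, Allele4q]:
        return (self.allele1, self.allele2)

    def permissive_alleles(self) -> tuple[Allele4q, ...]:
        """The 4qA alleles, sorted by size (unknown sizes last)."""
        permissive = [a for a in self.alleles if a.subtype == "A"]
        return tuple(
            sorted(permissive, key=lambda a: math.inf if a.numeric_size is None else a.numeric_size)
        )


@dataclass(frozen=True, eq=False)
class MethylationProfile:
    """Per-CpG methylation fractions for the DR1 and DUX4-PAS regions.

    Either region may be absent as a whole (``None``) — DUX4-PAS cannot be
    amplified from 4qB/4qB subjects — and individual unmeasured sites within
    a present region are NaN.  Site indexing is 1-based in all public APIs,
    matching the CpG naming convention (DR1 CpG 1..29, DUX4-PAS CpG 1..10).
    """

    dr1: np.ndarray | None = None
    dux4_pas: np.ndarray | None = None

    def __post_init__(self):
        for name, vec, expected in (
            ("dr1", self.dr1, N_DR1_CPGS),
            ("dux4_pas", self.dux4_pas, N_PAS_CPGS),
        ):
            if vec is None:
                continue
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (expected,):
                raise ValueError(f"{name} must have length {expected}, got {arr.shape}")
            finite = arr[~np.isnan(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
            object.__setattr__(self, name, arr)

    def __eq__(self, other):
        if not isinstance(other, MethylationProfile):
            return NotImplemented

        def same(a, b):
            if a is None or b is None:
                return a is b
            return np.array_equal(a, b, equal_nan=True)

        return same(self.dr1, other.dr1) and same(self.dux4_pas, other.dux4_pas)

    @property
    def is_absent(self) -> bool:
        return self.dr1 is None and self.dux4_pas is None

    def dr1_site(self, cpg: int) -> float | None:
        """DR1 methylation at 1-based CpG index, or None if unmeasured."""
        if self.dr1 is None:
            return None
        value = float(self.dr1[cpg - 1])
        return None if math.isnan(value) else value

    def pas_site(self, cpg: int) -> float | None:
        """DUX4-PAS methylation at 1-based CpG index, or None if unmeasured."""
        if self.dux4_pas is None:
            return None
        value = float(self.dux4_pas[cpg - 1])
        return None if math.isnan(value) else value


@dataclass(frozen=True)
class ClinicalRecord:
    """Passive clinical metadata; never used by any computation."""

    css: float | None = None
    fcs: float | None = None
    mri_pattern1: bool | None = None
    mri_pattern2: bool | None = None

    def __post_init__(self):
        for name in ("css", "fcs"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    family_id: str
    relation: str = ""
    affected: str = "unknown"  # affected | unaffected | unknown
    genotype: Genotype4q | None = None
    methylation: MethylationProfile = field(default_factory=MethylationProfile)
    clinical: ClinicalRecord | None = None
    sex: str = "unknown"  # M | F | unknown
    age: float | None = None
    #: variant keys ("GENE:c.xxx") this subject carries, from segregation data
    variants: tuple[str, ...] = ()
    #: decision node / label recorded in the source data (for concordance checks)
    recorded_node: int | None = None
    recorded_label: str | None = None

    def __post_init__(self):
        if self.affected not in {"affected", "unaffected", "unknown"}:
            raise ValueError(f"bad affected status {self.affected!r}")
        if self.sex not in {"M", "F", "unknown"}:
            raise ValueError(f"bad sex {self.sex!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated exome variant as emitted by the annotation pipeline.

    In-silico verdicts and splicing-impact calls are consumed as given —
    this package never recomputes predictor scores.
    """

    gene: str
    coding_hgvs: str
    chrom: str = ""
    position: int | None = None  # 1-based, GRCh37
    protein_hgvs: str | None = None
    type_label: str | None = None
    coverage: int = 0
    gnomad_af: float | None = None
    internal_ref_count: int = 0
    insilico_verdict: str = "na"  # strong_pathogenic | moderate_pathogenic | uncertain | supporting_benign | na
    in_domain: bool = False
    splicing_impact: str = "na"  # broken_site | new_site | none | na
    zygosity: str = "het"  # het | hom
    #: subject ids in which the variant was detected (probands for WES hits)
    carriers: tuple[str, ...] = ()

    _VERDICTS = {"strong_pathogenic", "moderate_pathogenic", "uncertain", "supporting_benign", "na"}

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError("gnomad_af must lie in [0, 1]")
        if self.insilico_verdict not in self._VERDICTS:
            raise ValueError(f"bad insilico_verdict {self.insilico_verdict!r}")
        if self.splicing_impact not in {"broken_site", "new_site", "none", "na"}:
            raise ValueError(f"bad splicing_impact {self.splicing_impact!r}")
        if self.zygosity not in {"het", "hom"}:
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.coding_hgvs}"


@dataclass(frozen=True)
class GeneConstraint:
    """Per-gene constraint statistics and the benign cut-off frequency used by BS1."""

    gene: str
    z_missense: float
    z_lof: float
    benign_cutoff_freq: float

    def __post_init__(self):
        if self.benign_cutoff_freq <= 0:
            raise ValueError("benign_cutoff_freq must be > 0")


@dataclass(frozen=True)
class PedigreeMember:
    subject_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affected: str = "unknown"


@dataclass(frozen=True)
class Pedigree:
    family_id: str
    members: tuple[PedigreeMember, ...]

    def __post_init__(self):
        ids = {m.subject_id for m in self.members}
        if len(ids) != len(self.members):
            raise ValueError(f"duplicate subject ids in family {self.family_id}")
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValueError(
                        f"family {self.family_id}: parent {pid!r} of {m.subject_id!r} "
                        "not present in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self):
        parents = {
            m.subject_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        state: dict[str, int] = {}

        def visit(node: str):
            if state.get(node) == 1:
                raise ValueError(f"pedigree cycle involving {node!r} in {self.family_id}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for p in parents.get(node, ()):
                visit(p)
            state[node] = 2

        for sid in parents:
            visit(sid)

    def member(self, subject_id: str) -> PedigreeMember | None:
        for m in self.members:
            if m.subject_id == subject_id:
                return m
        return None

    def parents_of(self, subject_id: str) -> tuple[str | None, str | None]:
        m = self.member(subject_id)
        if m is None:
            return (None, None)
        return (m.father_id, m.mother_id)


# ---------------------------------------------------------------------------
# Subject table I/O
# ---------------------------------------------------------------------------

_PAS_COLS = [f"pas_cpg{i}" for i in range(1, N_PAS_CPGS + 1)]
_DR1_COLS = [f"dr1_cpg{i}" for i in range(1, N_DR1_CPGS + 1)]

#: Documented subject-table layout (TSV, UTF-8).
COHORT_COLUMNS = (
    ["family_id", "subject_id", "relation", "affected",
     "allele1_ru", "allele1_type", "allele2_ru", "allele2_type"]
    + _PAS_COLS + _DR1_COLS
    + ["sex", "age", "css", "fcs"]
)

#: Optional extras read when present and always written.
COHORT_EXTRA_COLUMNS = ["variants", "recorded_node", "recorded_label"]


def _region_vector(row: Mapping, cols: Sequence[str], rid: str) -> np.ndarray | None:
    values = [parse_fraction(row.get(c), row=rid, column=c) for c in cols]
    if all(v is None for v in values):
        return None
    return np.array([np.nan if v is None else v for v in values], dtype=float)


def _subject_from_row(row: Mapping, rid: str) -> Subject:
    genotype = None
    a1 = _parse_ru(row.get("allele1_ru"), row=rid, column="allele1_ru")
    a2 = _parse_ru(row.get("allele2_ru"), row=rid, column="allele2_ru")
    t1 = None if _is_missing(row.get("allele1_type")) else str(row["allele1_type"]).strip().upper()
    t2 = None if _is_missing(row.get("allele2_type")) else str(row["allele2_type"]).strip().upper()
    if t1 and t2:
        try:
            genotype = Genotype4q(Allele4q(a1, t1), Allele4q(a2, t2))
        except ValueError as exc:
            raise CohortFormatError(f"row {rid}: {exc}") from exc

    profile = MethylationProfile(
        dr1=_region_vector(row, _DR1_COLS, rid),
        dux4_pas=_region_vector(row, _PAS_COLS, rid),
    )

    def num(col):
        if _is_missing(row.get(col)):
            return None
        try:
            return float(row[col])
        except ValueError as exc:
            raise CohortFormatError(f"row {rid}, column {col}: bad number {row[col]!r}") from exc

    css, fcs = num("css"), num("fcs")
    clinical = ClinicalRecord(css=css, fcs=fcs) if css is not None or fcs is not None else None

    affected = str(row.get("affected", "unknown")).strip().lower()
    if _is_missing(affected):
        affected = "unknown"
    sex = str(row.get("sex", "unknown")).strip().upper()
    sex = sex if sex in {"M", "F"} else "unknown"

    variants_cell = row.get("variants")
    variants: tuple[str, ...] = ()
    if not _is_missing(variants_cell) and str(variants_cell).strip().lower() != "negative":
        variants = tuple(v.strip() for v in str(variants_cell).split(";") if v.strip())

    node_cell = row.get("recorded_node")
    recorded_node = None if _is_missing(node_cell) else int(float(node_cell))
    label_cell = row.get("recorded_label")
    recorded_label = None if _is_missing(label_cell) else str(label_cell).strip()

    try:
        return Subject(
            subject_id=str(row["subject_id"]).strip(),
            family_id=str(row["family_id"]).strip(),
            relation="" if _is_missing(row.get("relation")) else str(row["relation"]).strip(),
            affected=affected,
            genotype=genotype,
            methylation=profile,
            clinical=clinical,
            sex=sex,
            age=num("age"),
            variants=variants,
            recorded_node=recorded_node,
            recorded_label=recorded_label,
        )
    except (ValueError, KeyError) as exc:
        raise CohortFormatError(f"row {rid}: {exc}") from exc


def read_cohort(path) -> list[Subject]:
    """Read a subject table (TSV) into :class:`Subject` records.

    Missing methylation cells ("—", empty, "na") become absent values —
    never zero; percent strings are normalised to fractions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"family_id", "subject_id"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"subject table missing required columns: {sorted(missing)}")
    subjects = []
    for idx, row in df.iterrows():
        rid = row.get("subject_id") or str(idx + 2)
        subjects.append(_subject_from_row(row, rid))
    seen: set[str] = set()
    for s in subjects:
        if s.subject_id in seen:
            raise CohortFormatError(f"duplicate subject_id {s.subject_id!r}")
        seen.add(s.subject_id)
    return subjects


def _subject_to_row(s: Subject) -> dict:
    row = {c: "—" for c in COHORT_COLUMNS + COHORT_EXTRA_COLUMNS}
    row.update(
        family_id=s.family_id,
        subject_id=s.subject_id,
        relation=s.relation or "—",
        affected=s.affected,
        sex=s.sex if s.sex != "unknown" else "—",
    )
    if s.genotype is not None:
        row["allele1_ru"] = s.genotype.allele1.size_text()
        row["allele1_type"] = s.genotype.allele1.subtype
        row["allele2_ru"] = s.genotype.allele2.size_text()
        row["allele2_type"] = s.genotype.allele2.subtype
    if s.methylation.dux4_pas is not None:
        for i, col in enumerate(_PAS_COLS):
            row[col] = format_fraction(float(s.methylation.dux4_pas[i]))
    if s.methylation.dr1 is not None:
        for i, col in enumerate(_DR1_COLS):
            row[col] = format_fraction(float(s.methylation.dr1[i]))
    if s.age is not None:
        row["age"] = repr(s.age) if s.age != int(s.age) else str(int(s.age))
    if s.clinical is not None:
        if s.clinical.css is not None:
            row["css"] = repr(s.clinical.css) if s.clinical.css != int(s.clinical.css) else str(int(s.clinical.css))
        if s.clinical.fcs is not None:
            row["fcs"] = repr(s.clinical.fcs) if s.clinical.fcs != int(s.clinical.fcs) else str(int(s.clinical.fcs))
    if s.variants:
        row["variants"] = ";".join(s.variants)
    if s.recorded_node is not None:
        row["recorded_node"] = str(s.recorded_node)
    if s.recorded_label is not None:
        row["recorded_label"] = s.recorded_label
    return row


def cohort_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    cols = COHORT_COLUMNS + COHORT_EXTRA_COLUMNS
    return pd.DataFrame([_subject_to_row(s) for s in subjects], columns=cols)


# ---------------------------------------------------------------------------
# Variant table I/O
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "gene", "chrom", "position", "type_label", "coding_hgvs", "protein_hgvs",
    "coverage", "gnomad_af", "internal_ref_count", "insilico_verdict",
    "in_domain", "splicing_impact", "zygosity", "carriers",
]

_DASHES = str.maketrans({"–": "-", "−": "-", "—": "-"})


def _normalise_hgvs(text: str) -> str:
    return text.translate(_DASHES).replace(" ", "")


def _variant_from_row(row: Mapping, rid: str) -> AnnotatedVariant:
    def cell(col, default=None):
        value = row.get(col)
        return default if _is_missing(value) else str(value).strip()

    af = parse_fraction(row.get("gnomad_af"), row=rid, column="gnomad_af")
    in_domain = (cell("in_domain", "false") or "false").lower() in {"1", "true", "yes"}
    try:
        return AnnotatedVariant(
            gene=cell("gene", ""),
            chrom=cell("chrom", "") or "",
            position=None if cell("position") is None else int(float(cell("position"))),
            type_label=cell("type_label"),
            coding_hgvs=_normalise_hgvs(cell("coding_hgvs", "") or ""),
            protein_hgvs=None if cell("protein_hgvs") is None else _normalise_hgvs(cell("protein_hgvs")),
            coverage=int(float(cell("coverage", "0"))),
            gnomad_af=af,
            internal_ref_count=int(float(cell("internal_ref_count", "0") or "0")),
            insilico_verdict=cell("insilico_verdict", "na") or "na",
            in_domain=in_domain,
            splicing_impact=cell("splicing_impact", "na") or "na",
            zygosity=cell("zygosity", "het") or "het",
            carriers=tuple(v.strip() for v in (cell("carriers", "") or "").split(";") if v.strip()),
        )
    except ValueError as exc:
        raise CohortFormatError(f"variant row {rid}: {exc}") from exc


def _read_variants_vcf(path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        af = info.get("GNOMAD_AF")
        out.append(
            AnnotatedVariant(
                gene=str(info.get("GENE", "")),
                chrom=rec.CHROM,
                position=rec.POS,
                coding_hgvs=_normalise_hgvs(str(info.get("CHGVS", ""))),
                protein_hgvs=None if info.get("PHGVS") in (None, ".") else _normalise_hgvs(str(info["PHGVS"])),
                type_label=None if info.get("TYPE") in (None, ".") else str(info["TYPE"]),
                coverage=int(info.get("COV", 0)),
                gnomad_af=None if af in (None, ".") else float(af),
                internal_ref_count=int(info.get("INTREF", 0)),
                insilico_verdict=str(info.get("INSILICO", "na")),
                in_domain=bool(int(info.get("INDOMAIN", 0))),
                splicing_impact=str(info.get("HSF", "na")),
            )
        )
    return out


def read_variants(path) -> list[AnnotatedVariant]:
    """Read an annotated variant table (TSV, or VCF with annotation INFO keys)."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return _read_variants_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "coding_hgvs", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"variant table missing required columns: {sorted(missing)}")
    return [
        _variant_from_row(row, row.get("coding_hgvs") or str(idx + 2))
        for idx, row in df.iterrows()
    ]


def _variant_to_row(v: AnnotatedVariant) -> dict:
    return {
        "gene": v.gene,
        "chrom": v.chrom or "—",
        "position": "—" if v.position is None else str(v.position),
        "type_label": v.type_label or "—",
        "coding_hgvs": v.coding_hgvs,
        "protein_hgvs": v.protein_hgvs or "—",
        "coverage": str(v.coverage),
        "gnomad_af": "—" if v.gnomad_af is None else repr(float(v.gnomad_af)),
        "internal_ref_count": str(v.internal_ref_count),
        "insilico_verdict": v.insilico_verdict,
        "in_domain": "true" if v.in_domain else "false",
        "splicing_impact": v.splicing_impact,
        "zygosity": v.zygosity,
        "carriers": ";".join(v.carriers) if v.carriers else "—",
    }


def variant_frame(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    return pd.DataFrame([_variant_to_row(v) for v in variants], columns=VARIANT_COLUMNS)


def read_constraints(path) -> dict[str, GeneConstraint]:
    """Read a gene-constraint table (columns gene, z_missense, z_lof, benign_cutoff_freq)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "z_missense", "z_lof", "benign_cutoff_freq"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"constraint table missing required columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        gc = GeneConstraint(
            gene=row["gene"].strip(),
            z_missense=float(row["z_missense"]),
            z_lof=float(row["z_lof"]),
            benign_cutoff_freq=float(row["benign_cutoff_freq"]),
        )
        out[gc.gene] = gc
    return out


def write_report(results: Sequence, path, *, kind: str | None = None) -> None:
    """Write per-subject or per-variant summaries as a TSV.

    ``results`` is a sequence of :class:`Subject` or :class:`AnnotatedVariant`;
    the table kind is inferred from the first element, or forced with
    ``kind`` in {"subjects", "variants"} (needed for empty sequences).
    Output round-trips bit-for-bit through :func:`read_cohort` /
    :func:`read_variants` for representable values.
    """
    results = list(results)
    if kind is None:
        if not results:
            kind = "subjects"
        elif isinstance(results[0], AnnotatedVariant):
            kind = "variants"
        else:
            kind = "subjects"
    frame = variant_frame(results) if kind == "variants" else cohort_frame(results)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED I/O (standard 6-column pedigree format)
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "M", "2": "F"}
_PED_PHENO = {"1": "unaffected", "2": "affected"}


def read_ped(path) -> list[Pedigree]:
    """Read a standard 6-column PED file into one :class:`Pedigree` per family."""
    families: dict[str, list[PedigreeMember]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"\s+", line)
        if len(fields) < 6:
            raise CohortFormatError(f"PED line has {len(fields)} fields, expected 6: {line!r}")
        fam, sid, father, mother, sex, pheno = fields[:6]
        families.setdefault(fam, []).append(
            PedigreeMember(
                subject_id=sid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_PED_SEX.get(sex, "unknown"),
                affected=_PED_PHENO.get(pheno, "unknown"),
            )
        )
    return [Pedigree(fam, tuple(members)) for fam, members in families.items()]


def write_ped(pedigrees: Iterable[Pedigree], path) -> None:
    sex_code = {"M": "1", "F": "2"}
    pheno_code = {"unaffected": "1", "affected": "2"}
    lines = []
    for ped in pedigrees:
        for m in ped.members:
            lines.append(
                "\t".join([
                    ped.family_id, m.subject_id,
                    m.father_id or "0", m.mother_id or "0",
                    sex_code.get(m.sex, "0"), pheno_code.get(m.affected, "0"),
                ])
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def with_profile(subject: Subject, profile: MethylationProfile) -> Subject:
    """Convenience: return a copy of ``subject`` with a replaced profile."""
    return replace(subject, methylation=profile)
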