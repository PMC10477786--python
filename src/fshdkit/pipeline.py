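"""End-to-end orchestration: methylation -> prioritizer -> ACMG -> family.

Given a subject table, an annotated variant table, a PED pedigree file and
a gene-constraint table, the pipeline classifies every subject's
methylation profile, filters the variant table, assigns ACMG evidence and
five-tier labels, traces variant origins through the pedigrees, and
categorizes each subject genetically.  Identical configuration and inputs
produce byte-identical reports; the run manifest records the configuration
hash and per-stage counts for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .acmg import AcmgConfig, AcmgResult, classify_all
from .core import (
    Pedigree,
    Subject,
    cohort_frame,
    read_cohort,
    read_constraints,
    read_ped,
    read_variants,
    variant_frame,
)
from .family import CategoryRules, categorize, segregate
from .methylation import ClassifierConfig, classify_subject
from .prioritizer import PrioritizerConfig, prioritize_cohort

logger = logging.getLogger("fshdkit")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    cohort_path: str
    variants_path: str
    constraints_path: str | None = None
    ped_path: str | None = None
    out_dir: str = "fshdkit_out"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    prioritizer: PrioritizerConfig = field(default_factory=PrioritizerConfig)
    acmg: AcmgConfig = field(default_factory=AcmgConfig)
    category_rules: CategoryRules = field(default_factory=CategoryRules)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("classifier", ClassifierConfig),
            ("prioritizer", PrioritizerConfig),
            ("acmg", AcmgConfig),
            ("category_rules", CategoryRules),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)


def _config_hash(config: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, frozenset):
            return sorted(obj)
        return str(obj)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    subjects: list[Subject]
    classifier_results: dict
    prioritization: object
    acmg_results: list[AcmgResult]
    acmg_tally: dict
    segregations: dict  # variant_key -> {subject_id: origin}
    categories: dict  # subject_id -> category
    manifest: dict


def _segregate_all(
    pedigrees: list[Pedigree],
    subjects: list[Subject],
    variant_keys: list[str],
) -> dict:
    """Trace each variant through every family whose members carry it.

    Every subject present in the cohort counts as genotyped for every
    variant segregating in its own family (the source tables report
    explicit negatives); subjects absent from the cohort are untested.
    """
    by_family: dict[str, list[Subject]] = {}
    for s in subjects:
        by_family.setdefault(s.family_id, []).append(s)
    ped_by_family = {p.family_id: p for p in pedigrees}
    cohort_ids = {s.subject_id for s in subjects}
    out: dict[str, dict[str, str]] = {}
    for key in variant_keys:
        calls: dict[str, str] = {}
        for family_id, members in by_family.items():
            if not any(key in m.variants for m in members):
                continue
            ped = ped_by_family.get(family_id)
            if ped is None:
                for m in members:
                    if key in m.variants:
                        calls[m.subject_id] = "undetermined"
                continue
            carried = {m.subject_id: key in m.variants for m in members}
            status = {
                m.subject_id: carried.get(m.subject_id, False)
                if m.subject_id in cohort_ids
                else None
                for m in ped.members
            }
            for call in segregate(ped, status, key):
                calls[call.subject_id] = call.origin
        out[key] = calls
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the reports and manifest to ``out_dir``."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        subjects = read_cohort(config.cohort_path)
    except Exception as exc:
        raise RuntimeError(f"stage cohort-reading failed: {exc}") from exc
    try:
        variants = read_variants(config.variants_path)
    except Exception as exc:
        raise RuntimeError(f"stage variant-reading failed: {exc}") from exc
    constraints = (
        read_constraints(config.constraints_path) if config.constraints_path else {}
    )
    pedigrees = read_ped(config.ped_path) if config.ped_path else []

    # stage 1: methylation classification
    classifier_results = {
        s.subject_id: classify_subject(s, config.classifier) for s in subjects
    }
    logger.info("classified %d subjects", len(subjects))

    # stage 2: variant prioritization
    summary = prioritize_cohort(variants, config.prioritizer, constraints)
    logger.info("retained %d / %d variants", summary.n_retained, len(variants))

    # stage 3: segregation + ACMG
    retained_keys = [d.variant.key for d in summary.retained]
    segregations = _segregate_all(pedigrees, subjects, retained_keys)
    variant_origin = {
        key: ("de_novo" if "de_novo" in calls.values() else next(iter(calls.values()), "undetermined"))
        for key, calls in segregations.items()
    }
    acmg_results, acmg_tally = classify_all(
        list(summary.retained),
        segregations=variant_origin,
        constraints=constraints,
        config=config.acmg,
    )
    label_by_key = {r.variant.key: r.label for r in acmg_results}

    # stage 4: genetic categorization
    categories = {}
    for s in subjects:
        has_modifier = any(
            label_by_key.get(v) in {"pathogenic", "likely_pathogenic"} for v in s.variants
        )
        categories[s.subject_id] = categorize(
            s, has_modifier, classifier_results[s.subject_id].label, config.category_rules
        )

    manifest = {
        "fshdkit_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "counts": {
            "subjects": len(subjects),
            "variants_in": len(variants),
            "variants_retained": summary.n_retained,
            "acmg_tally": dict(sorted(acmg_tally.items())),
            "families": len({s.family_id for s in subjects}),
        },
    }

    _write_reports(
        out_dir, subjects, classifier_results, summary, acmg_results,
        segregations, categories, manifest,
    )
    return PipelineResult(
        subjects=subjects,
        classifier_results=classifier_results,
        prioritization=summary,
        acmg_results=acmg_results,
        acmg_tally=acmg_tally,
        segregations=segregations,
        categories=categories,
        manifest=manifest,
    )


def _write_reports(out_dir, subjects, classifier_results, summary, acmg_results,
                   segregations, categories, manifest):
    subject_report = cohort_frame(subjects)
    subject_report["predicted_node"] = [
        classifier_results[s.subject_id].node for s in subjects
    ]
    subject_report["predicted_label"] = [
        classifier_results[s.subject_id].label for s in subjects
    ]
    subject_report["category"] = [categories[s.subject_id] for s in subjects]
    subject_report.to_csv(out_dir / "subject_report.tsv", sep="\t", index=False)

    acmg_by_key = {r.variant.key: r for r in acmg_results}
    variant_report = variant_frame([d.variant for d in summary.retained])
    keys = [d.variant.key for d in summary.retained]
    variant_report["variant_class"] = [d.variant_class.tally_class for d in summary.retained]
    variant_report["flags"] = [";".join(sorted(d.flags)) or "—" for d in summary.retained]
    variant_report["acmg_criteria"] = [acmg_by_key[k].trace for k in keys]
    variant_report["acmg_label"] = [acmg_by_key[k].label for k in keys]
    variant_report["segregation"] = [
        ";".join(f"{sid}:{origin}" for sid, origin in sorted(segregations.get(k, {}).items()))
        or "—"
        for k in keys
    ]
    variant_report.to_csv(out_dir / "variant_report.tsv", sep="\t", index=False)

    family_rows = []
    for s in subjects:
        origins = [
            segregations.get(v, {}).get(s.subject_id, "undetermined") for v in s.variants
        ]
        family_rows.append({
            "family_id": s.family_id,
            "subject_id": s.subject_id,
            "relation": s.relation or "—",
            "affected": s.affected,
            "variants": ";".join(s.variants) or "—",
            "origins": ";".join(origins) or "—",
            "predicted_node": classifier_results[s.subject_id].node,
            "predicted_label": classifier_results[s.subject_id].label,
            "category": categories[s.subject_id],
        })
    import pandas as pd

    pd.DataFrame(family_rows).to_csv(out_dir / "family_report.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
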