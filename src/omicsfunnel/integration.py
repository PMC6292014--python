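"""Cross-case variant intersection, quality stratification, omics integration
and verification-cohort rules — the gene-and-variant filtration funnel.

Stages (each a pure function):

1. intersect the per-case variant lists (keyed by locus identity, with
   per-case genotypes retained on the merged record);
2. stratify the shared variants by genotype quality (GQ/DP thresholds over
   the discovery samples);
3. integrate with the transcriptome and pathway layers: a candidate is a
   (variant, gene) pair whose gene passed the differential-expression filter
   and belongs to at least one significant pathway;
4. verify candidates in independent pedigree/control cohorts: present in a
   case cohort and absent from every control -> possible putative mutation;
   present in cases and controls -> potential putative effect modifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_core import (
    CohortError,
    DERecord,
    GenotypeCall,
    PathwaySet,
    SampleInfo,
    VariantRecord,
)


@dataclass
class IntegratedCandidate:
    variant: VariantRecord
    gene: str
    de_record: DERecord
    pathways: frozenset
    rare: Optional[bool]  # None when the variant carries no MAF annotation

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("an integrated candidate must sit in >= 1 pathway")


@dataclass
class VerificationStatus:
    verdict: str  # possible_putative_mutation | potential_putative_effect_modifier | unsupported
    supporting_cohorts: list = field(default_factory=list)
    control_carriers: int = 0


def intersect_case_variants(per_case_lists: Sequence[Sequence[VariantRecord]]) -> list:
    """Variants present in every case list, keyed by locus identity only.

    Genotypes may differ across cases; per-case calls are merged onto the
    returned records.  Order follows the first list.
    """
    if len(per_case_lists) < 2:
        raise ValueError("need at least 2 case variant lists to intersect")
    key_sets = [{record.key for record in case} for case in per_case_lists]
    shared_keys = set.intersection(*key_sets)

    merged: dict = {}
    order = []
    for case in per_case_lists:
        for record in case:
            if record.key not in shared_keys:
                continue
            if record.key not in merged:
                merged[record.key] = VariantRecord(
                    key=record.key,
                    rsid=record.rsid,
                    gene=record.gene,
                    consequence=record.consequence,
                    maf=record.maf,
                    calls=dict(record.calls),
                )
                order.append(record.key)
            else:
                target = merged[record.key]
                target.calls.update(record.calls)
                if target.rsid is None:
                    target.rsid = record.rsid
                if target.gene is None:
                    target.gene = record.gene
                if target.maf is None:
                    target.maf = record.maf
    return [merged[key] for key in order]


def merge_calls(records: Sequence[VariantRecord], extra: Sequence[VariantRecord]) -> None:
    """Attach calls from ``extra`` (e.g. control VCFs) onto matching records."""
    by_key = {record.key: record for record in records}
    for record in extra:
        target = by_key.get(record.key)
        if target is not None:
            for sample_id, call in record.calls.items():
                target.calls.setdefault(sample_id, call)


def _call_passes(call: GenotypeCall, min_gq: int, min_dp: int, missing_passes: bool) -> bool:
    if call.code == "missing":
        return True
    for value, threshold in ((call.gq, min_gq), (call.dp, min_dp)):
        if value is None:
            if not missing_passes:
                return False
        elif value < threshold:
            return False
    return True


def quality_stratify(
    variants: Sequence[VariantRecord],
    min_gq: int = 20,
    min_dp: int = 10,
    samples: Optional[Iterable[str]] = None,
    missing_passes: bool = True,
) -> tuple:
    """Split variants into (passing, failing) by per-call GQ/DP thresholds.

    A variant passes iff every non-missing call (restricted to ``samples``
    when given — by default the discovery samples attached to the record)
    satisfies gq >= min_gq and dp >= min_dp.  Calls lacking GQ/DP pass by
    default (``missing_passes``).
    """
    if min_gq < 0 or min_dp < 0:
        raise ValueError("quality thresholds must be non-negative")
    wanted = set(samples) if samples is not None else None
    passing, failing = [], []
    for record in variants:
        calls = [
            call
            for sid, call in record.calls.items()
            if wanted is None or sid in wanted
        ]
        if all(_call_passes(c, min_gq, min_dp, missing_passes) for c in calls):
            passing.append(record)
        else:
            failing.append(record)
    return passing, failing


def integrate(
    shared_variants: Sequence[VariantRecord],
    retained_de: Mapping[str, DERecord],
    significant_pathways: Sequence[PathwaySet],
    rare_maf: float = 0.01,
) -> list:
    """Overlap shared variants with DE genes sitting in significant pathways.

    Emits one candidate per (variant, gene) where the variant's gene passed
    the DE filter AND belongs to >= 1 significant pathway.  The rare flag is
    maf < rare_maf when a MAF annotation is present, else undefined (None).
    """
    candidates = []
    for record in shared_variants:
        gene = record.gene
        if gene is None or gene not in retained_de:
            continue
        memberships = frozenset(
            pathway.name for pathway in significant_pathways if gene in pathway.genes
        )
        if not memberships:
            continue
        rare = None if record.maf is None else bool(record.maf < rare_maf)
        candidates.append(
            IntegratedCandidate(
                variant=record,
                gene=gene,
                de_record=retained_de[gene],
                pathways=memberships,
                rare=rare,
            )
        )
    return candidates


def verify_in_cohorts(
    candidate,
    required_genotype: str,
    verification_samples: Sequence[SampleInfo],
) -> VerificationStatus:
    """Check a candidate variant against independent pedigree/control cohorts.

    ``required_genotype`` is ``"carrier"`` (dosage >= 1) or ``"hom_alt"``.
    Samples with phenotype ``case`` form the pedigree-case cohorts (grouped
    by cohort label); samples with phenotype ``control`` or ``unknown`` form
    the control side.  Verdicts: found in >= 1 case cohort and in no control
    -> possible putative mutation; found in cases and in >= 1 control ->
    potential putative effect modifier; otherwise unsupported.
    """
    if required_genotype not in ("carrier", "hom_alt"):
        raise ValueError(f"unknown required genotype {required_genotype!r}")
    if not verification_samples:
        raise CohortError("empty verification sample set")
    record = candidate.variant if hasattr(candidate, "variant") else candidate
    calls = record.calls if record is not None else {}

    def has_required(sample_id: str) -> bool:
        call = calls.get(sample_id)
        if call is None or call.dosage is None:
            return False
        return call.dosage >= 1 if required_genotype == "carrier" else call.dosage == 2

    supporting = []
    seen_cohorts = []
    control_carriers = 0
    for sample in verification_samples:
        if sample.phenotype == "case":
            if sample.cohort not in seen_cohorts:
                seen_cohorts.append(sample.cohort)
            if has_required(sample.sample_id) and sample.cohort not in supporting:
                supporting.append(sample.cohort)
        else:  # control or unknown: the no-disease comparator
            if has_required(sample.sample_id):
                control_carriers += 1

    if supporting and control_carriers == 0:
        verdict = "possible_putative_mutation"
    elif supporting and control_carriers > 0:
        verdict = "potential_putative_effect_modifier"
    else:
        verdict = "unsupported"
    return VerificationStatus(
        verdict=verdict,
        supporting_cohorts=supporting,
        control_carriers=control_carriers,
    )


def funnel_counts(
    all_case_variants: Sequence[Sequence[VariantRecord]],
    shared_variants: Sequence[VariantRecord],
    retained_de: Mapping[str, DERecord],
    candidates: Sequence[IntegratedCandidate],
    rare_maf: float = 0.01,
) -> list:
    """Ordered stage counts for the filtration funnel.

    ``total`` counts distinct variants across the per-case lists;
    ``intersection`` the shared variants; ``dbsnp_known`` those with an rsID;
    ``in_de_genes`` those whose gene passed the DE filter; ``rare`` the
    annotated-MAF subset of the DE stage below ``rare_maf``; ``in_pathways``
    the distinct variants among the integrated candidates.  ``rare`` and
    ``in_pathways`` are sibling refinements of ``in_de_genes``; counts are
    monotone non-increasing along each parent-child path.
    """
    total = len({record.key for case in all_case_variants for record in case})
    in_de = [
        record
        for record in shared_variants
        if record.gene is not None and record.gene in retained_de
    ]
    rare = [record for record in in_de if record.maf is not None and record.maf < rare_maf]
    return [
        ("total", total),
        ("intersection", len(shared_variants)),
        ("dbsnp_known", sum(1 for record in shared_variants if record.rsid is not None)),
        ("in_de_genes", len(in_de)),
        ("rare", len(rare)),
        ("in_pathways", len({candidate.variant.key for candidate in candidates})),
    ]
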