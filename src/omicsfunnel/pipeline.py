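"""End-to-end orchestration of the integrative funnel, plus hub prioritization.

Stages run in order: DE filter -> pathway enrichment -> cross-case variant
intersection -> genotype-quality stratification -> omics integration ->
verification-cohort check -> association/classification on the replication
cohort -> linkage disequilibrium on selected pairs -> hub ranking -> reports.

The pipeline is a pure function of (inputs, config): identical runs produce
byte-identical reports (no timestamps in provenance).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .association import ClassificationResult, classify_variants
from .de_pathway import enrich_pathways, filter_de
from .integration import (
    IntegratedCandidate,
    VerificationStatus,
    funnel_counts,
    integrate,
    intersect_case_variants,
    merge_calls,
    quality_stratify,
    verify_in_cohorts,
)
from .io_core import (
    CohortError,
    VariantKey,
    read_de_table,
    read_gmt,
    read_sample_sheet,
    read_vcf,
    write_reports,
)
from .popgen_ld import LDResult, em_haplotype_freqs

logger = logging.getLogger("omicsfunnel")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults follow the study conventions: DE q < 0.05 (status OK),
    pathway alpha 0.05 on the raw Fisher p, association alpha 0.05, rare
    variants below MAF 0.01, genotype quality GQ >= 20 and DP >= 10, and a
    hub is a putative-mutation gene in >= 2 significant pathways.
    """

    discovery_vcfs: list = field(default_factory=list)
    verification_vcf: Optional[str] = None
    replication_vcf: Optional[str] = None
    sample_sheet: str = ""
    de_table: str = ""
    de_dialect: str = "generic_tsv"
    gmt: str = ""
    q_max: float = 0.05
    require_ok: bool = True
    alpha_pathway: float = 0.05
    alpha_assoc: float = 0.05
    rare_maf: float = 0.01
    min_gq: int = 20
    min_dp: int = 10
    hub_min: int = 2
    required_genotype: str = "hom_alt"  # verification rule: hom_alt | carrier
    gene_info_key: str = "GENE"
    maf_info_key: str = "MAF"
    ld_pairs: Optional[list] = None  # [[keyA, keyB], ...] as "chrom:pos:ref>alt"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)


@dataclass
class HubRanking:
    gene: str
    n_significant_pathways: int
    pathways: list
    min_pathway_p: float
    is_hub: bool


@dataclass
class ReportBundle:
    funnel: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    verification: list = field(default_factory=list)  # (candidate, VerificationStatus)
    classifications: list = field(default_factory=list)
    ld: list = field(default_factory=list)  # (key_a, key_b, LDResult)
    hubs: list = field(default_factory=list)
    pathogenic_pathways: list = field(default_factory=list)  # (name, kind, genes)
    provenance: dict = field(default_factory=dict)

    def tables(self) -> dict:
        rows = {"provenance": self.provenance}
        rows["funnel"] = [{"stage": s, "count": c} for s, c in self.funnel]
        rows["enrichment"] = [
            {
                "pathway": e.pathway,
                "overlap": e.overlap,
                "pathway_size": e.pathway_size,
                "query_size": e.query_size,
                "universe_size": e.universe_size,
                "p": e.p,
                "q_bh": e.q_bh,
                "neg_log10_p": e.neg_log10_p,
                "significant": e.significant,
            }
            for e in self.enrichment
        ]
        rows["verification"] = [
            {
                "variant": str(candidate.variant.key),
                "gene": candidate.gene,
                "verdict": status.verdict,
                "supporting_cohorts": ",".join(status.supporting_cohorts),
                "control_carriers": status.control_carriers,
            }
            for candidate, status in self.verification
        ]
        assoc_rows = []
        class_rows = []
        for result in self.classifications:
            for construction, test in sorted(result.direct_tests.items()):
                assoc_rows.append(
                    {
                        "variant": str(result.variant),
                        "construction": construction,
                        "test": test.test,
                        "statistic": test.statistic,
                        "df": test.df,
                        "p": test.p,
                        "p_bh": result.direct_p_bh if construction == "genotype" else None,
                        "expected_warning": test.expected_warning,
                    }
                )
            for construction, test in (
                ("joint2", result.interaction_test),
                ("joint3", result.joint_disease_test),
            ):
                if test is not None:
                    assoc_rows.append(
                        {
                            "variant": str(result.variant),
                            "construction": construction,
                            "test": test.test,
                            "statistic": test.statistic,
                            "df": test.df,
                            "p": test.p,
                            "p_bh": None,
                            "expected_warning": test.expected_warning,
                        }
                    )
            class_rows.append(
                {
                    "variant": str(result.variant),
                    "gene": result.gene,
                    "verdict": result.verdict,
                    "direct_construction": "genotype" if result.direct_test else None,
                    "direct_p": result.direct_test.p if result.direct_test else None,
                    "direct_p_bh": result.direct_p_bh,
                    "best_partner": str(result.best_partner)
                    if result.best_partner
                    else None,
                    "interaction_p": result.interaction_test.p
                    if result.interaction_test
                    else None,
                    "joint_disease_p": result.joint_disease_test.p
                    if result.joint_disease_test
                    else None,
                    "alpha": result.alpha,
                }
            )
        rows["associations"] = assoc_rows
        rows["classifications"] = class_rows
        rows["ld"] = [
            {
                "variant_a": str(a),
                "variant_b": str(b),
                "f_AB": res.hap_freqs[0],
                "f_Ab": res.hap_freqs[1],
                "f_aB": res.hap_freqs[2],
                "f_ab": res.hap_freqs[3],
                "D": res.D,
                "D_prime": res.D_prime,
                "r2": res.r2,
                "n": res.n_samples,
                "iterations": res.n_iterations,
            }
            for a, b, res in self.ld
        ]
        rows["hubs"] = [
            {
                "gene": h.gene,
                "n_significant_pathways": h.n_significant_pathways,
                "min_pathway_p": h.min_pathway_p,
                "is_hub": h.is_hub,
                "pathways": ",".join(h.pathways),
            }
            for h in self.hubs
        ]
        rows["pathogenic_pathways"] = [
            {"pathway": name, "kind": kind, "genes": ",".join(sorted(genes))}
            for name, kind, genes in self.pathogenic_pathways
        ]
        return rows


def rank_hubs(
    classifications: list,
    enrichment: list,
    pathway_sets: list,
    hub_min: int = 2,
) -> list:
    """Rank putative-mutation genes by significant-pathway membership.

    A gene is a hub when it contributes to at least ``hub_min`` significant
    pathways.  Ordering: membership count descending, then smallest pathway p
    ascending, then gene name.
    """
    significant = {e.pathway: e.p for e in enrichment if e.significant}
    sets_by_name = {s.name: s for s in pathway_sets}
    mutation_genes = sorted(
        {
            c.gene
            for c in classifications
            if c.verdict == "putative_mutation" and c.gene is not None
        }
    )
    rankings = []
    for gene in mutation_genes:
        member_of = sorted(
            name
            for name in significant
            if name in sets_by_name and gene in sets_by_name[name].genes
        )
        min_p = min((significant[name] for name in member_of), default=float("nan"))
        rankings.append(
            HubRanking(
                gene=gene,
                n_significant_pathways=len(member_of),
                pathways=member_of,
                min_pathway_p=min_p,
                is_hub=len(member_of) >= hub_min,
            )
        )
    rankings.sort(key=lambda h: (-h.n_significant_pathways, h.min_pathway_p, h.gene))
    return rankings


def _stage(name: str, description: str):
    logger.info("stage %-14s %s", name, description)


def run_pipeline(config: PipelineConfig, out_dir=None) -> ReportBundle:
    """Execute the full integrative flow and (optionally) write reports."""
    samples = read_sample_sheet(config.sample_sheet)
    by_role = {}
    for s in samples:
        by_role.setdefault(s.role, []).append(s)

    # --- transcriptome layer ------------------------------------------------
    de_records = read_de_table(config.de_table, dialect=config.de_dialect)
    retained = filter_de(de_records, q_max=config.q_max, require_ok=config.require_ok)
    universe = [r.gene for r in de_records if r.status == "OK"]
    pathway_sets = read_gmt(config.gmt)
    enrichment = enrich_pathways(
        retained.keys(), pathway_sets, universe, alpha=config.alpha_pathway
    )
    significant_sets = [
        s for s in pathway_sets if s.name in {e.pathway for e in enrichment if e.significant}
    ]
    _stage("de_filter", f"{len(retained)}/{len(de_records)} genes retained")
    _stage("enrichment", f"{len(significant_sets)}/{len(pathway_sets)} pathways significant")

    # --- variant layer ------------------------------------------------------
    discovery = {s.sample_id: s for s in by_role.get("discovery", [])}
    per_sample = {}
    for path in config.discovery_vcfs:
        records = read_vcf(
            path,
            samples,
            gene_info_key=config.gene_info_key,
            maf_info_key=config.maf_info_key,
        )
        seen = {sid for record in records for sid in record.calls}
        for sid in seen:
            per_sample.setdefault(sid, []).extend(
                r for r in records if sid in r.calls
            )
    case_lists = [
        per_sample[sid]
        for sid, info in sorted(discovery.items())
        if info.phenotype == "case" and sid in per_sample
    ]
    control_lists = [
        per_sample[sid]
        for sid, info in sorted(discovery.items())
        if info.phenotype != "case" and sid in per_sample
    ]
    all_case_lists = case_lists
    shared = intersect_case_variants(case_lists)
    for extra in control_lists:
        merge_calls(shared, extra)
    passing, failing = quality_stratify(
        shared, min_gq=config.min_gq, min_dp=config.min_dp
    )
    _stage("intersection", f"{len(shared)} variants shared by all cases")
    _stage("quality", f"{len(passing)} pass GQ>={config.min_gq}, DP>={config.min_dp}")

    candidates = integrate(passing, retained, significant_sets, rare_maf=config.rare_maf)
    _stage("integration", f"{len(candidates)} (variant, gene) candidates")

    # --- verification -------------------------------------------------------
    verification_rows = []
    verification_samples = by_role.get("verification", [])
    if verification_samples and config.verification_vcf:
        ver_records = {
            r.key: r
            for r in read_vcf(
                config.verification_vcf,
                samples,
                gene_info_key=config.gene_info_key,
                maf_info_key=config.maf_info_key,
            )
        }
        for candidate in candidates:
            record = ver_records.get(candidate.variant.key)
            if record is None:
                status = VerificationStatus("unsupported", [], 0)
            else:
                status = verify_in_cohorts(
                    record, config.required_genotype, verification_samples
                )
            verification_rows.append((candidate, status))
    _stage("verification", f"{len(verification_rows)} candidates checked")

    # --- replication: association + classification ---------------------------
    classifications: list = []
    genotype_vectors = {}
    replication_samples = by_role.get("replication", [])
    if replication_samples and config.replication_vcf and candidates:
        rep_ids = [s.sample_id for s in replication_samples]
        rep_phenotypes = [s.phenotype for s in replication_samples]
        rep_records = {
            r.key: r
            for r in read_vcf(
                config.replication_vcf,
                samples,
                gene_info_key=config.gene_info_key,
                maf_info_key=config.maf_info_key,
            )
        }
        gene_of = {}
        for candidate in candidates:
            key = candidate.variant.key
            gene_of[key] = candidate.gene
            record = rep_records.get(key)
            if record is None:
                logger.warning("candidate %s absent from replication VCF", key)
                continue
            genotype_vectors[key] = record.dosages(rep_ids)
        if genotype_vectors:
            classifications = classify_variants(
                genotype_vectors, rep_phenotypes, alpha=config.alpha_assoc
            )
            for result in classifications:
                result.gene = gene_of.get(result.variant)
    _stage("classification", f"{len(classifications)} variants classified")

    # --- linkage disequilibrium ----------------------------------------------
    ld_rows = []
    pairs = []
    if config.ld_pairs:
        pairs = [
            (VariantKey.parse(a), VariantKey.parse(b)) for a, b in config.ld_pairs
        ]
    else:
        for result in classifications:
            if result.verdict == "putative_effect_modifier" and result.best_partner:
                pair = tuple(sorted((result.variant, result.best_partner), key=str))
                if pair not in pairs:
                    pairs.append(pair)
    for key_a, key_b in pairs:
        if key_a in genotype_vectors and key_b in genotype_vectors:
            ld_rows.append(
                (
                    key_a,
                    key_b,
                    em_haplotype_freqs(genotype_vectors[key_a], genotype_vectors[key_b]),
                )
            )
    _stage("ld", f"{len(ld_rows)} pairs evaluated")

    # --- prioritization -------------------------------------------------------
    hubs = rank_hubs(classifications, enrichment, pathway_sets, hub_min=config.hub_min)
    hub_genes = {h.gene for h in hubs if h.is_hub}
    modifier_genes = {
        c.gene
        for c in classifications
        if c.verdict == "putative_effect_modifier" and c.gene is not None
    }
    sets_by_name = {s.name: s for s in pathway_sets}
    pathogenic = []
    for e in enrichment:
        if not e.significant or e.pathway not in sets_by_name:
            continue
        genes = sets_by_name[e.pathway].genes
        if genes & hub_genes:
            pathogenic.append((e.pathway, "pathogenic", sorted(genes & hub_genes)))
        if genes & modifier_genes:
            pathogenic.append(
                (e.pathway, "effect_modifying", sorted(genes & modifier_genes))
            )
    _stage("prioritization", f"{len(hubs)} genes ranked, {len(pathogenic)} pathways flagged")

    bundle = ReportBundle(
        funnel=funnel_counts(all_case_lists, shared, retained, candidates, config.rare_maf),
        enrichment=enrichment,
        candidates=candidates,
        verification=verification_rows,
        classifications=classifications,
        ld=ld_rows,
        hubs=hubs,
        pathogenic_pathways=pathogenic,
        provenance={
            "package": "omicsfunnel",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "counts": {
                "de_retained": len(retained),
                "significant_pathways": len(significant_sets),
                "shared_variants": len(shared),
                "quality_failing": len(failing),
                "candidates": len(candidates),
                "classified": len(classifications),
            },
        },
    )
    if out_dir is not None:
        write_reports(bundle, out_dir)
    return bundle
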