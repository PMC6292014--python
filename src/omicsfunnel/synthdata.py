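"""Deterministic, seeded generator of case-control cohorts with planted truth.

The generator emulates the statistical structure of an integrative
RNA-Seq/exome study without any downloads:

* a small discovery cohort (default 6 cases / 4 controls) whose per-sample
  variant lists drive the intersection funnel — planted candidate variants
  are carried by every discovery case, as a real all-case intersection
  candidate is by definition;
* a verification set of pedigree cases plus population controls, constructed
  so the planted mutation is found in a pedigree and in no control, while the
  planted modifiers are found in cases and controls;
* a large replication cohort (default 500 cases / 500 controls) drawn under
  Hardy-Weinberg with case-control ascertainment by rejection sampling, in
  which genotype-phenotype association tests have realistic power;
* a differential-expression table (log-normal FPKMs, planted fold changes,
  per-gene two-sample t-tests, BH q-values) and pathway gene sets containing
  a planted hub gene, enriched for the planted DE genes.

Disease risk follows a logistic model: logit of the baseline penetrance,
plus log(mutation_effect) when the subject has the required mutation
genotype, plus log(interaction_effect) when both modifier-pair members are
carried.  Per-modifier offsets are solved numerically so that each
modifier's *marginal* association with disease is exactly null in the
population — the pair acts purely through the interaction, which is what
distinguishes an effect modifier from a mutation.

Everything is a pure function of the configuration (seed included): the same
seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import fsolve
from scipy.special import expit, logit

from .association import bh_adjust
from .io_core import DERecord, PathwaySet, SampleInfo, VariantKey

VARIANT_ROLES = ("mutation", "modifier_pair_member", "null", "ld_partner")


# ---------------------------------------------------------------------------
# Configuration and truth manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """One planted locus: frequency, role and annotations."""

    name: str
    gene: Optional[str]
    allele_freq: float
    role: str
    chrom: str = "1"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"
    rsid: Optional[str] = None
    maf: Optional[float] = None  # annotated population MAF written to INFO
    force_in_cases: bool = False  # carried by every discovery case
    low_quality: bool = False  # emitted with failing GQ in discovery cases

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(f"{self.name}: allele_freq must lie in (0, 1)")
        if self.role not in VARIANT_ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")

    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def default_variant_panel() -> tuple:
    """The default planted panel: one penetrant mutation, one pure-interaction
    modifier pair, one LD pair and assorted null variants (one rare, one
    novel, one low-quality)."""
    raw = [
        # name, gene, freq, role, rsid, maf, force, lowq
        ("VAR_MUT", "G001", 0.25, "mutation", "rs9000001", 0.25, True, False),
        ("VAR_MODA", "G002", 0.30, "modifier_pair_member", "rs9000002", 0.30, True, False),
        ("VAR_MODB", "G003", 0.30, "modifier_pair_member", None, None, True, False),
        ("VAR_LDA", "G004", 0.30, "ld_partner", "rs9000004", 0.30, True, False),
        ("VAR_LDB", "G005", 0.20, "ld_partner", "rs9000005", 0.20, True, False),
        ("VAR_NUL1", "G006", 0.30, "null", "rs9000006", 0.30, True, False),
        ("VAR_NUL2", "G007", 0.05, "null", "rs9000007", 0.005, True, False),
        ("VAR_NUL3", "G008", 0.30, "null", "rs9000008", 0.30, True, False),
        ("VAR_NUL4", "G101", 0.90, "null", "rs9000009", 0.90, False, False),
        ("VAR_NUL5", "G102", 0.30, "null", "rs9000010", 0.30, False, False),
        ("VAR_LOWQ", "G103", 0.90, "null", "rs9000011", 0.90, True, True),
    ]
    return tuple(
        VariantSpec(
            name=name,
            gene=gene,
            allele_freq=freq,
            role=role,
            pos=1000 * (i + 1),
            rsid=rsid,
            maf=maf,
            force_in_cases=force,
            low_quality=lowq,
        )
        for i, (name, gene, freq, role, rsid, maf, force, lowq) in enumerate(raw)
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    # replication cohort (association/classification power)
    n_cases: int = 500
    n_controls: int = 500
    # discovery cohort (intersection funnel)
    n_discovery_cases: int = 6
    n_discovery_controls: int = 4
    # verification cohorts (pedigrees + population controls)
    pedigrees: dict = field(
        default_factory=lambda: {"FAM001": 3, "FAM027": 5, "PED_CN": 5}
    )
    n_hapmap_controls: int = 9
    # penetrance model
    penetrance: float = 0.05
    mutation_effect: float = 8.0  # odds multiplier for the required genotype
    interaction_effect: float = 8.0  # odds multiplier when both modifiers carried
    mutation_genotype: str = "hom_alt"  # hom_alt | carrier
    # LD pair
    ld_target: float = 1.0  # target D' for the designated pair
    # variant panel
    variants: tuple = field(default_factory=default_variant_panel)
    # DE table
    n_genes: int = 200
    n_planted_de: int = 20
    fold_change: float = 4.0
    dispersion: float = 0.3  # sd of log2 FPKM around the gene mean
    n_de_cases: int = 6
    n_de_controls: int = 4
    n_lowdata: int = 5
    # pathways
    n_sets: int = 8
    set_size: int = 15
    hub_gene: str = "G001"
    hub_membership: int = 3
    # ascertainment
    max_batches: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.penetrance < 1.0:
            raise ValueError("penetrance must lie in (0, 1)")
        if self.mutation_effect <= 0 or self.interaction_effect <= 0:
            raise ValueError("odds multipliers must be positive")
        if not 0.0 <= self.ld_target <= 1.0:
            raise ValueError("ld_target (D') must lie in [0, 1]")
        if self.n_planted_de > self.n_genes:
            raise ValueError("n_planted_de exceeds n_genes")
        if self.hub_membership > self.n_sets:
            raise ValueError("hub_membership exceeds n_sets")
        if self.mutation_genotype not in ("hom_alt", "carrier"):
            raise ValueError("mutation_genotype must be hom_alt or carrier")
        self.variants = tuple(self.variants)

    # -- panel helpers -----------------------------------------------------

    def role_indices(self, role: str) -> list:
        return [i for i, v in enumerate(self.variants) if v.role == role]

    def gene_names(self) -> list:
        return [f"G{i + 1:03d}" for i in range(self.n_genes)]

    def planted_de_genes(self) -> list:
        return self.gene_names()[: self.n_planted_de]

    def lowdata_genes(self) -> list:
        return self.gene_names()[self.n_genes - self.n_lowdata :]

    @classmethod
    def from_mapping(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "variants" in data and data["variants"] is not None:
            data["variants"] = tuple(
                VariantSpec(**v) if isinstance(v, dict) else v
                for v in data["variants"]
            )
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["variants"] = [dataclasses.asdict(v) for v in self.variants]
        return out


@dataclass
class GroundTruth:
    """Planted truth serialized alongside the generated cohort."""

    seed: int
    variant_roles: dict
    variant_keys: dict
    expected_verdicts: dict  # only for planted-effect variants
    planted_de_genes: list
    recovered_de_genes: list
    lowdata_genes: list
    hub_gene: str
    enriched_pathways: list  # realized significant pathway names
    funnel: dict

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as handle:
            return cls(**json.load(handle))


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


def hap_freqs_for_target(p_a: float, p_b: float, d_prime: float) -> np.ndarray:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) with a target D' > 0."""
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie in (0, 1); monomorphic loci have no D'")
    if not 0.0 <= d_prime <= 1.0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        raise ValueError(
            f"target D' {d_prime} infeasible; D' must lie in [0, 1] "
            f"(D in [0, {d_max:.6g}])"
        )
    d = d_prime * min(p_a * (1 - p_b), (1 - p_a) * p_b)
    freqs = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    return np.clip(freqs, 0.0, 1.0)


def simulate_ld_pair(
    n: int, p_a: float, p_b: float, d_prime: float, rng: np.random.Generator
) -> tuple:
    """Sample n individuals as pairs of two-locus haplotypes.

    Returns (dosages_a, dosages_b, true_hap_freqs, sampled_hap_counts); the
    sampled counts are the phased truth that EM estimation from the unphased
    dosages should recover.
    """
    freqs = hap_freqs_for_target(p_a, p_b, d_prime)
    haps = rng.choice(4, size=(n, 2), p=freqs / freqs.sum())
    alt_a = np.isin(haps, (0, 1)).sum(axis=1)
    alt_b = np.isin(haps, (0, 2)).sum(axis=1)
    counts = np.bincount(haps.ravel(), minlength=4)
    return alt_a.astype(np.int8), alt_b.astype(np.int8), freqs, counts


def simulate_genotypes(
    config: SimulationConfig, n: Optional[int] = None, rng=None
) -> np.ndarray:
    """Draw an (n x variants) dosage matrix.

    Independent loci follow Hardy-Weinberg at their allele frequencies; the
    designated LD pair (the first two ``ld_partner`` roles) is drawn as
    two-locus haplotypes constructed to have ``ld_target`` D'.
    """
    if n is None:
        n = config.n_cases + config.n_controls
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = len(config.variants)
    genotypes = np.empty((n, m), dtype=np.int8)
    ld_pair = config.role_indices("ld_partner")[:2]
    for j, spec in enumerate(config.variants):
        if j in ld_pair:
            continue
        genotypes[:, j] = rng.binomial(2, spec.allele_freq, size=n)
    if len(ld_pair) == 2:
        ja, jb = ld_pair
        ga, gb, _, _ = simulate_ld_pair(
            n,
            config.variants[ja].allele_freq,
            config.variants[jb].allele_freq,
            config.ld_target,
            rng,
        )
        genotypes[:, ja] = ga
        genotypes[:, jb] = gb
    elif len(ld_pair) == 1:
        j = ld_pair[0]
        genotypes[:, j] = rng.binomial(2, config.variants[j].allele_freq, size=n)
    return genotypes


# ---------------------------------------------------------------------------
# Penetrance model
# ---------------------------------------------------------------------------


def _carrier_freq(allele_freq: float) -> float:
    return 1.0 - (1.0 - allele_freq) ** 2


def pure_interaction_offsets(
    penetrance: float,
    interaction_effect: float,
    f_carrier_a: float,
    f_carrier_b: float,
) -> Tuple[float, float]:
    """Per-modifier log-odds offsets nulling each marginal association.

    With an interaction term alone, carrying one modifier raises marginal
    risk through the chance of carrying the other; these offsets compensate
    so each modifier's marginal (carrier-level, hence genotype-level)
    association with disease is exactly zero in the population.
    """
    if interaction_effect == 1.0:
        return 0.0, 0.0
    b0 = float(logit(penetrance))
    bi = math.log(interaction_effect)

    def equations(x):
        a_off, b_off = x
        e1 = (
            f_carrier_b * expit(b0 + a_off + b_off + bi)
            + (1 - f_carrier_b) * expit(b0 + a_off)
        ) - (
            f_carrier_b * expit(b0 + b_off) + (1 - f_carrier_b) * expit(b0)
        )
        e2 = (
            f_carrier_a * expit(b0 + a_off + b_off + bi)
            + (1 - f_carrier_a) * expit(b0 + b_off)
        ) - (
            f_carrier_a * expit(b0 + a_off) + (1 - f_carrier_a) * expit(b0)
        )
        return [e1, e2]

    start = (-bi * f_carrier_b, -bi * f_carrier_a)
    solution, info, status, message = fsolve(equations, start, full_output=True)
    residual = float(np.abs(info["fvec"]).max())
    if status != 1 or residual > 1e-10:
        raise RuntimeError(f"marginal-balancing offsets did not converge: {message}")
    return float(solution[0]), float(solution[1])


def disease_probability(
    genotypes: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Per-subject disease probability under the logistic penetrance model."""
    eta = np.full(genotypes.shape[0], float(logit(config.penetrance)))
    for j in config.role_indices("mutation"):
        if config.mutation_genotype == "hom_alt":
            has = genotypes[:, j] == 2
        else:
            has = genotypes[:, j] >= 1
        eta += math.log(config.mutation_effect) * has
    modifiers = config.role_indices("modifier_pair_member")[:2]
    if len(modifiers) == 2:
        ja, jb = modifiers
        carrier_a = genotypes[:, ja] >= 1
        carrier_b = genotypes[:, jb] >= 1
        off_a, off_b = pure_interaction_offsets(
            config.penetrance,
            config.interaction_effect,
            _carrier_freq(config.variants[ja].allele_freq),
            _carrier_freq(config.variants[jb].allele_freq),
        )
        eta += math.log(config.interaction_effect) * (carrier_a & carrier_b)
        eta += off_a * carrier_a + off_b * carrier_b
    return expit(eta)


def assign_phenotypes(
    genotypes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli disease labels (True = case) under the penetrance model."""
    p = disease_probability(genotypes, config)
    return rng.random(genotypes.shape[0]) < p


def simulate_case_control(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Ascertain exactly (n_cases, n_controls) by rejection sampling.

    Returns (genotype matrix, phenotype array of "case"/"control"), cases
    first.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    need_cases, need_controls = config.n_cases, config.n_controls
    batch = max(1024, 2 * (need_cases + need_controls))
    case_rows, control_rows = [], []
    for _ in range(config.max_batches):
        genotypes = simulate_genotypes(config, n=batch, rng=rng)
        is_case = assign_phenotypes(genotypes, config, rng)
        case_rows.append(genotypes[is_case])
        control_rows.append(genotypes[~is_case])
        if (
            sum(len(x) for x in case_rows) >= need_cases
            and sum(len(x) for x in control_rows) >= need_controls
        ):
            break
    else:
        raise RuntimeError(
            f"could not ascertain {need_cases} cases / {need_controls} controls "
            f"within {config.max_batches} batches"
        )
    cases = np.concatenate(case_rows)[:need_cases]
    controls = np.concatenate(control_rows)[:need_controls]
    genotypes = np.concatenate([cases, controls])
    phenotypes = np.array(["case"] * need_cases + ["control"] * need_controls)
    return genotypes, phenotypes


# ---------------------------------------------------------------------------
# DE table and pathways
# ---------------------------------------------------------------------------


def simulate_de_table(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Per-gene log-normal FPKMs with planted fold changes.

    Planted genes are shifted by log2(fold_change) in cases; each gene gets a
    two-sample t-test on log2(FPKM + 1) and BH q-values across genes.
    Returns (records, planted gene list).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    planted = set(config.planted_de_genes())
    lowdata = set(config.lowdata_genes())
    if planted & lowdata:
        raise ValueError("planted DE genes overlap the LOWDATA genes")

    n_genes = config.n_genes
    mu = rng.normal(4.0, 1.0, size=n_genes)
    shift = np.array([math.log2(config.fold_change) if g in planted else 0.0 for g in genes])
    log_case = (
        mu[:, None]
        + shift[:, None]
        + rng.normal(0.0, config.dispersion, size=(n_genes, config.n_de_cases))
    )
    log_control = mu[:, None] + rng.normal(
        0.0, config.dispersion, size=(n_genes, config.n_de_controls)
    )
    fpkm_case = 2.0**log_case
    fpkm_control = 2.0**log_control

    # the noise model is homoscedastic, so the pooled-variance t-test applies
    t_stat, p = stats.ttest_ind(
        np.log2(fpkm_case + 1.0), np.log2(fpkm_control + 1.0), axis=1, equal_var=True
    )
    q = bh_adjust(p)

    records = []
    for i, gene in enumerate(genes):
        mean_case = float(fpkm_case[i].mean())
        mean_control = float(fpkm_control[i].mean())
        records.append(
            DERecord(
                gene=gene,
                fpkm_case=mean_case,
                fpkm_control=mean_control,
                log2_ratio=math.log2(mean_case / mean_control),
                test_stat=float(t_stat[i]),
                p=float(p[i]),
                q=float(q[i]),
                status="LOWDATA" if gene in lowdata else "OK",
            )
        )
    return records, sorted(planted)


def simulate_pathways(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list:
    """Gene sets with a planted hub: the hub gene sits in ``hub_membership``
    sets that are enriched for planted DE genes; remaining sets are drawn
    from non-DE genes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    planted = config.planted_de_genes()
    lowdata = set(config.lowdata_genes())
    if config.hub_gene not in genes:
        raise ValueError(f"hub gene {config.hub_gene!r} not in the gene universe")
    background = [g for g in genes if g not in set(planted) | lowdata]

    # variant-bearing planted genes must flow through the funnel
    variant_genes = [
        v.gene for v in config.variants if v.gene in set(planted) and v.gene != config.hub_gene
    ]
    must_cover = list(dict.fromkeys(variant_genes))

    sets = []
    n_planted_per_set = min(len(planted), max(len(must_cover), int(0.65 * config.set_size)))
    for i in range(config.hub_membership):
        members = [config.hub_gene]
        members += [g for k, g in enumerate(must_cover) if k % config.hub_membership == i]
        pool = [g for g in planted if g not in members]
        extra = max(0, n_planted_per_set - len(members))
        members += list(rng.choice(pool, size=min(extra, len(pool)), replace=False))
        fill = config.set_size - len(members)
        members += list(rng.choice(background, size=max(fill, 0), replace=False))
        sets.append(PathwaySet(name=f"SET{i + 1:02d}", genes=frozenset(members)))
    for i in range(config.hub_membership, config.n_sets):
        members = rng.choice(background, size=min(config.set_size, len(background)), replace=False)
        sets.append(PathwaySet(name=f"SET{i + 1:02d}", genes=frozenset(members)))
    return sets


# ---------------------------------------------------------------------------
# Discovery / verification cohort construction
# ---------------------------------------------------------------------------


def _conditional_carrier_dosage(freq: float, rng: np.random.Generator) -> int:
    """Draw a dosage from HWE conditioned on carrying >= 1 alt allele."""
    p_het = 2 * freq * (1 - freq)
    p_hom = freq * freq
    return 1 if rng.random() < p_het / (p_het + p_hom) else 2


def _draw_discovery(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Discovery genotypes: HWE, with planted candidates forced into every
    case (the all-case intersection is the point of the discovery cohort)."""
    n = config.n_discovery_cases + config.n_discovery_controls
    genotypes = simulate_genotypes(config, n=n, rng=rng)
    for j, spec in enumerate(config.variants):
        if not spec.force_in_cases:
            continue
        for row in range(config.n_discovery_cases):
            if spec.role == "mutation":
                genotypes[row, j] = 2 if config.mutation_genotype == "hom_alt" else max(
                    genotypes[row, j], 1
                )
            elif genotypes[row, j] == 0:
                genotypes[row, j] = _conditional_carrier_dosage(spec.allele_freq, rng)
    return genotypes


def _verification_samples(config: SimulationConfig) -> list:
    samples = []
    for pedigree, size in config.pedigrees.items():
        for i in range(size):
            samples.append(
                SampleInfo(f"{pedigree}_{i + 1}", "case", pedigree, "verification")
            )
    for i in range(config.n_hapmap_controls):
        samples.append(SampleInfo(f"HAP{i + 1:02d}", "unknown", "HAPMAP", "verification"))
    samples.append(SampleInfo("ITC01", "control", "ITALY_CTRL", "verification"))
    return samples


def _draw_verification(
    config: SimulationConfig, samples: Sequence[SampleInfo], rng: np.random.Generator
) -> np.ndarray:
    """Verification genotypes: the mutation is planted in one pedigree and
    kept out of every control; modifiers are planted in cases and controls."""
    genotypes = simulate_genotypes(config, n=len(samples), rng=rng)
    case_rows = [i for i, s in enumerate(samples) if s.phenotype == "case"]
    control_rows = [i for i, s in enumerate(samples) if s.phenotype != "case"]
    last_pedigree = list(config.pedigrees)[-1] if config.pedigrees else None
    planted_rows = [
        i for i, s in enumerate(samples) if s.phenotype == "case" and s.cohort == last_pedigree
    ]

    required = 2 if config.mutation_genotype == "hom_alt" else 1
    for j in config.role_indices("mutation"):
        spec = config.variants[j]
        for row in control_rows:  # controls never reach the required genotype
            if config.mutation_genotype == "hom_alt":
                if genotypes[row, j] == 2:
                    p_ref = (1 - spec.allele_freq) ** 2
                    p_het = 2 * spec.allele_freq * (1 - spec.allele_freq)
                    genotypes[row, j] = 1 if rng.random() < p_het / (p_het + p_ref) else 0
            else:
                genotypes[row, j] = 0
        for row in planted_rows[: max(2, 1)]:  # two members, pedigree-style
            genotypes[row, j] = required

    for j in config.role_indices("modifier_pair_member"):
        if case_rows and not any(genotypes[row, j] >= 1 for row in case_rows):
            genotypes[case_rows[0], j] = 1
        if control_rows:
            genotypes[control_rows[0], j] = max(genotypes[control_rows[0], j], 1)
    return genotypes


# ---------------------------------------------------------------------------
# VCF writing (synthetic cohorts only)
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=omicsfunnel-synthdata
##contig=<ID={chrom}>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(
    path,
    sample_ids: Sequence[str],
    specs: Sequence[VariantSpec],
    dosages: np.ndarray,
    gq: Optional[np.ndarray] = None,
    dp: Optional[np.ndarray] = None,
    only_carried: bool = False,
) -> None:
    """Write a (samples x variants) dosage matrix as a VCF 4.2 text file.

    With ``only_carried``, rows where no listed sample carries an alt allele
    are dropped, mimicking a per-sample variant caller's output.
    """
    chroms = sorted({spec.chrom for spec in specs})
    lines = ["##fileformat=VCFv4.2", "##source=omicsfunnel-synthdata"]
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines += _VCF_HEADER.splitlines()[3:]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))

    for j, spec in enumerate(specs):
        column = dosages[:, j]
        if only_carried and not any(d is not None and d >= 1 for d in column):
            continue
        info = []
        if spec.gene is not None:
            info.append(f"GENE={spec.gene}")
        if spec.maf is not None:
            info.append(f"MAF={spec.maf:g}")
        fields = [
            spec.chrom,
            str(spec.pos),
            spec.rsid or ".",
            spec.ref,
            spec.alt,
            ".",
            "PASS",
            ";".join(info) or ".",
            "GT:GQ:DP",
        ]
        for i in range(len(sample_ids)):
            d = column[i]
            d = None if d is None else int(d)
            g = int(gq[i, j]) if gq is not None else 99
            depth = int(dp[i, j]) if dp is not None else 40
            fields.append(f"{_GT_STRINGS[d]}:{g}:{depth}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_sample_sheet(path, samples: Sequence[SampleInfo]) -> None:
    lines = ["sample_id\tphenotype\tcohort\trole"]
    for s in samples:
        lines.append(f"{s.sample_id}\t{s.phenotype}\t{s.cohort}\t{s.role}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_de_table(path, records: Sequence[DERecord]) -> None:
    lines = ["gene\tfpkm_case\tfpkm_control\tlog2_ratio\ttest_stat\tp\tq\tstatus"]
    for r in records:
        lines.append(
            f"{r.gene}\t{r.fpkm_case:.6g}\t{r.fpkm_control:.6g}\t{r.log2_ratio:.6g}\t"
            f"{r.test_stat:.6g}\t{r.p:.6g}\t{r.q:.6g}\t{r.status}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_gmt(path, sets: Sequence[PathwaySet]) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, "synthetic gene set"] + sorted(s.genes)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Truth funnel (independent recount on the realized data)
# ---------------------------------------------------------------------------


def _truth_funnel(
    config: SimulationConfig,
    discovery: np.ndarray,
    de_records: Sequence[DERecord],
    pathway_sets: Sequence[PathwaySet],
    q_max: float = 0.05,
    alpha_pathway: float = 0.05,
    rare_maf: float = 0.01,
) -> tuple:
    """Recount the funnel stages directly from the generated matrices."""
    n_cases = config.n_discovery_cases
    carried = discovery[:n_cases] >= 1  # cases x variants presence
    in_any = carried.any(axis=0)
    in_all = carried.all(axis=0)

    retained = {r.gene for r in de_records if r.q < q_max and r.status == "OK"}
    universe = {r.gene for r in de_records if r.status == "OK"}
    query = retained & universe
    significant = []
    for pset in pathway_sets:
        members = pset.genes & universe
        overlap = len(members & query)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(query), len(members))
        )
        if p < alpha_pathway:
            significant.append(pset.name)
    significant_genes = set().union(
        *(pset.genes for pset in pathway_sets if pset.name in set(significant))
    ) if significant else set()

    specs = config.variants
    intersected = [j for j in range(len(specs)) if in_all[j]]
    in_de = [j for j in intersected if specs[j].gene in retained]
    rare = [j for j in in_de if specs[j].maf is not None and specs[j].maf < rare_maf]
    quality_pass = [j for j in intersected if not specs[j].low_quality]
    in_pathways = [
        j
        for j in quality_pass
        if specs[j].gene in retained and specs[j].gene in significant_genes
    ]
    funnel = {
        "total": int(in_any.sum()),
        "intersection": len(intersected),
        "dbsnp_known": sum(1 for j in intersected if specs[j].rsid is not None),
        "in_de_genes": len(in_de),
        "rare": len(rare),
        "in_pathways": len(in_pathways),
    }
    return funnel, significant


# ---------------------------------------------------------------------------
# Cohort emission
# ---------------------------------------------------------------------------


def emit_cohort(config: SimulationConfig, out_dir) -> tuple:
    """Write the full synthetic cohort and its truth manifest.

    Produces per-sample discovery VCFs, a multi-sample verification VCF, a
    multi-sample replication VCF, a sample sheet, a DE table (generic TSV), a
    GMT file and ``truth.json``.  Returns (manifest dict of paths,
    GroundTruth).  Re-reading the files through the io_core readers
    reproduces the in-memory objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    de_records, planted = simulate_de_table(config, rng=rng)
    pathway_sets = simulate_pathways(config, rng=rng)

    discovery_samples = [
        SampleInfo(f"DCASE{i + 1}", "case", "discovery", "discovery")
        for i in range(config.n_discovery_cases)
    ] + [
        SampleInfo(f"DCTRL{i + 1}", "control", "discovery", "discovery")
        for i in range(config.n_discovery_controls)
    ]
    discovery = _draw_discovery(config, rng)
    n_disc = len(discovery_samples)
    m = len(config.variants)
    gq = rng.integers(30, 100, size=(n_disc, m))
    dp = 20 + rng.poisson(20, size=(n_disc, m))
    for j, spec in enumerate(config.variants):
        if spec.low_quality:
            gq[: config.n_discovery_cases, j] = 5

    verification_samples = _verification_samples(config)
    verification = _draw_verification(config, verification_samples, rng)
    ver_gq = rng.integers(30, 100, size=(len(verification_samples), m))
    ver_dp = 20 + rng.poisson(20, size=(len(verification_samples), m))

    replication, rep_phenotypes = simulate_case_control(config, rng=rng)
    replication_samples = [
        SampleInfo(f"RCASE{i + 1:04d}", "case", "replication", "replication")
        for i in range(config.n_cases)
    ] + [
        SampleInfo(f"RCTRL{i + 1:04d}", "control", "replication", "replication")
        for i in range(config.n_controls)
    ]
    assert list(rep_phenotypes) == [s.phenotype for s in replication_samples]
    rep_gq = rng.integers(30, 100, size=(len(replication_samples), m))
    rep_dp = 20 + rng.poisson(20, size=(len(replication_samples), m))

    manifest = {}
    discovery_dir = out_dir / "discovery"
    discovery_dir.mkdir(exist_ok=True)
    discovery_vcfs = []
    for i, sample in enumerate(discovery_samples):
        path = discovery_dir / f"{sample.sample_id}.vcf"
        write_vcf(
            path,
            [sample.sample_id],
            config.variants,
            discovery[i : i + 1],
            gq[i : i + 1],
            dp[i : i + 1],
            only_carried=True,
        )
        discovery_vcfs.append(str(path))
    manifest["discovery_vcfs"] = discovery_vcfs

    verification_path = out_dir / "verification.vcf"
    write_vcf(
        verification_path,
        [s.sample_id for s in verification_samples],
        config.variants,
        verification,
        ver_gq,
        ver_dp,
    )
    manifest["verification_vcf"] = str(verification_path)

    replication_path = out_dir / "replication.vcf"
    write_vcf(
        replication_path,
        [s.sample_id for s in replication_samples],
        config.variants,
        replication,
        rep_gq,
        rep_dp,
    )
    manifest["replication_vcf"] = str(replication_path)

    all_samples = discovery_samples + verification_samples + replication_samples
    sheet_path = out_dir / "samples.tsv"
    _write_sample_sheet(sheet_path, all_samples)
    manifest["sample_sheet"] = str(sheet_path)

    de_path = out_dir / "de_table.tsv"
    _write_de_table(de_path, de_records)
    manifest["de_table"] = str(de_path)

    gmt_path = out_dir / "pathways.gmt"
    _write_gmt(gmt_path, pathway_sets)
    manifest["gmt"] = str(gmt_path)

    funnel, significant = _truth_funnel(config, discovery, de_records, pathway_sets)
    expected_verdicts = {}
    for j in config.role_indices("mutation"):
        expected_verdicts[str(config.variants[j].key())] = "putative_mutation"
    for j in config.role_indices("modifier_pair_member")[:2]:
        expected_verdicts[str(config.variants[j].key())] = "putative_effect_modifier"
    truth = GroundTruth(
        seed=config.seed,
        variant_roles={v.name: v.role for v in config.variants},
        variant_keys={v.name: str(v.key()) for v in config.variants},
        expected_verdicts=expected_verdicts,
        planted_de_genes=planted,
        recovered_de_genes=sorted(
            r.gene for r in de_records if r.q < 0.05 and r.status == "OK"
        ),
        lowdata_genes=config.lowdata_genes(),
        hub_gene=config.hub_gene,
        enriched_pathways=sorted(significant),
        funnel=funnel,
    )
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    manifest["truth"] = str(truth_path)
    return manifest, truth


# ---------------------------------------------------------------------------
# Recovery study (operating characteristics of the classification engine)
# ---------------------------------------------------------------------------


def classification_recovery_study(
    n_seeds: int = 200, base_seed: int = 0, **config_overrides
) -> dict:
    """Planted-truth recovery rates of the classification engine over seeds.

    For each seed a replication cohort is ascertained under the default
    penetrance model and every panel variant is classified.  Returns the
    mutation recovery rate, per-modifier recovery rates, the rate at which
    the modifiers show a (false) direct association, and the pooled rate at
    which variants with no planted effect (null and LD-partner roles) are
    labelled putative mutations.
    """
    from .association import classify_variants

    mutation_hits = 0
    modifier_hits = [0, 0]
    modifier_direct = 0
    null_hits = 0
    null_trials = 0
    for i in range(n_seeds):
        config = SimulationConfig(seed=base_seed + i, **config_overrides)
        genotypes, phenotypes = simulate_case_control(config)
        vectors = {v.name: genotypes[:, j] for j, v in enumerate(config.variants)}
        results = {r.variant: r for r in classify_variants(vectors, phenotypes)}
        for j in config.role_indices("mutation"):
            mutation_hits += results[config.variants[j].name].verdict == "putative_mutation"
        for k, j in enumerate(config.role_indices("modifier_pair_member")[:2]):
            result = results[config.variants[j].name]
            modifier_hits[k] += result.verdict == "putative_effect_modifier"
            if result.direct_test is not None and result.direct_test.p < result.alpha:
                modifier_direct += 1
        for j in config.role_indices("null") + config.role_indices("ld_partner"):
            null_trials += 1
            null_hits += results[config.variants[j].name].verdict == "putative_mutation"
    return {
        "n_seeds": n_seeds,
        "mutation_recovery": mutation_hits / n_seeds,
        "modifier_recovery_a": modifier_hits[0] / n_seeds,
        "modifier_recovery_b": modifier_hits[1] / n_seeds,
        "modifier_direct_rate": modifier_direct / (2 * n_seeds),
        "null_mutation_rate": null_hits / null_trials,
        "n_null_trials": null_trials,
    }
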