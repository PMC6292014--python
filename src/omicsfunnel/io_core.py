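"""Shared data model and readers/writers for the pipeline's external formats.

The pipeline consumes per-sample variant calls (VCF 4.x with GT and optional
GQ/DP), a differential-expression table (Cuffdiff-style ``.diff`` or a generic
TSV), pathway gene sets (GMT) and a phenotype sample sheet (TSV), and emits
deterministic TSV/JSON reports.

Conventions
-----------
* Coordinates are 1-based, fully closed (VCF convention).
* Gene symbols are uppercased on load.
* Genotypes are genotype-based, not phase-based: ``|`` separators are treated
  like ``/``.
* Multi-allelic sites are split into one record per (site, alt) pair, with
  per-alt dosages.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence


class FormatError(ValueError):
    """An input file violates its format contract."""


class CohortError(ValueError):
    """Samples or phenotypes are inconsistent with the cohort design."""


# ---------------------------------------------------------------------------
# Genotype vocabulary
# ---------------------------------------------------------------------------

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPE_CODES = (HOM_REF, HET, HOM_ALT, MISSING)
_CODE_DOSAGE = {HOM_REF: 0, HET: 1, HOM_ALT: 2}
_DOSAGE_CODE = {0: HOM_REF, 1: HET, 2: HOM_ALT}

PHENOTYPES = ("case", "control", "unknown")
ROLES = ("discovery", "verification", "replication")
DE_STATUSES = ("OK", "LOWDATA", "HIDATA", "FAIL")

_ALLELE_CHARS = set("ACGTN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantKey:
    """Locus identity: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", str(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"invalid {name} allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse ``chrom:pos:ref>alt`` (as printed by ``str``)."""
        try:
            chrom, pos, alleles = text.split(":")
            ref, alt = alleles.split(">")
            return cls(chrom, int(pos), ref, alt)
        except ValueError as exc:
            raise FormatError(f"cannot parse variant key {text!r}") from exc


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one (site, alt) pair."""

    sample_id: str
    code: str
    dosage: Optional[int]
    gq: Optional[int] = None
    dp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.code not in GENOTYPE_CODES:
            raise ValueError(f"unknown genotype code {self.code!r}")
        if self.code == MISSING:
            if self.dosage is not None:
                raise ValueError("missing genotype cannot carry a dosage")
        elif self.dosage != _CODE_DOSAGE[self.code]:
            raise ValueError(
                f"dosage {self.dosage} inconsistent with code {self.code}"
            )
        for name in ("gq", "dp"):
            value = getattr(self, name)
            if value is not None and (not isinstance(value, int) or value < 0):
                raise ValueError(f"{name} must be a non-negative integer or None")

    @classmethod
    def from_dosage(
        cls,
        sample_id: str,
        dosage: Optional[int],
        gq: Optional[int] = None,
        dp: Optional[int] = None,
    ) -> "GenotypeCall":
        if dosage is None:
            return cls(sample_id, MISSING, None, gq, dp)
        return cls(sample_id, _DOSAGE_CODE[int(dosage)], int(dosage), gq, dp)


@dataclass
class VariantRecord:
    """One called variant with per-sample genotype calls and annotations."""

    key: VariantKey
    rsid: Optional[str] = None
    gene: Optional[str] = None
    consequence: Optional[str] = None
    maf: Optional[float] = None
    calls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene is not None:
            self.gene = self.gene.upper()
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF must lie in [0, 1], got {self.maf}")

    def dosages(self, sample_ids: Sequence[str]) -> list:
        """Dosage per sample (None where missing or uncalled)."""
        out = []
        for sid in sample_ids:
            call = self.calls.get(sid)
            out.append(None if call is None else call.dosage)
        return out


@dataclass
class DERecord:
    """One gene's differential-expression test row."""

    gene: str
    fpkm_case: float
    fpkm_control: float
    log2_ratio: float
    test_stat: float
    p: float
    q: float
    status: str

    def __post_init__(self) -> None:
        self.gene = self.gene.upper()
        if self.fpkm_case < 0 or self.fpkm_control < 0:
            raise ValueError(f"{self.gene}: FPKM must be non-negative")
        for name in ("p", "q"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{self.gene}: {name}={value} outside [0, 1]")
        if self.status not in DE_STATUSES:
            raise ValueError(f"{self.gene}: unknown status {self.status!r}")
        if self.fpkm_case > 0 and self.fpkm_control > 0:
            expected = math.log2(self.fpkm_case / self.fpkm_control)
            if abs(expected) > 1e-9 and expected * self.log2_ratio < 0:
                raise ValueError(
                    f"{self.gene}: log2_ratio sign disagrees with FPKM pair"
                )


@dataclass(frozen=True)
class SampleInfo:
    """One subject of the study design (stratum, phenotype and role)."""

    sample_id: str
    phenotype: str
    cohort: str
    role: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set (the stand-in carrier for curated pathways)."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


# ---------------------------------------------------------------------------
# Gene map fallback (chrom, start, end, gene; 1-based closed)
# ---------------------------------------------------------------------------


class GeneMap:
    """Interval lookup used when variants carry no gene annotation."""

    def __init__(self, intervals: Iterable) -> None:
        self._by_chrom: dict = {}
        for chrom, start, end, gene in intervals:
            self._by_chrom.setdefault(str(chrom), []).append(
                (int(start), int(end), gene.upper())
            )
        for rows in self._by_chrom.values():
            rows.sort()

    def lookup(self, chrom: str, pos: int) -> Optional[str]:
        for start, end, gene in self._by_chrom.get(str(chrom), ()):
            if start <= pos <= end:
                return gene
        return None


def read_gene_map(path) -> GeneMap:
    intervals = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return GeneMap(intervals)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _format_int_field(variant, tag: str) -> Optional[list]:
    """Per-sample integer FORMAT values; None where absent or missing."""
    try:
        arr = variant.format(tag)
    except Exception:
        return None
    if arr is None:
        return None
    out = []
    for row in arr:
        value = row[0] if getattr(row, "__len__", None) else row
        try:
            value = float(value)
        except (TypeError, ValueError):
            out.append(None)
            continue
        out.append(None if (math.isnan(value) or value < 0) else int(value))
    return out


def read_vcf(
    path,
    cohort_design: Optional[Sequence[SampleInfo]] = None,
    *,
    gene_info_key: str = "GENE",
    maf_info_key: str = "MAF",
    consequence_info_key: str = "CSQ",
    gene_map: Optional[GeneMap] = None,
    on_unknown_sample: str = "skip",
) -> list:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alternate allele, with
    dosages counted per alt.  GT values ``0/1``, ``1/0`` (and phased
    equivalents) map to het, ``1/1`` to hom_alt, ``0/0`` to hom_ref and
    ``./.`` to missing.  The rsID is taken from the ID column; gene and MAF
    annotations are read from configurable INFO keys, with an optional
    interval gene map as fallback.

    Samples present in the VCF but absent from ``cohort_design`` are skipped
    with a warning, or rejected when ``on_unknown_sample="error"``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # malformed header surfaces here
        raise FormatError(f"{path}: malformed VCF: {exc}") from None

    known = None
    if cohort_design is not None:
        known = {s.sample_id for s in cohort_design}
        unknown = [s for s in samples if s not in known]
        if unknown:
            if on_unknown_sample == "error":
                raise CohortError(
                    f"{path}: samples absent from cohort design: {unknown}"
                )
            warnings.warn(
                f"{path}: skipping samples absent from cohort design: {unknown}",
                stacklevel=2,
            )

    records = []
    for variant in vcf:
        try:
            genotypes = variant.genotypes
        except Exception as exc:
            raise FormatError(f"{path}: {variant.CHROM}:{variant.POS}: {exc}") from None
        gqs = _format_int_field(variant, "GQ")
        dps = _format_int_field(variant, "DP")
        rsid = variant.ID if variant.ID not in (None, ".", "") else None
        gene = variant.INFO.get(gene_info_key)
        if gene is None and gene_map is not None:
            gene = gene_map.lookup(variant.CHROM, variant.POS)
        maf = variant.INFO.get(maf_info_key)
        if maf is not None:
            try:
                maf = float(maf)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: {variant.CHROM}:{variant.POS}: non-numeric MAF {maf!r}"
                ) from None
        consequence = variant.INFO.get(consequence_info_key)

        for alt_index, alt in enumerate(variant.ALT, start=1):
            if not set(alt.upper()) <= _ALLELE_CHARS:
                continue  # symbolic / spanning-deletion alleles
            calls = {}
            for sample_index, sample_id in enumerate(samples):
                if known is not None and sample_id not in known:
                    continue
                alleles = genotypes[sample_index][:-1]
                gq = gqs[sample_index] if gqs is not None else None
                dp = dps[sample_index] if dps is not None else None
                if not alleles or any(a is None or a < 0 for a in alleles):
                    calls[sample_id] = GenotypeCall(sample_id, MISSING, None, gq, dp)
                else:
                    dosage = sum(1 for a in alleles if a == alt_index)
                    calls[sample_id] = GenotypeCall.from_dosage(
                        sample_id, dosage, gq, dp
                    )
            try:
                key = VariantKey(variant.CHROM, variant.POS, variant.REF, alt)
            except ValueError as exc:
                raise FormatError(f"{path}: {exc}") from None
            records.append(
                VariantRecord(
                    key=key,
                    rsid=rsid,
                    gene=gene,
                    consequence=consequence,
                    maf=maf,
                    calls=calls,
                )
            )
    return records


# ---------------------------------------------------------------------------
# DE table reading
# ---------------------------------------------------------------------------

DE_DIALECTS = ("cuffdiff_diff", "generic_tsv")

_GENERIC_COLUMNS = {
    "gene": "gene",
    "fpkm_case": "fpkm_case",
    "fpkm_control": "fpkm_control",
    "log2_ratio": "log2_ratio",
    "test_stat": "test_stat",
    "p": "p",
    "q": "q",
    "status": "status",
}

# Cuffdiff convention: sample_1 = control, sample_2 = case, so that
# log2(fold_change) = log2(value_2 / value_1) compares cases over controls.
_CUFFDIFF_COLUMNS = {
    "gene": "gene",
    "fpkm_control": "value_1",
    "fpkm_case": "value_2",
    "log2_ratio": "log2(fold_change)",
    "test_stat": "test_stat",
    "p": "p_value",
    "q": "q_value",
    "status": "status",
}

_STATUS_MAP = {s: s for s in DE_STATUSES}
_STATUS_MAP["NOTEST"] = "FAIL"


def _parse_float(token: str, path, lineno: int, column: str) -> float:
    token = token.strip()
    lowered = token.lower()
    if lowered in ("inf", "+inf", "infinity"):
        return math.inf
    if lowered in ("-inf", "-infinity"):
        return -math.inf
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: line {lineno}: non-numeric value {token!r} in column {column}"
        ) from None


def read_de_table(path, dialect: str = "generic_tsv") -> list:
    """Read a differential-expression TSV into :class:`DERecord` objects."""
    if dialect not in DE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DE_DIALECTS}")
    colmap = _GENERIC_COLUMNS if dialect == "generic_tsv" else _CUFFDIFF_COLUMNS

    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file (missing header)") from None
        index = {name: i for i, name in enumerate(header)}
        for logical, column in colmap.items():
            if column not in index:
                raise FormatError(f"{path}: missing required column {column!r}")

        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise FormatError(f"{path}: line {lineno}: too few fields")
            cell = lambda logical: row[index[colmap[logical]]]  # noqa: E731
            status_token = cell("status").strip().upper()
            if status_token not in _STATUS_MAP:
                raise FormatError(
                    f"{path}: line {lineno}: unknown status {status_token!r}"
                )
            try:
                records.append(
                    DERecord(
                        gene=cell("gene").strip(),
                        fpkm_case=_parse_float(cell("fpkm_case"), path, lineno, "fpkm_case"),
                        fpkm_control=_parse_float(
                            cell("fpkm_control"), path, lineno, "fpkm_control"
                        ),
                        log2_ratio=_parse_float(
                            cell("log2_ratio"), path, lineno, "log2_ratio"
                        ),
                        test_stat=_parse_float(cell("test_stat"), path, lineno, "test_stat"),
                        p=_parse_float(cell("p"), path, lineno, "p"),
                        q=_parse_float(cell("q"), path, lineno, "q"),
                        status=_STATUS_MAP[status_token],
                    )
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# GMT and sample sheet
# ---------------------------------------------------------------------------


def read_gmt(path) -> list:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated fields"
                )
            name, _description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets.append(PathwaySet(name=name, genes=frozenset(g.upper() for g in genes)))
    return sets


def read_sample_sheet(path) -> list:
    """Read the phenotype sample sheet (sample_id, phenotype, cohort, role)."""
    required = ("sample_id", "phenotype", "cohort", "role")
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file (missing header)")
        for column in required:
            if column not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {column!r}")
        samples = []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            sid = (row["sample_id"] or "").strip()
            if sid in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                samples.append(
                    SampleInfo(
                        sample_id=sid,
                        phenotype=(row["phenotype"] or "").strip(),
                        cohort=(row["cohort"] or "").strip(),
                        role=(row["role"] or "").strip(),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return samples


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

TABLE_COLUMNS = {
    "funnel": ("stage", "count"),
    "enrichment": (
        "pathway",
        "overlap",
        "pathway_size",
        "query_size",
        "universe_size",
        "p",
        "q_bh",
        "neg_log10_p",
        "significant",
    ),
    "associations": (
        "variant",
        "construction",
        "test",
        "statistic",
        "df",
        "p",
        "p_bh",
        "expected_warning",
    ),
    "classifications": (
        "variant",
        "gene",
        "verdict",
        "direct_construction",
        "direct_p",
        "direct_p_bh",
        "best_partner",
        "interaction_p",
        "joint_disease_p",
        "alpha",
    ),
    "verification": (
        "variant",
        "gene",
        "verdict",
        "supporting_cohorts",
        "control_carriers",
    ),
    "ld": (
        "variant_a",
        "variant_b",
        "f_AB",
        "f_Ab",
        "f_aB",
        "f_ab",
        "D",
        "D_prime",
        "r2",
        "n",
        "iterations",
    ),
    "hubs": ("gene", "n_significant_pathways", "min_pathway_p", "is_hub", "pathways"),
    "pathogenic_pathways": ("pathway", "kind", "genes"),
}


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def _json_default(value):
    if isinstance(value, (frozenset, set)):
        return sorted(value)
    if isinstance(value, VariantKey):
        return str(value)
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return None
    raise TypeError(f"not JSON serialisable: {type(value)}")


def write_reports(bundle, out_dir) -> dict:
    """Write the report bundle as deterministic TSV + JSON files.

    ``bundle`` is either a mapping from table name to a list of row dicts
    (plus an optional ``provenance`` dict), or any object exposing a
    ``tables()`` method returning such a mapping.  Identical inputs produce
    byte-identical files: floats are fixed-format and JSON keys are sorted.
    Returns a manifest mapping output name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = bundle.tables() if hasattr(bundle, "tables") else dict(bundle)
    provenance = tables.pop("provenance", {}) or {}

    manifest = {}
    for name, columns in TABLE_COLUMNS.items():
        rows = tables.get(name) or []
        path = out_dir / f"{name}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write("\t".join(columns) + "\n")
            for row in rows:
                handle.write(
                    "\t".join(_format_cell(row.get(col)) for col in columns) + "\n"
                )
        manifest[name] = str(path)

    json_path = out_dir / "classifications.json"
    with open(json_path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(
            tables.get("classifications") or [],
            handle,
            indent=2,
            sort_keys=True,
            default=_json_default,
        )
        handle.write("\n")
    manifest["classifications_json"] = str(json_path)

    prov_path = out_dir / "provenance.json"
    with open(prov_path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(provenance, handle, indent=2, sort_keys=True, default=_json_default)
        handle.write("\n")
    manifest["provenance"] = str(prov_path)
    return manifest
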