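"""Chi-square test battery and the putative mutation / effect-modifier engine.

The replication analyses classify each candidate variant against a
case-control cohort:

* **putative mutation** — the genotype-level contingency test (genotype
  classes x disease state) shows a direct association (p < alpha).  Carrier
  and per-genotype-stratum 2x2 tests are computed alongside to localise the
  associated genotype.
* **putative effect modifier** — no direct genotype-level association, but
  for some partner variant both the genotype x genotype independence test and
  the joint-genotype x disease test are significant.
* **unclassified** — neither.

Pearson chi-square tests use Yates' continuity correction on 2x2 tables, with
the correction term clamped at |O - E| so that perfectly proportional tables
give a statistic of exactly zero (the behaviour of the usual statistical
environments).  Missing genotypes are excluded pairwise-complete from every
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io_core import HET, HOM_ALT, HOM_REF, CohortError, VariantKey


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin or too few categories."""


_GENOTYPE_ORDER = (HOM_REF, HET, HOM_ALT)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray
    construction: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the counts matrix shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        if self.counts.sum() <= 0:
            raise DegenerateTableError("table has zero total count")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class AssociationResult:
    test: str
    statistic: float
    df: int
    p: float
    expected_warning: bool
    table: Optional[ContingencyTable] = None


def _normalise_genotype(value) -> Optional[int]:
    """Dosage in {0, 1, 2} or None for missing."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    value = int(value)
    if value < 0:
        return None
    if value > 2:
        raise ValueError(f"dosage {value} outside {{0, 1, 2}}")
    return value


def _normalise_phenotype(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip().lower()
        if value in ("case", "control"):
            return value
        if value in ("unknown", "", "na"):
            return None
        raise ValueError(f"unknown phenotype {value!r}")
    if isinstance(value, (bool, np.bool_, int, np.integer)):
        return "case" if value else "control"
    raise ValueError(f"unknown phenotype {value!r}")


def _pairwise_complete(genotypes, phenotypes):
    pairs = []
    for g, ph in zip(genotypes, phenotypes, strict=True):
        g = _normalise_genotype(g)
        ph = _normalise_phenotype(ph)
        if g is not None and ph is not None:
            pairs.append((g, ph))
    return pairs


def build_table(
    genotypes: Sequence,
    phenotypes: Sequence,
    mode: str,
    focus_genotype: Optional[str] = None,
) -> ContingencyTable:
    """Cross-classify one variant's genotypes against disease state.

    ``mode="carrier"`` gives a 2x2 (dosage >= 1 vs 0) x (case, control) table;
    ``mode="genotype"`` an up-to-3x2 table over the observed genotype classes;
    ``mode="stratum"`` a 2x2 (focus genotype vs all others) x disease table.
    Missing genotypes and unknown phenotypes are excluded; all-zero rows are
    dropped.
    """
    if mode not in ("carrier", "genotype", "stratum"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stratum":
        if focus_genotype not in _GENOTYPE_ORDER:
            raise ValueError("stratum mode requires a focus genotype class")
    pairs = _pairwise_complete(genotypes, phenotypes)
    if not pairs:
        raise DegenerateTableError("no non-missing genotype/phenotype pairs")

    cols = ("case", "control")
    if mode == "carrier":
        rows = ("carrier", "non_carrier")
        classify = lambda g: "carrier" if g >= 1 else "non_carrier"  # noqa: E731
        construction = "carrier"
    elif mode == "genotype":
        rows = _GENOTYPE_ORDER
        classify = lambda g: _GENOTYPE_ORDER[g]  # noqa: E731
        construction = "genotype"
    else:
        focus_dosage = _GENOTYPE_ORDER.index(focus_genotype)
        rows = (focus_genotype, "other")
        classify = lambda g: focus_genotype if g == focus_dosage else "other"  # noqa: E731
        construction = f"stratum:{focus_genotype}"

    counts = np.zeros((len(rows), len(cols)), dtype=float)
    for g, ph in pairs:
        counts[rows.index(classify(g)), cols.index(ph)] += 1
    keep = counts.sum(axis=1) > 0
    return ContingencyTable(
        tuple(r for r, k in zip(rows, keep) if k), cols, counts[keep], construction
    )


def build_joint_table(
    geno_a: Sequence,
    geno_b: Sequence,
    phenotypes: Optional[Sequence] = None,
) -> ContingencyTable:
    """Joint cross-classification of two variants' genotypes.

    Without phenotypes: genotype classes of A x genotype classes of B (a
    variant-variant dependence table).  With phenotypes: each observed joint
    (A, B) genotype combination forms a row, crossed with (case, control);
    empty combinations are dropped, which is what produces irregular degrees
    of freedom on sparse cohorts.
    """
    if phenotypes is None:
        pairs = []
        for ga, gb in zip(geno_a, geno_b, strict=True):
            ga, gb = _normalise_genotype(ga), _normalise_genotype(gb)
            if ga is not None and gb is not None:
                pairs.append((ga, gb))
        if not pairs:
            raise DegenerateTableError("no overlapping non-missing samples")
        a_classes = sorted({ga for ga, _ in pairs})
        b_classes = sorted({gb for _, gb in pairs})
        counts = np.zeros((len(a_classes), len(b_classes)), dtype=float)
        for ga, gb in pairs:
            counts[a_classes.index(ga), b_classes.index(gb)] += 1
        return ContingencyTable(
            tuple(_GENOTYPE_ORDER[a] for a in a_classes),
            tuple(_GENOTYPE_ORDER[b] for b in b_classes),
            counts,
            "joint2",
        )

    triples = []
    for ga, gb, ph in zip(geno_a, geno_b, phenotypes, strict=True):
        ga, gb = _normalise_genotype(ga), _normalise_genotype(gb)
        ph = _normalise_phenotype(ph)
        if ga is not None and gb is not None and ph is not None:
            triples.append((ga, gb, ph))
    if not triples:
        raise DegenerateTableError("no overlapping non-missing samples")
    combos = sorted({(ga, gb) for ga, gb, _ in triples})
    cols = ("case", "control")
    counts = np.zeros((len(combos), 2), dtype=float)
    for ga, gb, ph in triples:
        counts[combos.index((ga, gb)), cols.index(ph)] += 1
    labels = tuple(
        f"{_GENOTYPE_ORDER[ga]}/{_GENOTYPE_ORDER[gb]}" for ga, gb in combos
    )
    return ContingencyTable(labels, cols, counts, "joint3")


# ---------------------------------------------------------------------------
# Chi-square tests
# ---------------------------------------------------------------------------


def chi2_independence(table: ContingencyTable, yates: str = "auto") -> AssociationResult:
    """Pearson chi-square test of independence on an R x C table.

    With Yates' continuity correction (``yates="on"``, or ``"auto"`` on 2x2
    tables), each cell's deviation |O - E| is reduced by min(0.5, |O - E|),
    so a perfectly proportional table yields a statistic of exactly zero.
    """
    if yates not in ("auto", "on", "off"):
        raise ValueError(f"unknown yates policy {yates!r}")
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError(
            f"table is {counts.shape[0]}x{counts.shape[1]}; need at least 2x2"
        )
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    for labels, sums, kind in (
        (table.row_labels, row_sums, "row"),
        (table.col_labels, col_sums, "column"),
    ):
        for label, total in zip(labels, sums):
            if total == 0:
                raise DegenerateTableError(f"zero {kind} margin: {label!r}")
    expected = np.outer(row_sums, col_sums) / counts.sum()
    apply_yates = yates == "on" or (yates == "auto" and counts.shape == (2, 2))
    deviation = np.abs(counts - expected)
    if apply_yates:
        deviation = np.maximum(deviation - 0.5, 0.0)
    statistic = float((deviation**2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return AssociationResult(
        test="pearson_chi2_yates" if apply_yates else "pearson_chi2",
        statistic=statistic,
        df=df,
        p=float(stats.chi2.sf(statistic, df)),
        expected_warning=bool((expected < 5).any()),
        table=table,
    )


def chi2_gof(observed: Sequence, expected_probs: Sequence) -> AssociationResult:
    """Chi-square goodness-of-fit ("test for probabilities").

    ``statistic = sum((O_i - N p_i)^2 / (N p_i))`` with df = k - 1.
    """
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if observed.shape != probs.shape or observed.ndim != 1:
        raise ValueError("observed and expected_probs must be 1-D and equal-length")
    if observed.size < 2:
        raise DegenerateTableError("goodness-of-fit needs at least 2 categories")
    if (observed < 0).any():
        raise ValueError("observed counts must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError(f"expected probabilities sum to {probs.sum()}, not 1")
    if ((probs == 0) & (observed > 0)).any():
        raise ValueError("expected probability 0 with a positive observed count")
    n = observed.sum()
    expected = n * probs
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    statistic = float(terms.sum())
    df = observed.size - 1
    return AssociationResult(
        test="chi2_gof",
        statistic=statistic,
        df=df,
        p=float(stats.chi2.sf(statistic, df)),
        expected_warning=bool((expected < 5).any()),
        table=None,
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    variant: VariantKey
    verdict: str
    direct_test: Optional[AssociationResult]
    best_partner: Optional[VariantKey] = None
    interaction_test: Optional[AssociationResult] = None
    joint_disease_test: Optional[AssociationResult] = None
    alpha: float = 0.05
    direct_tests: dict = field(default_factory=dict)
    best_direct: Optional[AssociationResult] = None
    direct_p_bh: Optional[float] = None
    gene: Optional[str] = None


def _direct_battery(genotypes, phenotypes, yates) -> dict:
    """Genotype-level, carrier-level and per-stratum direct tests."""
    tests = {}
    try:
        tests["genotype"] = chi2_independence(
            build_table(genotypes, phenotypes, "genotype"), yates
        )
    except DegenerateTableError:
        pass
    try:
        tests["carrier"] = chi2_independence(
            build_table(genotypes, phenotypes, "carrier"), yates
        )
    except DegenerateTableError:
        pass
    observed = {
        _GENOTYPE_ORDER[g]
        for g in (_normalise_genotype(x) for x in genotypes)
        if g is not None
    }
    for cls in _GENOTYPE_ORDER:
        if cls not in observed:
            continue
        try:
            result = chi2_independence(
                build_table(genotypes, phenotypes, "stratum", focus_genotype=cls),
                yates,
            )
        except DegenerateTableError:
            continue
        tests[f"stratum:{cls}"] = result
    return tests


def classify_variants(
    genotypes: Mapping,
    phenotypes: Sequence,
    alpha: float = 0.05,
    partner_set: Optional[Sequence] = None,
    yates: str = "auto",
) -> list:
    """Classify each variant as putative mutation, effect modifier or neither.

    ``genotypes`` maps variant identifiers (``VariantKey`` or string) to
    dosage vectors over the cohort samples; ``phenotypes`` is the aligned
    case/control vector.  The decisive direct test is the genotype-level
    contingency test; a variant with direct p < alpha is a putative mutation
    (direct effects take precedence).  Otherwise every partner in
    ``partner_set`` (default: all other variants) is screened, and the
    variant is a putative effect modifier when, for some partner, both the
    genotype x genotype test and the joint-genotype x disease test have
    p < alpha; the best partner is the one with the smallest joint-test p.
    BH-adjusted direct p-values are reported alongside but do not drive
    verdicts.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    labels = [_normalise_phenotype(ph) for ph in phenotypes]
    present = {ph for ph in labels if ph is not None}
    if present != {"case", "control"}:
        raise CohortError("cohort must contain both cases and controls")
    keys = list(genotypes)
    partners = list(partner_set) if partner_set is not None else keys

    results = []
    for key in keys:
        vector = genotypes[key]
        direct_tests = _direct_battery(vector, phenotypes, yates)
        decisive = direct_tests.get("genotype")
        best_name = min(
            direct_tests, key=lambda name: (direct_tests[name].p, name), default=None
        )
        best_direct = direct_tests.get(best_name) if best_name else None

        verdict = "unclassified"
        best_partner = None
        interaction_test = None
        joint_disease_test = None
        if decisive is not None and decisive.p < alpha:
            verdict = "putative_mutation"
        else:
            candidates = []
            for partner in partners:
                if partner == key:
                    continue
                try:
                    pair_test = chi2_independence(
                        build_joint_table(vector, genotypes[partner]), yates
                    )
                    joint_test = chi2_independence(
                        build_joint_table(vector, genotypes[partner], phenotypes),
                        yates,
                    )
                except DegenerateTableError:
                    continue
                if pair_test.p < alpha and joint_test.p < alpha:
                    candidates.append((joint_test.p, str(partner), partner, pair_test, joint_test))
            if candidates:
                candidates.sort(key=lambda item: (item[0], item[1]))
                _, _, best_partner, interaction_test, joint_disease_test = candidates[0]
                verdict = "putative_effect_modifier"

        results.append(
            ClassificationResult(
                variant=key,
                verdict=verdict,
                direct_test=decisive,
                best_partner=best_partner,
                interaction_test=interaction_test,
                joint_disease_test=joint_disease_test,
                alpha=alpha,
                direct_tests=direct_tests,
                best_direct=best_direct,
            )
        )

    with_direct = [r for r in results if r.direct_test is not None]
    if with_direct:
        adjusted = bh_adjust([r.direct_test.p for r in with_direct])
        for result, p_bh in zip(with_direct, adjusted):
            result.direct_p_bh = float(p_bh)
    return results
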