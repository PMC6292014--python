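"""Differential-expression significance filtering and pathway over-representation.

The DE filter retains genes with BH q-value strictly below ``q_max`` (default
0.05) whose test status is OK.  Over-representation of the retained genes in
pathway gene sets is scored with the right-tailed Fisher / hypergeometric
test; significance is judged on the raw p (alpha = 0.05, i.e. -log10 p >=
1.301), with BH-adjusted pathway q-values reported alongside for
transparency.  The default enrichment universe is the set of genes that were
successfully tested (status OK) in the DE table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from scipy import stats

from .association import bh_adjust
from .io_core import DERecord, PathwaySet


def filter_de(
    records: Sequence[DERecord], q_max: float = 0.05, require_ok: bool = True
) -> dict:
    """Retain genes with q < q_max (strict), optionally requiring status OK.

    Returns a mapping gene -> DERecord so downstream stages can report the
    effect direction.
    """
    if not 0 < q_max < 1:
        raise ValueError(f"q_max must lie in (0, 1), got {q_max}")
    retained = {}
    for record in records:
        if record.q < q_max and (not require_ok or record.status == "OK"):
            retained[record.gene] = record
    return retained


class Log2Ratio(NamedTuple):
    value: float
    flag: str  # ok | case_only | control_only | undefined


def log2_ratio(fpkm_case: float, fpkm_control: float) -> Log2Ratio:
    """log2(case/control) expression ratio with zero-expression flags."""
    if fpkm_case < 0 or fpkm_control < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_case == 0 and fpkm_control == 0:
        return Log2Ratio(math.nan, "undefined")
    if fpkm_control == 0:
        return Log2Ratio(math.inf, "case_only")
    if fpkm_case == 0:
        return Log2Ratio(-math.inf, "control_only")
    return Log2Ratio(math.log2(fpkm_case / fpkm_control), "ok")


@dataclass
class EnrichmentResult:
    pathway: str
    overlap: int
    pathway_size: int
    query_size: int
    universe_size: int
    p: float
    neg_log10_p: float
    significant: bool
    q_bh: float = math.nan


def enrich_pathways(
    query_genes: Iterable[str],
    pathways: Sequence[PathwaySet],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list:
    """Right-tailed Fisher (hypergeometric) over-representation per pathway.

    ``p = P(X >= overlap)`` where X is hypergeometric with ``pathway_size``
    draws from a universe containing ``query_size`` successes.  Query genes
    outside the universe are dropped with a warning; pathway genes are
    intersected with the universe.  Results are sorted by ascending p, ties
    broken by pathway name.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("enrichment universe is empty")
    query = {g.upper() for g in query_genes}
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query &= universe

    n_universe = len(universe)
    n_query = len(query)
    results = []
    for pathway in pathways:
        members = pathway.genes & universe
        overlap = len(members & query)
        # P(X >= overlap): pathway_size draws, query_size successes.
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, n_query, len(members)))
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                pathway=pathway.name,
                overlap=overlap,
                pathway_size=len(members),
                query_size=n_query,
                universe_size=n_universe,
                p=p,
                neg_log10_p=-math.log10(p) if p > 0 else math.inf,
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway))
    if results:
        for result, q in zip(results, bh_adjust([r.p for r in results])):
            result.q_bh = float(q)
    return results
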