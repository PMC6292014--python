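"""Allele/carrier frequencies and two-locus linkage disequilibrium.

Haplotype frequencies are estimated from unphased genotypes with the standard
EM algorithm: only double heterozygotes are phase-ambiguous (coupling AB/ab
versus repulsion Ab/aB), and the E-step splits them by the current relative
likelihood of the two phases.  From the four haplotype frequencies
(AB, Ab, aB, ab — capital letters denote the alternate allele) the LD
coefficients are

    D  = f(AB) f(ab) - f(Ab) f(aB)
    D' = |D| / D_max
    r2 = D^2 / (p_A p_a q_B q_b)

with D_max = min(p_A q_b, p_a q_B) when D > 0 and min(p_A q_B, p_a q_b)
otherwise.  D' and r2 are undefined (None), not zero, when either locus is
monomorphic, so degenerate cohorts stay visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

# haplotype order: (AB, Ab, aB, ab); index 0 <-> alt at both loci
_HAP_LOCUS_A = np.array([1, 1, 0, 0])
_HAP_LOCUS_B = np.array([1, 0, 1, 0])


@dataclass
class LDResult:
    hap_freqs: Tuple[float, float, float, float]
    D: float
    D_prime: Optional[float]
    r2: Optional[float]
    n_iterations: int
    loglik: float
    n_samples: int
    loglik_trace: tuple = ()


def _clean_dosages(genotypes) -> np.ndarray:
    values = []
    for g in genotypes:
        if g is None:
            values.append(np.nan)
        else:
            values.append(float(g))
    arr = np.asarray(values, dtype=float)
    valid = arr[~np.isnan(arr)]
    if ((valid < 0) | (valid > 2) | (valid != np.round(valid))).any():
        raise ValueError("dosages must be 0, 1, 2 or missing")
    return arr


def allele_frequency(genotypes: Sequence) -> float:
    """Alternate-allele frequency: sum of dosages over 2 x non-missing count."""
    arr = _clean_dosages(genotypes)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise ValueError("all genotypes are missing")
    return float(valid.sum() / (2 * valid.size))


def carrier_frequency(n_carriers: int, n_total: int) -> float:
    """Carrier frequency n_carriers / n_total (reported to 6 decimals)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_carriers <= n_total:
        raise ValueError("n_carriers must lie in [0, n_total]")
    return n_carriers / n_total


def ld_stats(hap_freqs: Sequence) -> Tuple[float, Optional[float], Optional[float]]:
    """(D, D', r2) from haplotype frequencies (AB, Ab, aB, ab)."""
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or (f < -1e-12).any():
        raise ValueError("need four non-negative haplotype frequencies")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"haplotype frequencies sum to {f.sum()}, not 1")
    f_ab_cap, f_ab_lo, f_lo_cap, f_lo_lo = f  # AB, Ab, aB, ab
    p_a = f_ab_cap + f_ab_lo  # alt frequency, locus A
    q_b = f_ab_cap + f_lo_cap  # alt frequency, locus B
    d = float(f_ab_cap * f_lo_lo - f_ab_lo * f_lo_cap)
    eps = 1e-12
    if min(p_a, 1 - p_a) < eps or min(q_b, 1 - q_b) < eps:
        return d, None, None
    if d > 0:
        d_max = min(p_a * (1 - q_b), (1 - p_a) * q_b)
    else:
        d_max = min(p_a * q_b, (1 - p_a) * (1 - q_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * q_b * (1 - q_b))
    return d, float(min(d_prime, 1.0)), float(min(r2, 1.0))


def _genotype_prob(f: np.ndarray, ga: int, gb: int) -> float:
    """P(unphased genotype pair) under random union of haplotypes."""
    total = 0.0
    for h1 in range(4):
        for h2 in range(4):
            if (
                _HAP_LOCUS_A[h1] + _HAP_LOCUS_A[h2] == ga
                and _HAP_LOCUS_B[h1] + _HAP_LOCUS_B[h2] == gb
            ):
                total += f[h1] * f[h2]
    return total


def em_haplotype_freqs(
    geno_a: Sequence,
    geno_b: Sequence,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDResult:
    """EM haplotype-frequency estimation from two unphased dosage vectors.

    Starts from linkage equilibrium (products of the observed allele
    frequencies), which is deterministic and symmetric, and stops when the
    largest frequency change drops below ``tol`` or after ``max_iter``
    iterations.  The log-likelihood is non-decreasing across iterations.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    a = _clean_dosages(geno_a)
    b = _clean_dosages(geno_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask].astype(int), b[mask].astype(int)
    n = a.size
    if n < 2:
        raise ValueError("fewer than 2 informative samples")

    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)

    p_a = a.sum() / (2 * n)
    p_b = b.sum() / (2 * n)
    f = np.array(
        [
            p_a * p_b,
            p_a * (1 - p_b),
            (1 - p_a) * p_b,
            (1 - p_a) * (1 - p_b),
        ]
    )

    # fixed (phase-unambiguous) haplotype contributions per genotype cell
    fixed = np.zeros(4)
    contributions = {
        (2, 2): (2, 0, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 0): (0, 2, 0, 0),
        (1, 2): (1, 0, 1, 0),
        (1, 0): (0, 1, 0, 1),
        (0, 2): (0, 0, 2, 0),
        (0, 1): (0, 0, 1, 1),
        (0, 0): (0, 0, 0, 2),
    }
    for (ga, gb), weights in contributions.items():
        fixed += counts[ga, gb] * np.asarray(weights, dtype=float)
    n_double_het = counts[1, 1]

    def loglik(freqs: np.ndarray) -> float:
        total = 0.0
        for ga in range(3):
            for gb in range(3):
                if counts[ga, gb] == 0:
                    continue
                prob = _genotype_prob(freqs, ga, gb)
                total += counts[ga, gb] * math.log(max(prob, 1e-300))
        return total

    iterations = 0
    trace = [loglik(f)]
    for iterations in range(1, max_iter + 1):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        weight = 0.5 if coupling + repulsion == 0 else coupling / (coupling + repulsion)
        hap_counts = fixed + n_double_het * np.array(
            [weight, 1 - weight, 1 - weight, weight]
        )
        new_f = hap_counts / (2 * n)
        delta = float(np.abs(new_f - f).max())
        f = new_f
        trace.append(loglik(f))
        if delta < tol:
            break

    d, d_prime, r2 = ld_stats(f)
    return LDResult(
        hap_freqs=tuple(float(x) for x in f),
        D=d,
        D_prime=d_prime,
        r2=r2,
        n_iterations=iterations,
        loglik=trace[-1],
        n_samples=int(n),
        loglik_trace=tuple(trace),
    )
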