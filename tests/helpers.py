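"""Shared test utilities: pileup builders and independent brute-force oracles.

The oracles re-derive every quantity from first principles — explicit
enumeration over indicator vectors and dense-grid numerical integration —
and never call the production code paths they are used to check.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from cohortsnv.model import BASES, LikelihoodPair, ReadObservation, SamplePileup


def make_pileup(
    bases: Sequence[str],
    error_probs: float | Sequence[float] = 0.01,
    strands: Optional[Sequence[bool]] = None,
    sample_id: str = "s",
) -> SamplePileup:
    if isinstance(error_probs, float):
        error_probs = [error_probs] * len(bases)
    if strands is None:
        strands = [True] * len(bases)
    obs = tuple(
        ReadObservation(base=b, error_prob=q, forward_strand=st)
        for b, q, st in zip(bases, error_probs, strands)
    )
    return SamplePileup(sample_id=sample_id, observations=obs)


def random_pileup(
    rng: np.random.Generator, n_max: int = 200, sample_id: str = "s"
) -> SamplePileup:
    n = int(rng.integers(0, n_max + 1))
    bases = rng.choice(list(BASES), size=n)
    qs = 10.0 ** (-rng.uniform(0.5, 4.0, size=n))
    strands = rng.random(n) < 0.5
    return make_pileup(list(bases), list(map(float, qs)), list(map(bool, strands)),
                       sample_id)


# ---- independent likelihood pieces ----------------------------------------

def oracle_log_rho(pileup: SamplePileup, normal: str, tumor: str) -> float:
    d_n = sum(1 for o in pileup.observations if o.base == normal)
    d_t = sum(1 for o in pileup.observations if o.base == tumor)
    d_e = pileup.depth - d_n - d_t
    return (
        math.lgamma(pileup.depth + 1)
        - math.lgamma(d_n + 1) - math.lgamma(d_t + 1) - math.lgamma(d_e + 1)
    )


def oracle_log_z0(pileup: SamplePileup, normal: str, tumor: str) -> float:
    if pileup.depth == 0:
        return 0.0
    total = oracle_log_rho(pileup, normal, tumor)
    for o in pileup.observations:
        total += math.log(1 - o.error_prob) if o.base == normal \
            else math.log(o.error_prob / 3)
    return total


def grid_log_z1(
    pileup: SamplePileup,
    normal: str,
    tumor: str,
    epsilon: float = 0.05,
    n_points: int = 100_001,
) -> float:
    """Dense-grid (composite Simpson) integral of the VAF marginal, in log
    space so depths of hundreds of reads stay finite."""
    if pileup.depth == 0:
        return 0.0
    if n_points % 2 == 0:
        n_points += 1
    f = np.linspace(epsilon, 1.0, n_points)
    log_g = np.zeros(n_points)
    for o in pileup.observations:
        q = o.error_prob
        if o.base == tumor:
            log_g += np.log((1 - q) * f + (q / 3) * (1 - f))
        elif o.base == normal:
            log_g += np.log((1 - q) * (1 - f) + (q / 3) * f)
        else:
            log_g += math.log(q / 3)
    h = (1.0 - epsilon) / (n_points - 1)
    w = np.ones(n_points)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    log_integral = logsumexp(log_g + np.log(w * h / 3.0))
    return (
        oracle_log_rho(pileup, normal, tumor)
        + log_integral
        - math.log(1 - epsilon)
    )


# ---- enumeration oracles ---------------------------------------------------

def oracle_log_prior(z: Tuple[int, ...], mu: float) -> float:
    m = len(z)
    if sum(z) == 0:
        return math.log1p(-mu)
    if mu == 0.0:
        return -math.inf
    return math.log(mu) - math.log(2 ** m - 1)


def brute_marginal_log(pairs: Sequence[LikelihoodPair], mu: float) -> float:
    """Explicit sum over all 2^m indicator vectors."""
    terms = []
    for z in itertools.product([0, 1], repeat=len(pairs)):
        log_lik = sum(p.log_p1 if zi else p.log_p0 for p, zi in zip(pairs, z))
        lp = oracle_log_prior(z, mu)
        if lp > -math.inf:
            terms.append(lp + log_lik)
    return float(logsumexp(terms))


def _oracle_pairs(
    cohort: Sequence[SamplePileup],
    normal: str,
    tumor: str,
    epsilon: float,
    n_points: int,
) -> List[LikelihoodPair]:
    return [
        LikelihoodPair(
            log_p0=oracle_log_z0(p, normal, tumor),
            log_p1=grid_log_z1(p, normal, tumor, epsilon, n_points),
        )
        for p in cohort
    ]


def brute_somatic_posterior(
    cohort: Sequence[SamplePileup],
    normal: str,
    mu: float,
    epsilon: float = 0.05,
    n_points: int = 20_001,
) -> Tuple[float, Dict[str, float]]:
    """Full enumeration posterior: sum over T != N and all 2^m vectors."""
    log_num_terms, log_den_terms = [], []
    marginals: Dict[str, float] = {}
    for tumor in BASES:
        if tumor == normal:
            continue
        pairs = _oracle_pairs(cohort, normal, tumor, epsilon, n_points)
        log_num_terms.append(
            math.log1p(-mu) + sum(p.log_p0 for p in pairs)
        )
        marginals[tumor] = brute_marginal_log(pairs, mu)
        log_den_terms.append(marginals[tumor])
    posterior = 1.0 - math.exp(logsumexp(log_num_terms) - logsumexp(log_den_terms))
    return posterior, marginals


def brute_tin_score(
    normal_pileup: SamplePileup,
    cohort: Sequence[SamplePileup],
    normal: str,
    tumor: str,
    mu: float,
    epsilon: float = 0.05,
    n_points: int = 20_001,
) -> float:
    """TIN score by enumeration over all 2^(m+1) vectors (Z_0, z)."""
    pairs = _oracle_pairs([normal_pileup] + list(cohort), normal, tumor,
                          epsilon, n_points)
    num_terms, den_terms = [], []
    for z in itertools.product([0, 1], repeat=len(pairs)):
        log_lik = sum(p.log_p1 if zi else p.log_p0 for p, zi in zip(pairs, z))
        lp = oracle_log_prior(z, mu)
        if lp == -math.inf:
            continue
        den_terms.append(lp + log_lik)
        if z[0] == 1:
            num_terms.append(lp + log_lik)
    log_posterior = logsumexp(num_terms) - logsumexp(den_terms)
    return max(0.0, -10.0 * log_posterior / math.log(10.0))


def rel_err_from_logs(log_a: float, log_b: float) -> float:
    """|a/b - 1| computed without leaving log space."""
    return abs(math.expm1(log_a - log_b))


# ---- fixture writers -------------------------------------------------------

def write_vcf_text(path, rows, contigs=(("chr1", 100000), ("chr2", 100000))):
    """Minimal VCF v4.2 writer for candidate-set fixtures.

    rows: (chrom, pos, ref, alt, filter_field) tuples, filter_field a raw
    string such as 'PASS', 'LowEVS' or '.'.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={ln}>" for c, ln in contigs]
    lines += [
        '##FILTER=<ID=LowEVS,Description="synthetic low-quality flag">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for chrom, pos, ref, alt, filt in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
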