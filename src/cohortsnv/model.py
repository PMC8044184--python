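"""Bayesian model for joint somatic SNV calling across multiple samples.

A locus is evaluated independently.  The normal sample is assumed homozygous
for a single normal allele ``N``; at most one alternative (tumor) allele ``T``
is modeled.  For each of ``m`` tumor samples a latent binary indicator ``z_i``
says whether the sample carries the variant.  Conditional on ``z_i = 1`` the
variant allele frequency ``f_i`` has a uniform prior on ``[eps, 1]``;
conditional on ``z_i = 0`` the frequency is exactly zero.  Each error-free
base is ``T`` with probability ``f_i`` (else ``N``), and the observed base
differs from the error-free base with the read's sequencing-error probability
``q``, errors being unbiased over the three other nucleotides.

The somatic probability reported for a locus is

    P(Z != 0 | N, b, q) = 1 - P(Z = 0 | N, b, q),

with the prior over indicator vectors putting mass ``1 - mu`` on the all-zero
vector and spreading ``mu`` uniformly over the remaining ``2^m - 1`` vectors.
All computations are carried out in log space; the exponential sum over
indicator vectors collapses to a linear-time product form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

BASES: Tuple[str, str, str, str] = ("A", "C", "G", "T")

#: Sequencing-error probabilities are clamped into this range.  q = 0 is
#: numerically degenerate and q >= 0.75 carries no information (the emission
#: becomes uniform over the four bases).
ERROR_PROB_MIN = 1e-10
ERROR_PROB_MAX = 0.75


class InvalidBaseError(ValueError):
    """Raised when a base outside {A, C, G, T} reaches the model."""


def _check_base(b: str) -> str:
    if b not in BASES:
        raise InvalidBaseError(f"not a canonical nucleotide: {b!r}")
    return b


def phred_to_error_prob(phred: float) -> float:
    """Convert a Phred quality to an error probability, clamped to (0, 0.75]."""
    q = 10.0 ** (-phred / 10.0)
    return min(max(q, ERROR_PROB_MIN), ERROR_PROB_MAX)


@dataclass(frozen=True)
class ReadObservation:
    """One quality-filtered read base at a locus."""

    base: str
    error_prob: float
    forward_strand: bool = True
    mapping_quality: int = 60

    def __post_init__(self) -> None:
        _check_base(self.base)
        if not 0.0 < self.error_prob < 1.0:
            raise ValueError(f"error_prob must lie in (0, 1): {self.error_prob}")


@dataclass(frozen=True)
class SamplePileup:
    """All retained read observations of one sample at one locus.

    An empty pileup is legal and behaves as an all-normal sample.
    """

    sample_id: str
    observations: Tuple[ReadObservation, ...] = ()

    @property
    def depth(self) -> int:
        return len(self.observations)

    def bases(self) -> Tuple[str, ...]:
        return tuple(o.base for o in self.observations)


@dataclass(frozen=True)
class AlleleCounts:
    """Partition of a pileup's bases relative to a (normal, tumor) allele pair."""

    d_n: int
    d_t: int
    d_e: int
    fwd_t: int = 0
    rev_t: int = 0

    def __post_init__(self) -> None:
        if min(self.d_n, self.d_t, self.d_e) < 0:
            raise ValueError("allele counts must be nonnegative")
        if self.fwd_t + self.rev_t != self.d_t and (self.fwd_t or self.rev_t):
            raise ValueError("strand-split counts must sum to d_t")

    @property
    def depth(self) -> int:
        return self.d_n + self.d_t + self.d_e


@dataclass(frozen=True)
class LikelihoodPair:
    """Per-sample log likelihoods under z_i = 0 and z_i = 1 for a fixed T."""

    log_p0: float
    log_p1: float


@dataclass
class ModelParams:
    """Model and filtering parameters.

    mu
        Prior probability that a candidate locus carries a somatic SNV in at
        least one sample.  Candidate loci arrive pre-enriched by a permissive
        single-sample caller, so the default is deliberately small.
    epsilon
        Lower truncation of the uniform VAF prior given z_i = 1.
    call_threshold
        Posterior cutoff for emitting a call.
    tin_threshold
        Phred cutoff below which the tumor-in-normal filter fires.
    mapq_min, baseq_min
        Read-level quality filters applied when building pileups
        (strictly-below semantics: MAPQ < mapq_min is dropped).
    quad_order
        Minimum Gauss-Legendre order for the VAF integral; the effective
        order grows with pileup depth so the polynomial integrand is
        integrated exactly.
    """

    mu: float = 1e-3
    epsilon: float = 0.05
    call_threshold: float = 0.5
    tin_threshold: float = 20.0
    mapq_min: int = 30
    baseq_min: int = 13
    quad_order: int = 32

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"mu must lie in [0, 1): {self.mu}")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1): {self.epsilon}")


def base_emission(b: str, x: str, q: float) -> float:
    """P(observed base b | error-free base x, error probability q).

    Equals ``1 - q`` when ``b == x`` and ``q / 3`` otherwise: sequencing
    errors are assumed unbiased across the three alternative bases.
    """
    _check_base(b)
    _check_base(x)
    if not 0.0 < q < 1.0:
        raise ValueError(f"error probability must lie in (0, 1): {q}")
    return 1.0 - q if b == x else q / 3.0


def allele_counts(pileup: SamplePileup, normal: str, tumor: str) -> AlleleCounts:
    """Count bases of a pileup relative to the allele pair (N, T)."""
    d_n = d_t = d_e = fwd_t = rev_t = 0
    for obs in pileup.observations:
        if obs.base == normal:
            d_n += 1
        elif obs.base == tumor:
            d_t += 1
            if obs.forward_strand:
                fwd_t += 1
            else:
                rev_t += 1
        else:
            d_e += 1
    return AlleleCounts(d_n=d_n, d_t=d_t, d_e=d_e, fwd_t=fwd_t, rev_t=rev_t)


def log_multinomial_coeff(counts: AlleleCounts) -> float:
    """log of n! / (d_n! d_t! d_e!) via log-gamma."""
    n = counts.depth
    return float(
        gammaln(n + 1)
        - gammaln(counts.d_n + 1)
        - gammaln(counts.d_t + 1)
        - gammaln(counts.d_e + 1)
    )


def _linear_factors(
    pileup: SamplePileup, normal: str, tumor: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-read emission factors as linear functions of the VAF f.

    Each read contributes a factor ``a + s * f`` where ``a`` is the factor at
    f = 0 and ``a + s`` the factor at f = 1.  Bases outside {N, T} contribute
    the constant ``q / 3``.
    """
    n = pileup.depth
    a = np.empty(n)
    s = np.empty(n)
    for j, obs in enumerate(pileup.observations):
        q = obs.error_prob
        if obs.base == tumor:
            a[j] = q / 3.0
            s[j] = (1.0 - q) - q / 3.0
        elif obs.base == normal:
            a[j] = 1.0 - q
            s[j] = q / 3.0 - (1.0 - q)
        else:
            a[j] = q / 3.0
            s[j] = 0.0
    return a, s


def likelihood_given_f(
    pileup: SamplePileup, f: float, normal: str, tumor: str
) -> float:
    """Product over reads of the per-read emission at VAF f (without the
    multinomial coefficient)."""
    if normal == tumor:
        raise ValueError("normal and tumor allele must differ")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1]: {f}")
    a, s = _linear_factors(pileup, normal, tumor)
    return float(np.prod(a + s * f))


def log_likelihood_z0(pileup: SamplePileup, normal: str, tumor: str) -> float:
    """log P(b_i | z_i = 0, T, N, q_i): the VAF collapses to zero.

    The multinomial coefficient is computed with the counts partitioned
    relative to (N, T) so that exactly the same coefficient multiplies both
    members of the sample's likelihood pair; it does not cancel when
    marginalizing over candidate tumor alleles.
    """
    if normal == tumor:
        raise ValueError("normal and tumor allele must differ")
    if pileup.depth == 0:
        return 0.0
    total = log_multinomial_coeff(allele_counts(pileup, normal, tumor))
    for obs in pileup.observations:
        q = obs.error_prob
        total += math.log(1.0 - q) if obs.base == normal else math.log(q / 3.0)
    return total


def _gauss_legendre(order: int) -> Tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(order)


def log_likelihood_z1(
    pileup: SamplePileup,
    normal: str,
    tumor: str,
    epsilon: float = 0.05,
    quad_order: int = 32,
) -> float:
    """log P(b_i | z_i = 1, T, N, q_i) with f ~ Uniform[epsilon, 1].

    The integrand is a polynomial in f of degree n_i, so Gauss-Legendre
    quadrature of order ``max(quad_order, ceil((n_i + 1) / 2))`` integrates it
    exactly (up to round-off).  Evaluated in log space to stay finite at
    depths of many thousands of reads.
    """
    if normal == tumor:
        raise ValueError("normal and tumor allele must differ")
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1): {epsilon}")
    n = pileup.depth
    if n == 0:
        return 0.0
    order = max(quad_order, (n + 1 + 1) // 2)
    nodes, weights = _gauss_legendre(order)
    # map [-1, 1] -> [epsilon, 1]
    half = (1.0 - epsilon) / 2.0
    f = epsilon + half * (nodes + 1.0)
    a, s = _linear_factors(pileup, normal, tumor)
    # log integrand at each node: sum over reads of log(a_j + s_j * f_k)
    log_g = np.log(a[:, None] + s[:, None] * f[None, :]).sum(axis=0)
    log_integral = logsumexp(log_g + np.log(weights * half))
    log_rho = log_multinomial_coeff(allele_counts(pileup, normal, tumor))
    return float(log_rho + log_integral - math.log1p(-epsilon))


def likelihood_pair(
    pileup: SamplePileup, normal: str, tumor: str, params: ModelParams
) -> LikelihoodPair:
    """Both conditional log likelihoods of one sample for a fixed tumor allele."""
    return LikelihoodPair(
        log_p0=log_likelihood_z0(pileup, normal, tumor),
        log_p1=log_likelihood_z1(
            pileup, normal, tumor, params.epsilon, params.quad_order
        ),
    )


def _log_prior_nonzero(mu: float, m: int) -> float:
    """log of mu / (2^m - 1), stable for large m."""
    if mu == 0.0:
        return -math.inf
    return math.log(mu) - (m * math.log(2.0) + math.log1p(-(2.0 ** -m)))


def joint_marginal_over_z(pairs: Sequence[LikelihoodPair], mu: float) -> float:
    """log of sum over all 2^m indicator vectors z of P(b | z) P(z).

    Uses the closed-form collapse

        (1 - 2^m/(2^m - 1) mu) prod_i P0_i
            + mu/(2^m - 1) prod_i (P0_i + P1_i),

    valid because the prior is uniform over the nonzero vectors.  The first
    coefficient can be negative (large mu, small m); a signed log-sum-exp
    handles that, and the total is a genuine probability, hence positive.
    """
    m = len(pairs)
    if m == 0:
        raise ValueError("at least one sample is required")
    if not 0.0 <= mu < 1.0:
        raise ValueError(f"mu must lie in [0, 1): {mu}")
    log_prod_p0 = sum(p.log_p0 for p in pairs)
    if mu == 0.0:
        return log_prod_p0
    log_mu_frac = _log_prior_nonzero(mu, m)
    # coefficient of prod P0: 1 - mu - mu/(2^m - 1)
    c0 = 1.0 - mu - math.exp(log_mu_frac)
    log_prod_sum = sum(np.logaddexp(p.log_p0, p.log_p1) for p in pairs)
    terms = [log_mu_frac + log_prod_sum]
    signs = [1.0]
    if c0 != 0.0:
        terms.append(math.log(abs(c0)) + log_prod_p0)
        signs.append(math.copysign(1.0, c0))
    val, sign = logsumexp(terms, b=signs, return_sign=True)
    if sign <= 0:
        raise FloatingPointError("joint marginal collapsed to a non-positive value")
    return float(val)


def omit_all_normal_samples(
    cohort: Sequence[SamplePileup], normal: str
) -> Tuple[List[SamplePileup], List[str]]:
    """Drop samples whose pileup is empty or contains only the normal allele.

    The somatic posterior of such samples is uninformative yet their sheer
    number would otherwise dilute the posterior towards zero, so they are
    excluded before the joint computation.
    """
    retained: List[SamplePileup] = []
    omitted: List[str] = []
    for pileup in cohort:
        if any(obs.base != normal for obs in pileup.observations):
            retained.append(pileup)
        else:
            omitted.append(pileup.sample_id)
    return retained, omitted


@dataclass
class PosteriorResult:
    """Somatic posterior at a locus plus reusable per-allele marginals."""

    somatic_prob: float
    log_marginal_by_t: Dict[str, float]
    pairs_by_t: Dict[str, List[LikelihoodPair]] = field(default_factory=dict)


def somatic_posterior(
    cohort: Sequence[SamplePileup], normal: str, params: ModelParams
) -> PosteriorResult:
    """Posterior probability that at least one sample carries a somatic SNV.

    Computed as ``1 - P(Z = 0 | N, b, q)`` where both numerator and
    denominator marginalize over the three candidate tumor alleles T != N.
    The per-T log marginals (the denominator terms) are returned for reuse by
    tumor-allele estimation and the per-sample machinery.
    """
    _check_base(normal)
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one informative sample")
    mu = params.mu
    log_num_terms: List[float] = []
    log_den_terms: List[float] = []
    log_marginal_by_t: Dict[str, float] = {}
    pairs_by_t: Dict[str, List[LikelihoodPair]] = {}
    log_one_minus_mu = math.log1p(-mu)
    for tumor in BASES:
        if tumor == normal:
            continue
        pairs = [likelihood_pair(p, normal, tumor, params) for p in cohort]
        pairs_by_t[tumor] = pairs
        log_p0_prod = sum(p.log_p0 for p in pairs)
        log_num_terms.append(log_one_minus_mu + log_p0_prod)
        log_marg = joint_marginal_over_z(pairs, mu)
        log_marginal_by_t[tumor] = log_marg
        log_den_terms.append(log_marg)
    log_p_z0 = logsumexp(log_num_terms) - logsumexp(log_den_terms)
    prob = -math.expm1(min(log_p_z0, 0.0))
    return PosteriorResult(
        somatic_prob=min(max(prob, 0.0), 1.0),
        log_marginal_by_t=log_marginal_by_t,
        pairs_by_t=pairs_by_t,
    )


def estimate_tumor_allele(
    per_t_log_marginals: Dict[str, float], normal: str
) -> str:
    """Maximum-likelihood tumor allele: argmax over T of the z-marginal.

    Ties break lexicographically (A < C < G < T) for determinism.
    """
    expected = {b for b in BASES if b != normal}
    if set(per_t_log_marginals) != expected:
        raise ValueError(
            f"marginals must cover exactly the three alleles != {normal}"
        )
    return max(sorted(per_t_log_marginals), key=lambda t: (per_t_log_marginals[t], ))


def tin_posterior(
    normal_pileup: SamplePileup,
    cohort: Sequence[SamplePileup],
    normal: str,
    tumor: str,
    params: ModelParams,
) -> float:
    """Tumor-in-normal (TIN) score: -10 log10 P(Z_0 = 1 | b_0, b, T, N, q).

    ``Z_0`` indicates that the *normal* sample itself carries the tumor
    allele, which signals contamination or a mis-identified normal allele.
    The indicator prior is the same uniform-over-nonzero-vectors prior,
    extended to the (m + 1)-length vector (Z_0, z).  Every vector with
    Z_0 = 1 is nonzero, so the numerator keeps the linear-time product form.
    Higher scores mean cleaner normals; scores below the threshold (default
    20, i.e. posterior above 0.01) flag the call.
    """
    pair0 = likelihood_pair(normal_pileup, normal, tumor, params)
    pairs = [likelihood_pair(p, normal, tumor, params) for p in cohort]
    m_total = len(pairs) + 1
    mu = params.mu
    log_num = (
        _log_prior_nonzero(mu, m_total)
        + pair0.log_p1
        + sum(np.logaddexp(p.log_p0, p.log_p1) for p in pairs)
    )
    log_den = joint_marginal_over_z([pair0] + pairs, mu)
    log_posterior = min(log_num - log_den, 0.0)
    score = -10.0 * log_posterior / math.log(10.0)
    return max(score, 0.0)


def per_sample_support(
    cohort: Sequence[SamplePileup],
    normal: str,
    tumor: str,
    params: ModelParams,
) -> List[int]:
    """Binary support vector over all m samples for a called variant.

    A sample supports the call iff it has at least one quality-filtered read
    carrying T and its per-sample posterior P(z_i = 1 | b_i) under an
    indifferent prior (mu' = 0.5) exceeds 0.5, i.e. P1 > P0.  All-normal
    samples never support.
    """
    support: List[int] = []
    for pileup in cohort:
        has_t = any(obs.base == tumor for obs in pileup.observations)
        if not has_t:
            support.append(0)
            continue
        pair = likelihood_pair(pileup, normal, tumor, params)
        support.append(1 if pair.log_p1 > pair.log_p0 else 0)
    return support
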