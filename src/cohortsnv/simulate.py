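"""Synthetic multi-sample cohorts for end-to-end testing and benchmarking.

The generator emulates bulk DNA sequencing of a tumor whose clones form a
linear phylogeny: clone ``k`` carries every mutation introduced along the
path from the root (normal) clone, so a mutation introduced at clone ``k``
has heterozygous VAF ``0.5 * sum_{j >= k} prevalence[sample, j]`` in each
bulk sample.  Reads are drawn per locus: Poisson depth, a discrete Phred
quality distribution, Bernoulli(VAF) error-free bases, and unbiased
single-base sequencing errors.  Alongside true SNV loci the generator
plants non-variant loci whose error reads (plus an explicit false-positive
rate) feed a permissive pseudo-caller, so the downstream joint caller sees a
realistic mixture of true and spurious candidates.

The pseudo-caller is a deliberately simple stand-in for a real single-sample
SNV caller: it nominates a locus in a sample when at least two non-reference
reads are present, and marks it accepted (PASS) under a stricter rule
(>= 4 alternative reads and alternative fraction >= 0.1).  Its thresholds
are plumbing for exercising the pipeline, not claims about any real caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .model import BASES, ReadObservation, SamplePileup

DEFAULT_CHROM = "sim1"
LOCUS_SPACING = 200
LOCUS_OFFSET = 100

#: Per-sample prevalence of (normal clone, tumor clones 1..4).  Rows sum to
#: one.  Chosen so every clone's mutations reach VAF >= 0.05 in at least two
#: samples, with the terminal clone's mutations staying at VAF <= 0.1
#: everywhere — the low-frequency stratum a joint caller is supposed to
#: rescue.
DEFAULT_MIXTURE: Tuple[Tuple[float, ...], ...] = (
    (0.2, 0.4, 0.3, 0.1, 0.0),
    (0.1, 0.1, 0.5, 0.2, 0.1),
    (0.3, 0.0, 0.1, 0.5, 0.1),
    (0.1, 0.2, 0.2, 0.3, 0.2),
    (0.4, 0.3, 0.1, 0.1, 0.1),
)

#: Phred-quality offsets relative to the requested mean error rate and their
#: probabilities; the induced mean error probability stays within 2% of the
#: requested rate.
QUAL_OFFSETS = (-5, 0, 5)
QUAL_PROBS = (0.15, 0.35, 0.5)


@dataclass
class CloneCohortSpec:
    """Parameters of a simulated cohort.

    ``mixture`` rows are per-tumor-sample prevalences over (normal clone,
    tumor clone 1, ..., tumor clone K); each row must sum to one.
    """

    n_true_snvs: int = 500
    n_null_loci: int = 500
    mixture: Tuple[Tuple[float, ...], ...] = DEFAULT_MIXTURE
    depth_mean: float = 60.0
    error_rate: float = 0.01
    fp_rate: float = 0.1
    seed: int = 0
    chrom: str = DEFAULT_CHROM

    def __post_init__(self) -> None:
        for row in self.mixture:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"mixture row does not sum to 1: {row}")
            if any(p < 0 for p in row):
                raise ValueError(f"negative prevalence in mixture row: {row}")
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError(f"fp_rate must lie in [0, 1]: {self.fp_rate}")

    @property
    def n_samples(self) -> int:
        return len(self.mixture)

    @property
    def n_clones(self) -> int:
        return len(self.mixture[0]) - 1

    @property
    def n_loci(self) -> int:
        return self.n_true_snvs + self.n_null_loci


@dataclass
class LocusTruth:
    chrom: str
    pos: int  # 1-based
    normal_allele: str
    tumor_allele: Optional[str]  # None at non-variant loci
    is_snv: bool
    clone: Optional[int]
    vafs: Tuple[float, ...]  # per tumor sample

    @property
    def max_vaf(self) -> float:
        return max(self.vafs) if self.vafs else 0.0


@dataclass
class SimulatedCohort:
    """Truth table plus in-memory pileups for every sample and locus."""

    spec: CloneCohortSpec
    truth: List[LocusTruth]
    sample_ids: List[str]
    normal_id: str
    # pileups[sample_id][pos] -> SamplePileup (includes the normal sample)
    pileups: Dict[str, Dict[int, SamplePileup]]
    reference: str = ""

    @property
    def contig_length(self) -> int:
        return LOCUS_OFFSET + LOCUS_SPACING * (self.spec.n_loci + 1)

    def true_loci(self) -> List[LocusTruth]:
        return [t for t in self.truth if t.is_snv]

    # ---- file emission ---------------------------------------------------

    def write_reference(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f">{self.spec.chrom}\n")
            for i in range(0, len(self.reference), 70):
                fh.write(self.reference[i:i + 70] + "\n")
        return path

    def _sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": self.spec.chrom, "LN": self.contig_length}],
            }
        )

    def write_alignments(self, outdir: str | Path) -> Dict[str, Path]:
        """One coordinate-sorted SAM per sample with single-base reads.

        Each pileup observation becomes a minimal 1M-CIGAR read carrying the
        observed base, its Phred quality, MAPQ 60, and the strand flag —
        enough to exercise the pileup layer bit-exactly without fragment
        realism.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        header = self._sam_header()
        for sample_id in [self.normal_id] + self.sample_ids:
            path = outdir / f"{sample_id}.sam"
            with pysam.AlignmentFile(str(path), "w", header=header) as out:
                for pos in sorted(self.pileups[sample_id]):
                    pileup = self.pileups[sample_id][pos]
                    for j, obs in enumerate(pileup.observations):
                        read = pysam.AlignedSegment(header)
                        read.query_name = f"{sample_id}.{pos}.{j}"
                        read.flag = 0 if obs.forward_strand else 16
                        read.reference_id = 0
                        read.reference_start = pos - 1
                        read.mapping_quality = obs.mapping_quality
                        read.cigartuples = [(0, 1)]
                        read.query_sequence = obs.base
                        phred = round(-10.0 * math.log10(obs.error_prob))
                        read.query_qualities = [phred]
                        out.write(read)
            paths[sample_id] = path
        return paths

    def write_truth(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            vaf_cols = "\t".join(f"vaf_{s}" for s in self.sample_ids)
            fh.write(f"chrom\tpos\tnormal\ttumor\tis_snv\tclone\t{vaf_cols}\n")
            for t in self.truth:
                vafs = "\t".join(f"{v:.6g}" for v in t.vafs)
                fh.write(
                    f"{t.chrom}\t{t.pos}\t{t.normal_allele}\t"
                    f"{t.tumor_allele or '.'}\t{int(t.is_snv)}\t"
                    f"{'.' if t.clone is None else t.clone}\t{vafs}\n"
                )
        return path

    def write_candidate_vcfs(self, outdir: str | Path) -> Dict[str, Path]:
        nominations = emulate_permissive_caller(self)
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        for sample_id in self.sample_ids:
            path = outdir / f"{sample_id}.candidates.vcf"
            header = pysam.VariantHeader()
            header.contigs.add(self.spec.chrom, length=self.contig_length)
            header.filters.add("LowSupport", None, None,
                               "Nominated permissively, below acceptance bar")
            with pysam.VariantFile(str(path), "w", header=header) as out:
                for pos, ref, alt, accepted in nominations[sample_id]:
                    rec = out.new_record(
                        contig=self.spec.chrom,
                        start=pos - 1,
                        alleles=(ref, alt),
                    )
                    rec.filter.add("PASS" if accepted else "LowSupport")
                    out.write(rec)
            paths[sample_id] = path
        return paths

    def write_all(self, outdir: str | Path) -> Dict[str, object]:
        """Write reference, alignments, candidate VCFs, and the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        return {
            "reference": self.write_reference(outdir / "reference.fa"),
            "alignments": self.write_alignments(outdir / "alignments"),
            "candidates": self.write_candidate_vcfs(outdir / "candidates"),
            "truth": self.write_truth(outdir / "truth.tsv"),
        }


def _clone_vaf_matrix(spec: CloneCohortSpec) -> np.ndarray:
    """(n_clones, n_samples) VAF of a mutation introduced at each clone."""
    mix = np.asarray(spec.mixture)  # (m, 1 + K)
    vafs = np.empty((spec.n_clones, spec.n_samples))
    for k in range(1, spec.n_clones + 1):
        vafs[k - 1] = 0.5 * mix[:, k:].sum(axis=1)
    return vafs


def _quality_table(error_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    base_q = round(-10.0 * math.log10(error_rate))
    phreds = np.array([max(base_q + off, 2) for off in QUAL_OFFSETS])
    return phreds, 10.0 ** (-phreds / 10.0)


def _simulate_pileup(
    rng: np.random.Generator,
    sample_id: str,
    vaf: float,
    depth_mean: float,
    normal: str,
    tumor: Optional[str],
    phreds: np.ndarray,
    error_probs: np.ndarray,
) -> SamplePileup:
    depth = int(rng.poisson(depth_mean))
    if depth == 0:
        return SamplePileup(sample_id=sample_id, observations=())
    qual_idx = rng.choice(len(phreds), size=depth, p=QUAL_PROBS)
    is_tumor_base = rng.random(depth) < vaf if tumor is not None else np.zeros(depth, bool)
    has_error = rng.random(depth) < error_probs[qual_idx]
    error_pick = rng.integers(0, 3, size=depth)
    forward = rng.random(depth) < 0.5
    obs = []
    for j in range(depth):
        true_base = tumor if is_tumor_base[j] else normal
        if has_error[j]:
            others = [b for b in BASES if b != true_base]
            base = others[error_pick[j]]
        else:
            base = true_base
        obs.append(
            ReadObservation(
                base=base,
                error_prob=float(error_probs[qual_idx[j]]),
                forward_strand=bool(forward[j]),
                mapping_quality=60,
            )
        )
    return SamplePileup(sample_id=sample_id, observations=tuple(obs))


def simulate_cohort(spec: CloneCohortSpec) -> SimulatedCohort:
    """Generate the truth table and per-sample pileups of a cohort.

    Fully deterministic given ``spec.seed``.  The matched normal sample has
    VAF zero at every locus; tumor-sample VAFs follow the clone mixture.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"tumor{i + 1}" for i in range(spec.n_samples)]
    normal_id = "normal"
    clone_vafs = _clone_vaf_matrix(spec)
    phreds, error_probs = _quality_table(spec.error_rate)

    n_loci = spec.n_loci
    positions = [LOCUS_OFFSET + LOCUS_SPACING * i for i in range(n_loci)]
    is_snv = np.zeros(n_loci, dtype=bool)
    is_snv[rng.choice(n_loci, size=spec.n_true_snvs, replace=False)] = True
    base_idx = rng.integers(0, 4, size=n_loci)
    alt_shift = rng.integers(1, 4, size=n_loci)
    clones = rng.integers(1, spec.n_clones + 1, size=n_loci)

    truth: List[LocusTruth] = []
    pileups: Dict[str, Dict[int, SamplePileup]] = {
        s: {} for s in [normal_id] + sample_ids
    }
    # Background reference with the normal allele planted at each locus.
    ref_chars = list(rng.choice(list(BASES), size=LOCUS_OFFSET + LOCUS_SPACING * (n_loci + 1)))
    for i, pos in enumerate(positions):
        normal_allele = BASES[base_idx[i]]
        ref_chars[pos - 1] = normal_allele
        if is_snv[i]:
            tumor_allele: Optional[str] = BASES[(base_idx[i] + alt_shift[i]) % 4]
            clone = int(clones[i])
            vafs = tuple(float(v) for v in clone_vafs[clone - 1])
        else:
            tumor_allele, clone = None, None
            vafs = tuple(0.0 for _ in sample_ids)
        truth.append(
            LocusTruth(
                chrom=spec.chrom, pos=pos, normal_allele=normal_allele,
                tumor_allele=tumor_allele, is_snv=bool(is_snv[i]),
                clone=clone, vafs=vafs,
            )
        )
        pileups[normal_id][pos] = _simulate_pileup(
            rng, normal_id, 0.0, spec.depth_mean, normal_allele, tumor_allele,
            phreds, error_probs,
        )
        for s, sample_id in enumerate(sample_ids):
            pileups[sample_id][pos] = _simulate_pileup(
                rng, sample_id, vafs[s], spec.depth_mean, normal_allele,
                tumor_allele, phreds, error_probs,
            )
    return SimulatedCohort(
        spec=spec,
        truth=truth,
        sample_ids=sample_ids,
        normal_id=normal_id,
        pileups=pileups,
        reference="".join(ref_chars),
    )


def emulate_permissive_caller(
    cohort: SimulatedCohort,
) -> Dict[str, List[Tuple[int, str, str, bool]]]:
    """Per-sample candidate nominations: (pos, REF, ALT, accepted).

    A sample nominates a locus when it holds >= 2 non-reference reads; the
    ALT is the most frequent non-reference base (ties broken A < C < G < T).
    The stricter acceptance rule (>= 4 ALT reads and ALT fraction >= 0.1)
    stands in for the original caller's default filters.  Additionally each
    non-variant locus is nominated with probability ``fp_rate`` per sample,
    emulating caller-specific false candidates beyond raw pileup errors.
    """
    spec = cohort.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out: Dict[str, List[Tuple[int, str, str, bool]]] = {}
    for sample_id in cohort.sample_ids:
        rows: List[Tuple[int, str, str, bool]] = []
        for t in cohort.truth:
            pileup = cohort.pileups[sample_id][t.pos]
            non_ref = [b for b in pileup.bases() if b != t.normal_allele]
            forced_fp = (not t.is_snv) and rng.random() < spec.fp_rate
            if len(non_ref) < 2 and not forced_fp:
                continue
            if non_ref:
                alt = max(sorted(set(non_ref)), key=non_ref.count)
            else:
                alt = next(b for b in BASES if b != t.normal_allele)
            alt_count = non_ref.count(alt)
            depth = pileup.depth
            accepted = alt_count >= 4 and depth > 0 and alt_count / depth >= 0.1
            rows.append((t.pos, t.normal_allele, alt, accepted))
        out[sample_id] = rows
    return out


def pass_union_positions(cohort: SimulatedCohort) -> set:
    """Positions accepted (PASS) by the pseudo-caller in at least one sample.

    This is the union call set a user of single-sample callers would obtain
    without joint re-calling; the benchmark's baseline.
    """
    union = set()
    for rows in emulate_permissive_caller(cohort).values():
        union.update(pos for pos, _, _, accepted in rows if accepted)
    return union


@dataclass
class PRPoint:
    threshold: float
    precision: float
    recall: float
    f1: float


def pr_curve(
    scored_calls: Sequence[Tuple[float, bool]], n_truth: int
) -> List[PRPoint]:
    """Precision-recall sweep over the observed score thresholds.

    ``scored_calls`` pairs each call's score with whether it matches a true
    variant; ``n_truth`` is the total number of true variants (missed ones
    count as false negatives at every threshold).  Thresholds descend, so
    recall is non-decreasing along the returned curve.
    """
    if not scored_calls:
        return []
    if n_truth <= 0:
        raise ValueError("n_truth must be positive")
    points: List[PRPoint] = []
    for threshold in sorted({s for s, _ in scored_calls}, reverse=True):
        tp = sum(1 for s, ok in scored_calls if s >= threshold and ok)
        fp = sum(1 for s, ok in scored_calls if s >= threshold and not ok)
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / n_truth
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        points.append(PRPoint(threshold, precision, recall, f1))
    return points
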