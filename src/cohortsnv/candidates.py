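"""Candidate locus extraction from permissive per-sample VCF call sets.

The joint caller does not discover variants from raw reads: it re-evaluates
the union of positions nominated by a single-sample SNV caller run under
permissive settings on each tumor/normal pair.  Records that fail the
original caller's filters are deliberately *included* — that permissiveness
is what gives the joint model low-frequency candidates to rescue.  Whether a
record additionally passed the caller's default filters is remembered
per sample: it drives the defer-to-single-caller rule and the novel-only
filter policy downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Set, Tuple

import pysam

from .model import BASES

logger = logging.getLogger(__name__)


@dataclass
class CandidateLocus:
    """A genomic position nominated for joint re-evaluation.

    ``normal_allele`` is the single-base REF of the nominating records and is
    taken as the homozygous allele of the matched normal.  ALT alleles seen
    in the input VCFs are recorded for reporting only; the joint model
    re-estimates the tumor allele itself.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    normal_allele: str
    source_samples: Set[str] = field(default_factory=set)
    originally_called_in: Set[str] = field(default_factory=set)
    seen_alts: Set[str] = field(default_factory=set)

    @property
    def pos0(self) -> int:
        """0-based position for the pileup layer."""
        return self.pos - 1


@dataclass
class CandidateSet:
    """Ordered candidate loci plus extraction bookkeeping counters."""

    loci: List[CandidateLocus]
    n_records: int = 0
    n_skipped_non_snv: int = 0
    n_ref_conflicts: int = 0

    def __iter__(self) -> Iterator[CandidateLocus]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)


def _is_accepted(record: "pysam.VariantRecord") -> bool:
    """True if the record passed the original caller's filters.

    A missing FILTER entry ('.') counts as accepted, matching the common
    convention of minimal caller output.
    """
    keys = list(record.filter.keys())
    return len(keys) == 0 or keys == ["PASS"]


def _snv_alts(record: "pysam.VariantRecord") -> List[str]:
    """Single-base canonical ALT alleles of a record (may be empty)."""
    alts = record.alts or ()
    return [a for a in alts if isinstance(a, str) and len(a) == 1 and a in BASES]


def extract_candidates(
    vcf_inputs: Sequence[Tuple[str, str]]
) -> CandidateSet:
    """Union the SNV positions of per-sample VCFs into ordered candidates.

    Parameters
    ----------
    vcf_inputs
        Pairs of (sample id, VCF path), one per tumor sample.  Plain or
        bgzip-compressed VCF v4.x.

    Returns
    -------
    CandidateSet
        One locus per distinct (chrom, pos), sorted by chromosome in the
        order the input headers declare contigs (first appearance wins) and
        by position within a chromosome.  Records whose REF is not a single
        canonical base, or with no single-base ALT, are skipped and counted.
        Positions where two inputs disagree on REF are dropped entirely with
        a warning: a wrong normal allele would corrupt the model at that
        locus.
    """
    chrom_rank: Dict[str, int] = {}
    by_key: Dict[Tuple[str, int], CandidateLocus] = {}
    conflicted: Set[Tuple[str, int]] = set()
    n_records = 0
    n_skipped = 0

    def _rank(chrom: str) -> None:
        if chrom not in chrom_rank:
            chrom_rank[chrom] = len(chrom_rank)

    for sample_id, path in vcf_inputs:
        with pysam.VariantFile(str(path)) as vcf:
            for contig in vcf.header.contigs:
                _rank(contig)
            for record in vcf:
                n_records += 1
                ref = record.ref
                alts = _snv_alts(record)
                if ref is None or len(ref) != 1 or ref not in BASES or not alts:
                    n_skipped += 1
                    continue
                _rank(record.chrom)
                key = (record.chrom, record.pos)
                if key in conflicted:
                    continue
                locus = by_key.get(key)
                if locus is None:
                    locus = CandidateLocus(
                        chrom=record.chrom, pos=record.pos, normal_allele=ref
                    )
                    by_key[key] = locus
                elif locus.normal_allele != ref:
                    logger.warning(
                        "REF conflict at %s:%d (%s vs %s from %s); locus skipped",
                        record.chrom, record.pos,
                        locus.normal_allele, ref, sample_id,
                    )
                    del by_key[key]
                    conflicted.add(key)
                    continue
                locus.source_samples.add(sample_id)
                locus.seen_alts.update(alts)
                if _is_accepted(record):
                    locus.originally_called_in.add(sample_id)

    loci = sorted(
        by_key.values(), key=lambda l: (chrom_rank[l.chrom], l.pos)
    )
    return CandidateSet(
        loci=loci,
        n_records=n_records,
        n_skipped_non_snv=n_skipped,
        n_ref_conflicts=len(conflicted),
    )


def originally_called(locus: CandidateLocus, sample_id: str) -> bool:
    """True iff this sample's original caller accepted the record here."""
    return sample_id in locus.originally_called_in
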