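"""Post-call empirical filters and the tumor-in-normal (TIN) filter.

These flags target recurrent artifact modes rather than the likelihood
model: thin normal coverage (germline status unknowable), globally weak
tumor support, one-strand-only support (oxidation/FFPE-style damage), runs
of clustered calls (undetected duplicates), and tumor allele visibly present
in the normal (contamination or mis-called normal allele).  By default the
flags *remove* only calls that no single-sample caller had accepted
("novel" calls) and merely annotate the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

from .candidates import CandidateLocus

FLAG_LOW_NORMAL_DEPTH = "low-normal-depth"
FLAG_LOW_TUMOR_SUPPORT = "low-tumor-support"
FLAG_EMPTY_STRAND = "empty-strand"
FLAG_CLUSTER = "cluster"
FLAG_TIN = "TIN"

ALL_FLAGS = (
    FLAG_LOW_NORMAL_DEPTH,
    FLAG_LOW_TUMOR_SUPPORT,
    FLAG_EMPTY_STRAND,
    FLAG_CLUSTER,
    FLAG_TIN,
)


@dataclass
class CallRecord:
    """The joint call at one candidate locus."""

    locus: CandidateLocus
    tumor_allele: str
    somatic_prob: float
    support: List[int]
    tin_score: float
    normal_depth: int
    tcount: List[int]
    strand_counts: List[Tuple[int, int]]  # per-sample (fwd_t, rev_t)
    depths: List[int] = field(default_factory=list)
    novel: bool = True
    filter_flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.somatic_prob <= 1.0:
            raise ValueError(f"somatic_prob out of [0, 1]: {self.somatic_prob}")
        if self.tin_score < 0.0:
            raise ValueError(f"tin_score must be >= 0: {self.tin_score}")


def apply_empirical_filters(record: CallRecord) -> CallRecord:
    """Annotate the depth/support/strand flags (idempotent, in place).

    low-normal-depth: normal pileup depth below 6.
    low-tumor-support: tumor-allele count below 4 in *every* sample.
    empty-strand: no sample has forward-strand tumor reads, or no sample has
    reverse-strand tumor reads.
    """
    if record.normal_depth < 6:
        record.filter_flags.add(FLAG_LOW_NORMAL_DEPTH)
    if record.tcount and all(c < 4 for c in record.tcount):
        record.filter_flags.add(FLAG_LOW_TUMOR_SUPPORT)
    if record.strand_counts:
        fwd_all_empty = all(f == 0 for f, _ in record.strand_counts)
        rev_all_empty = all(r == 0 for _, r in record.strand_counts)
        if fwd_all_empty or rev_all_empty:
            record.filter_flags.add(FLAG_EMPTY_STRAND)
    return record


def cluster_filter(records: Sequence[CallRecord]) -> Sequence[CallRecord]:
    """Flag clustered calls: >= 3 call sites spanning <= 100 bp.

    A record is flagged iff some same-chromosome window containing it holds
    at least three called sites with max(pos) - min(pos) <= 100 (inclusive
    span).  Input must be sorted by (chrom, pos); flags are added in place.
    """
    i = 0
    n = len(records)
    while i < n:
        chrom = records[i].locus.chrom
        j = i
        while j < n and records[j].locus.chrom == chrom:
            j += 1
        block = records[i:j]
        positions = [r.locus.pos for r in block]
        if positions != sorted(positions):
            raise ValueError("records must be sorted by (chrom, pos)")
        hi = 0
        for lo in range(len(block)):
            if hi < lo:
                hi = lo
            while hi + 1 < len(block) and positions[hi + 1] - positions[lo] <= 100:
                hi += 1
            if hi - lo >= 2:
                for r in block[lo:hi + 1]:
                    r.filter_flags.add(FLAG_CLUSTER)
        i = j
    return records


def tin_filter(record: CallRecord, threshold: float = 20.0) -> CallRecord:
    """Flag the call iff its TIN score is strictly below the Phred threshold."""
    if record.tin_score < threshold:
        record.filter_flags.add(FLAG_TIN)
    return record


def defer_single_sample(
    record: CallRecord | None,
    support_with_t_reads: int,
    originally_called_any: bool,
) -> bool:
    """Keep/drop decision for the defer-to-single-caller rule.

    When exactly one tumor sample contains variant-allele reads, the joint
    model adds nothing over the original caller, so the call stands only if
    some original caller accepted it.  Returns True to keep.
    """
    if support_with_t_reads == 1 and not originally_called_any:
        return False
    return True


def should_remove(record: CallRecord, mode: str = "novel") -> bool:
    """Whether a flagged record is dropped from the output.

    mode 'novel' (default): drop flagged records only when no original
    caller accepted the locus; previously accepted calls are annotated but
    kept.  mode 'all': drop any flagged record.  mode 'off': annotate only.
    """
    if mode not in ("novel", "all", "off"):
        raise ValueError(f"unknown filter mode: {mode}")
    if not record.filter_flags or mode == "off":
        return False
    if mode == "all":
        return True
    return record.novel
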