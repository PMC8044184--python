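"""Pileup construction from SAM/BAM at candidate loci.

Reads with mapping quality below ``mapq_min`` (default 30) and bases with
quality below ``baseq_min`` (default 13) are removed before any likelihood is
computed; duplicate-flagged and secondary/supplementary alignments are
dropped by default.  When a realigned alignment file accompanies the
original one (as produced by assembly-based callers), realigned reads
replace the originals with the same (query name, mate) key.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pysam

from .candidates import CandidateLocus
from .model import BASES, ModelParams, ReadObservation, SamplePileup, phred_to_error_prob

logger = logging.getLogger(__name__)

ReadKey = Tuple[str, bool]  # (query name, is first-of-pair)


def _read_key(read: pysam.AlignedSegment) -> ReadKey:
    # Unpaired reads report is_read1 False; the name alone then keys them.
    return (read.query_name or "", bool(read.is_paired and read.is_read1))


def _keyed(reads: Iterable[pysam.AlignedSegment], label: str) -> Dict[ReadKey, pysam.AlignedSegment]:
    out: Dict[ReadKey, pysam.AlignedSegment] = {}
    for read in reads:
        key = _read_key(read)
        if key in out:
            logger.warning("duplicate read key %s in %s; keeping first", key, label)
            continue
        out[key] = read
    return out


def merge_realigned(
    original: Iterable[pysam.AlignedSegment],
    realigned: Iterable[pysam.AlignedSegment],
) -> List[pysam.AlignedSegment]:
    """Update original reads with their realigned versions.

    A realigned read with the same (query name, first-of-pair) key replaces
    the original; realigned-only reads are added.  Duplicate keys within one
    source keep the first occurrence with a warning.
    """
    merged = _keyed(original, "original")
    merged.update(_keyed(realigned, "realigned"))
    return list(merged.values())


class _ReadStore:
    """In-memory per-chromosome read index with bisect lookup."""

    def __init__(self, reads: Iterable[pysam.AlignedSegment]) -> None:
        by_chrom: Dict[str, List[pysam.AlignedSegment]] = {}
        for read in reads:
            if read.is_unmapped or read.reference_name is None:
                continue
            by_chrom.setdefault(read.reference_name, []).append(read)
        self._by_chrom: Dict[str, List[pysam.AlignedSegment]] = {}
        self._starts: Dict[str, List[int]] = {}
        self._max_span: Dict[str, int] = {}
        for chrom, chrom_reads in by_chrom.items():
            chrom_reads.sort(key=lambda r: r.reference_start)
            self._by_chrom[chrom] = chrom_reads
            self._starts[chrom] = [r.reference_start for r in chrom_reads]
            self._max_span[chrom] = max(
                (r.reference_end or r.reference_start + 1) - r.reference_start
                for r in chrom_reads
            )

    def fetch(self, chrom: str, pos0: int) -> List[pysam.AlignedSegment]:
        reads = self._by_chrom.get(chrom)
        if not reads:
            return []
        starts = self._starts[chrom]
        lo = bisect_left(starts, pos0 - self._max_span[chrom] + 1)
        hi = bisect_right(starts, pos0)
        return [
            r for r in reads[lo:hi]
            if (r.reference_end or r.reference_start + 1) > pos0
        ]


class AlignmentSource:
    """Random access to one sample's reads, with optional realignment merge.

    Plain SAM input (not indexable) is loaded fully into memory, merged once
    at the read-set level, and served from a sorted per-chromosome index —
    adequate for the candidate-locus workloads this tool targets.  BAM/CRAM
    input is served through coordinate ``fetch`` and therefore requires an
    index; the realignment merge then happens per locus on the fetched read
    sets.
    """

    def __init__(
        self,
        path: str | Path,
        sample_id: str,
        realigned_path: Optional[str | Path] = None,
        exclude_flagged: bool = True,
    ) -> None:
        self.path = Path(path)
        self.sample_id = sample_id
        self.realigned_path = Path(realigned_path) if realigned_path else None
        self.exclude_flagged = exclude_flagged
        self._store: Optional[_ReadStore] = None
        self._afile: Optional[pysam.AlignmentFile] = None
        self._realigned_file: Optional[pysam.AlignmentFile] = None
        with pysam.AlignmentFile(str(self.path)) as f:
            self.header = f.header.copy()
        if self.path.suffix.lower() == ".sam":
            reads = self._load_all(self.path)
            if self.realigned_path is not None:
                reads = merge_realigned(reads, self._load_all(self.realigned_path))
            self._store = _ReadStore(reads)
        else:
            self._afile = self._open_indexed(self.path)
            if self.realigned_path is not None:
                self._realigned_file = self._open_indexed(self.realigned_path)

    @staticmethod
    def _load_all(path: Path) -> List[pysam.AlignedSegment]:
        with pysam.AlignmentFile(str(path)) as f:
            return list(f.fetch(until_eof=True))

    @staticmethod
    def _open_indexed(path: Path) -> pysam.AlignmentFile:
        afile = pysam.AlignmentFile(str(path))
        if not afile.has_index():
            afile.close()
            raise FileNotFoundError(
                f"alignment file {path} has no index; run 'samtools index' first"
            )
        return afile

    def close(self) -> None:
        for f in (self._afile, self._realigned_file):
            if f is not None:
                f.close()

    def __enter__(self) -> "AlignmentSource":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def fetch(self, chrom: str, pos0: int) -> List[pysam.AlignedSegment]:
        """All reads overlapping the 0-based position, realignment-merged."""
        if self._store is not None:
            return self._store.fetch(chrom, pos0)
        assert self._afile is not None
        try:
            original = list(self._afile.fetch(chrom, pos0, pos0 + 1))
        except (ValueError, KeyError):
            logger.warning(
                "%s: locus %s:%d outside contig bounds; empty pileup",
                self.path, chrom, pos0 + 1,
            )
            return []
        if self._realigned_file is None:
            return original
        try:
            realigned = list(self._realigned_file.fetch(chrom, pos0, pos0 + 1))
        except (ValueError, KeyError):
            realigned = []
        return merge_realigned(original, realigned)


def _base_at(read: pysam.AlignedSegment, pos0: int) -> Optional[Tuple[str, int]]:
    """(base, baseq) of the read at the reference position, or None if the
    read has a deletion/skip/clip there."""
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None:
        return None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            return seq[qpos].upper(), quals[qpos]
    return None


def load_pileup(
    source: AlignmentSource,
    locus: CandidateLocus,
    params: ModelParams,
    count_overlapping_mates_once: bool = False,
) -> SamplePileup:
    """Quality-filtered pileup of one sample at one candidate locus.

    One observation per aligned read with a match/mismatch base at the
    position.  Reads below ``mapq_min``, bases below ``baseq_min``,
    non-canonical bases, and (by default) duplicate/secondary/supplementary
    alignments contribute nothing.  With ``count_overlapping_mates_once``
    only the higher-quality mate of an overlapping pair is kept; by default
    both mates count independently.
    """
    observations: List[Tuple[ReadKey, ReadObservation]] = []
    for read in source.fetch(locus.chrom, locus.pos0):
        if read.is_unmapped:
            continue
        if source.exclude_flagged and (
            read.is_duplicate or read.is_secondary or read.is_supplementary
        ):
            continue
        if read.mapping_quality < params.mapq_min:
            continue
        hit = _base_at(read, locus.pos0)
        if hit is None:
            continue
        base, baseq = hit
        if baseq < params.baseq_min or base not in BASES:
            continue
        obs = ReadObservation(
            base=base,
            error_prob=phred_to_error_prob(baseq),
            forward_strand=not read.is_reverse,
            mapping_quality=read.mapping_quality,
        )
        observations.append((_read_key(read), obs))

    if count_overlapping_mates_once:
        best: Dict[str, ReadObservation] = {}
        for (qname, _), obs in observations:
            prev = best.get(qname)
            if prev is None or obs.error_prob < prev.error_prob:
                best[qname] = obs
        kept = tuple(best.values())
    else:
        kept = tuple(obs for _, obs in observations)
    return SamplePileup(sample_id=source.sample_id, observations=kept)
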