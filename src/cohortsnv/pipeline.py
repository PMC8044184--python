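"""End-to-end joint calling: candidates -> pileups -> posterior -> filters -> VCF.

Per candidate locus the pipeline builds quality-filtered pileups for every
tumor sample (merging realigned reads when provided), drops all-normal
samples, computes the somatic posterior and the maximum-likelihood tumor
allele, applies the defer-to-single-caller rule, and — for emitted calls —
the support vector, tumor-in-normal score, and the empirical filters.  The
output is a VCF v4.2 with the somatic probability (PROB), TIN score, and
per-sample depth/support annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .candidates import CandidateLocus, CandidateSet, extract_candidates
from .filters import (
    ALL_FLAGS,
    CallRecord,
    apply_empirical_filters,
    cluster_filter,
    defer_single_sample,
    should_remove,
    tin_filter,
)
from .model import (
    ModelParams,
    allele_counts,
    estimate_tumor_allele,
    omit_all_normal_samples,
    per_sample_support,
    somatic_posterior,
    tin_posterior,
)
from .pileup import AlignmentSource, load_pileup

logger = logging.getLogger(__name__)

_FLAG_DESCRIPTIONS = {
    "low-normal-depth": "Normal-sample depth below 6",
    "low-tumor-support": "Tumor allele count below 4 in all samples",
    "empty-strand": "No tumor-allele reads on one strand in all samples",
    "cluster": "At least 3 call sites within a 100 bp span",
    "TIN": "Tumor-in-normal score below threshold",
}


@dataclass
class CallConfig:
    """Inputs and settings of one joint-calling run."""

    normal: str
    tumors: List[Tuple[str, str]]  # (sample id, alignment path)
    candidate_vcfs: List[Tuple[str, str]]  # (sample id, VCF path)
    output: str
    reference: Optional[str] = None
    realigned: Dict[str, str] = field(default_factory=dict)  # sample id -> path
    normal_realigned: Optional[str] = None
    params: ModelParams = field(default_factory=ModelParams)
    filter_mode: str = "novel"
    count_overlapping_mates_once: bool = False
    exclude_flagged: bool = True

    def __post_init__(self) -> None:
        if len(self.tumors) < 1:
            raise ValueError("at least one tumor sample is required")
        tumor_ids = [s for s, _ in self.tumors]
        vcf_ids = [s for s, _ in self.candidate_vcfs]
        if sorted(tumor_ids) != sorted(vcf_ids):
            raise ValueError(
                "tumor alignments and candidate VCFs name different samples: "
                f"{tumor_ids} vs {vcf_ids}"
            )


@dataclass
class CallResult:
    records: List[CallRecord]
    summary: Dict[str, object]
    candidates: CandidateSet


def _check_reference(
    candidates: CandidateSet, reference: Optional[str]
) -> Tuple[List[CandidateLocus], int]:
    """Drop candidates whose VCF REF disagrees with the reference genome."""
    if reference is None:
        return list(candidates.loci), 0
    n_mismatch = 0
    kept: List[CandidateLocus] = []
    with pysam.FastaFile(reference) as fasta:
        contigs = set(fasta.references)
        for locus in candidates:
            if locus.chrom not in contigs:
                n_mismatch += 1
                continue
            ref_base = fasta.fetch(locus.chrom, locus.pos0, locus.pos0 + 1).upper()
            if ref_base != locus.normal_allele:
                logger.warning(
                    "REF mismatch vs reference at %s:%d (%s vs %s); skipped",
                    locus.chrom, locus.pos, locus.normal_allele, ref_base,
                )
                n_mismatch += 1
                continue
            kept.append(locus)
    return kept, n_mismatch


def run_call(config: CallConfig) -> CallResult:
    """Execute the joint-calling workflow and write the output VCF."""
    params = config.params
    candidates = extract_candidates(config.candidate_vcfs)
    loci, n_ref_mismatch = _check_reference(candidates, config.reference)
    tumor_ids = [s for s, _ in config.tumors]

    normal_src = AlignmentSource(
        config.normal, "normal", config.normal_realigned,
        exclude_flagged=config.exclude_flagged,
    )
    tumor_srcs = [
        AlignmentSource(
            path, sample_id, config.realigned.get(sample_id),
            exclude_flagged=config.exclude_flagged,
        )
        for sample_id, path in config.tumors
    ]

    n_all_normal = n_deferred = n_below_threshold = 0
    records: List[CallRecord] = []
    try:
        for locus in loci:
            n_allele = locus.normal_allele
            tumor_pileups = [
                load_pileup(src, locus, params, config.count_overlapping_mates_once)
                for src in tumor_srcs
            ]
            retained, omitted = omit_all_normal_samples(tumor_pileups, n_allele)
            if not retained:
                logger.debug(
                    "%s:%d: all samples all-normal; no call", locus.chrom, locus.pos
                )
                n_all_normal += 1
                continue
            posterior = somatic_posterior(retained, n_allele, params)
            t_star = estimate_tumor_allele(posterior.log_marginal_by_t, n_allele)

            n_with_t = sum(
                1 for p in tumor_pileups
                if any(o.base == t_star for o in p.observations)
            )
            originally_any = len(locus.originally_called_in) > 0
            if not defer_single_sample(None, n_with_t, originally_any):
                n_deferred += 1
                continue
            if posterior.somatic_prob < params.call_threshold and not originally_any:
                n_below_threshold += 1
                continue

            normal_pileup = load_pileup(
                normal_src, locus, params, config.count_overlapping_mates_once
            )
            tin = tin_posterior(normal_pileup, retained, n_allele, t_star, params)
            support = per_sample_support(tumor_pileups, n_allele, t_star, params)
            counts = [allele_counts(p, n_allele, t_star) for p in tumor_pileups]
            records.append(
                CallRecord(
                    locus=locus,
                    tumor_allele=t_star,
                    somatic_prob=posterior.somatic_prob,
                    support=support,
                    tin_score=tin,
                    normal_depth=normal_pileup.depth,
                    tcount=[c.d_t for c in counts],
                    strand_counts=[(c.fwd_t, c.rev_t) for c in counts],
                    depths=[p.depth for p in tumor_pileups],
                    novel=not originally_any,
                )
            )
    finally:
        normal_src.close()
        for src in tumor_srcs:
            src.close()

    for record in records:
        apply_empirical_filters(record)
        tin_filter(record, params.tin_threshold)
    cluster_filter(records)
    kept = [r for r in records if not should_remove(r, config.filter_mode)]

    contigs = [
        (sq["SN"], sq["LN"]) for sq in normal_src.header.to_dict().get("SQ", [])
    ]
    write_vcf(kept, tumor_ids, config.output, contigs)

    flag_counts = {
        flag: sum(1 for r in records if flag in r.filter_flags)
        for flag in ALL_FLAGS
    }
    summary: Dict[str, object] = {
        "n_candidates": len(candidates),
        "n_skipped_non_snv": candidates.n_skipped_non_snv,
        "n_ref_conflicts": candidates.n_ref_conflicts,
        "n_ref_mismatch": n_ref_mismatch,
        "n_all_normal": n_all_normal,
        "n_deferred": n_deferred,
        "n_below_threshold": n_below_threshold,
        "n_flagged_removed": len(records) - len(kept),
        "n_calls": len(kept),
        "flag_counts": flag_counts,
    }
    return CallResult(records=kept, summary=summary, candidates=candidates)


def write_vcf(
    records: Sequence[CallRecord],
    sample_ids: Sequence[str],
    path: str | Path,
    contigs: Sequence[Tuple[str, int]],
) -> Path:
    """Write call records as VCF v4.2.

    INFO: PROB (somatic probability), TIN (Phred tumor-in-normal score),
    NSUP (number of supporting samples).  Per tumor sample: DP (filtered
    depth), TCOUNT (tumor-allele count), SB (forward,reverse tumor-allele
    counts), ZS (supporting 0/1).  FILTER carries the flag names, or PASS.
    Records must arrive sorted by (contig order, position).
    """
    path = Path(path)
    header = pysam.VariantHeader()
    contig_rank = {}
    for name, length in contigs:
        header.contigs.add(name, length=length)
        contig_rank[name] = len(contig_rank)
    for flag in ALL_FLAGS:
        header.filters.add(flag, None, None, _FLAG_DESCRIPTIONS[flag])
    header.info.add("PROB", 1, "Float", "Posterior somatic probability")
    header.info.add("TIN", 1, "Float", "Phred-scaled tumor-in-normal score")
    header.info.add("NSUP", 1, "Integer", "Number of supporting tumor samples")
    header.formats.add("DP", 1, "Integer", "Quality-filtered depth")
    header.formats.add("TCOUNT", 1, "Integer", "Tumor allele count")
    header.formats.add("SB", 2, "Integer", "Tumor allele strand counts (fwd,rev)")
    header.formats.add("ZS", 1, "Integer", "Sample supports the call (1) or not (0)")
    for sample_id in sample_ids:
        header.add_sample(sample_id)

    last_key: Optional[Tuple[int, int]] = None
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for record in records:
            key = (contig_rank[record.locus.chrom], record.locus.pos)
            if last_key is not None and key < last_key:
                raise ValueError("records must be sorted by (chrom, pos)")
            last_key = key
            rec = out.new_record(
                contig=record.locus.chrom,
                start=record.locus.pos0,
                alleles=(record.locus.normal_allele, record.tumor_allele),
            )
            if record.filter_flags:
                for flag in sorted(record.filter_flags):
                    rec.filter.add(flag)
            else:
                rec.filter.add("PASS")
            rec.info["PROB"] = float(record.somatic_prob)
            rec.info["TIN"] = float(record.tin_score)
            rec.info["NSUP"] = int(sum(record.support))
            for i, sample_id in enumerate(sample_ids):
                rec.samples[sample_id]["DP"] = record.depths[i]
                rec.samples[sample_id]["TCOUNT"] = record.tcount[i]
                rec.samples[sample_id]["SB"] = record.strand_counts[i]
                rec.samples[sample_id]["ZS"] = record.support[i]
            out.write(rec)
    return path
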