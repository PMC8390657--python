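"""Transcriptional activity of DNA viral contigs from filtered alignments.

Transcript alignments are kept only under stringent cutoffs — percent
identity strictly above 0.95 and aligned fraction of the read strictly above
0.80.  Identity is defined over aligned read bases (CIGAR M/=/X) using the
NM-equivalent edit count; alignment fraction is relative to the read length
(soft-clipped bases count toward the read length but not the aligned bases).

Activity of a contig in a sample is its average base coverage — the per-base
depth summed over the contig divided by the contig length — scaled by the
sample's sequencing effort: ``normalized_activity = average_base_coverage /
(total_reads_in_sample / 1e6)``.  Deletions in the read consume reference
depth; insertions do not.  An optional switch divides by the contig length a
second time for strict reproduction of a double length normalization.

Retained reads are partitioned into gene-coding and noncoding by majority
overlap of their aligned reference bases with the gene intervals (ties count
as coding), and lysogenic-marker (integrase/excisionase) transcript counts
are normalized per million reads after the same filter.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord, GeneInterval

DEFAULT_ID_CUT = 0.95
DEFAULT_FRAC_CUT = 0.80

_REF_CONSUMING = frozenset("MDN=X")
_ALIGNED = frozenset("M=X")


def alignment_metrics(a: AlignmentRecord) -> tuple[float, float]:
    """(identity fraction, alignment fraction) of one mapped record.

    identity = (aligned read bases - NM edits) / aligned read bases;
    alignment fraction = aligned read bases / read length.  A record flagged
    for a missing mismatch count is refused.
    """
    if a.mismatch_count is None:
        raise ValueError(
            f"alignment {a.read_id}: missing NM tag, identity undefined"
        )
    aligned = a.aligned_read_bases
    if aligned == 0 or a.read_length == 0:
        return 0.0, 0.0
    matched = max(aligned - a.mismatch_count, 0)
    return matched / aligned, aligned / a.read_length


class FilterResult(list):
    """Retained alignments plus per-reason counts of rejected records."""

    def __init__(self, records: Iterable[AlignmentRecord] = ()) -> None:
        super().__init__(records)
        self.rejected: Counter[str] = Counter()


def filter_alignments(records: Iterable[AlignmentRecord],
                      id_cut: float = DEFAULT_ID_CUT,
                      frac_cut: float = DEFAULT_FRAC_CUT) -> FilterResult:
    """Retain records with identity > id_cut AND aligned fraction > frac_cut.

    Both inequalities are strict: a record at exactly the cutoff is rejected.
    Records flagged for a missing NM tag are rejected with reason
    ``missing_nm``.
    """
    out = FilterResult()
    for a in records:
        if a.mismatch_count is None:
            out.rejected["missing_nm"] += 1
            continue
        identity, fraction = alignment_metrics(a)
        if identity <= id_cut:
            out.rejected["low_identity"] += 1
        elif fraction <= frac_cut:
            out.rejected["low_fraction"] += 1
        else:
            out.append(a)
    return out


@dataclass
class ActivityProfile:
    """Per-contig, per-sample transcription summary."""

    contig_id: str
    sample_id: str
    mapped_read_count: int
    depth: np.ndarray
    average_base_coverage: float
    normalized_activity: float


def _ref_segments(a: AlignmentRecord) -> list[tuple[int, int]]:
    """Reference intervals consumed by M/=/X/D ops (0-based half-open)."""
    segments = []
    pos = a.contig_start
    for op, n in a.cigar:
        if op in _ALIGNED or op == "D":
            segments.append((pos, pos + n))
            pos += n
        elif op == "N":
            pos += n
    return segments


def depth_and_activity(retained: Sequence[AlignmentRecord], contig_id: str,
                       contig_length: int, total_reads_in_sample: int,
                       sample_id: str = "",
                       per_million: bool = True,
                       length_norm_twice: bool = False) -> ActivityProfile:
    """Per-base depth and normalized activity of one contig in one sample.

    ``sum(depth)`` equals the total aligned reference bases of the retained
    records exactly.  With ``per_million`` the average base coverage is
    divided by total reads (in millions); ``length_norm_twice`` additionally
    divides by the contig length again (alternate reading of the
    normalization, off by default).
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if total_reads_in_sample <= 0:
        raise ValueError("total_reads_in_sample must be positive")
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    n = 0
    for a in retained:
        if a.contig_id != contig_id:
            continue
        n += 1
        for s, e in _ref_segments(a):
            s = max(s, 0)
            e = min(e, contig_length)
            if s < e:
                diff[s] += 1
                diff[e] -= 1
    depth = np.cumsum(diff[:-1])
    avg = float(depth.sum()) / contig_length
    activity = avg
    if per_million:
        activity /= total_reads_in_sample / 1e6
    if length_norm_twice:
        activity /= contig_length
    return ActivityProfile(contig_id, sample_id, n, depth, avg, activity)


def partition_coding(retained: Sequence[AlignmentRecord],
                     genes: Sequence[GeneInterval],
                     contig_length: int) -> tuple[int, int, float]:
    """Split retained reads into gene-coding and noncoding.

    A read is coding when the majority of its aligned reference bases (M/=/X)
    overlap any gene interval; an exact 50/50 split counts as coding.
    Returns (coding count, noncoding count, percent noncoding).
    """
    mask = np.zeros(contig_length, dtype=bool)
    for g in genes:
        if g.end > contig_length:
            raise ValueError(f"gene {g.gene_id!r} exceeds contig length")
        mask[g.start:g.end] = True
    coding = noncoding = 0
    for a in retained:
        in_gene = total = 0
        pos = a.contig_start
        for op, nn in a.cigar:
            if op in _ALIGNED:
                s, e = max(pos, 0), min(pos + nn, contig_length)
                if s < e:
                    in_gene += int(mask[s:e].sum())
                    total += e - s
                pos += nn
            elif op in ("D", "N"):
                pos += nn
        if total and 2 * in_gene >= total:
            coding += 1
        else:
            noncoding += 1
    n = coding + noncoding
    pct_noncoding = 100.0 * noncoding / n if n else 0.0
    return coding, noncoding, pct_noncoding


def marker_counts(records: Iterable[AlignmentRecord],
                  marker_classes: Mapping[str, str],
                  total_reads_in_sample: int,
                  id_cut: float = DEFAULT_ID_CUT,
                  frac_cut: float = DEFAULT_FRAC_CUT) -> dict[str, float]:
    """Per-million transcript counts for each lysogenic marker class.

    ``marker_classes`` maps marker reference ids to a class (integrase or
    excisionase).  The same identity/fraction filter as for viral contigs is
    applied before counting.
    """
    if total_reads_in_sample <= 0:
        raise ValueError("total_reads_in_sample must be positive")
    classes = sorted(set(marker_classes.values()))
    counts = {c: 0 for c in classes}
    for a in filter_alignments(records, id_cut, frac_cut):
        cls = marker_classes.get(a.contig_id)
        if cls is not None:
            counts[cls] += 1
    scale = total_reads_in_sample / 1e6
    return {c: counts[c] / scale for c in classes}
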