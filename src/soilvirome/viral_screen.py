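"""Ensemble identification of DNA viral contigs.

A contig is called viral when it is longer than 2.5 kb and satisfies at
least three of four independent lines of evidence:

1. *probabilistic* — more of its genes have a viral than a cellular origin,
   where each gene's origin is the class of the database channel (three viral,
   two cellular) with the highest bit score;
2. *VirSorter* — classified category 1–3 by the external VirSorter run;
3. *IMG/VR* — a database hit at E <= 1.0e-05;
4. *VirFinder* — p < 0.05 together with a score > 0.90.

Channels 2–4 are consumed from an evidence table produced by the external
tools; the computation owned here is criterion 1 and the >= 3/4 integration.
Ties between a viral and a cellular channel resolve to cellular
(conservative viral calling).  A missing external channel counts as
criterion-false rather than excluding the contig: the integration rule is
defined over four fixed criteria.

The module also flags transcribed auxiliary metabolic genes (AMGs): genes
with a metabolic annotation at E <= 1e-5 that have at least one viral-labeled
gene strictly before and one strictly after them in genome order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import ContigRecord

VIRAL_CHANNELS = ("viral_hmm", "viral_pfam", "ncvog")
CELLULAR_CHANNELS = ("bacterial", "archaeal")
ALL_CHANNELS = VIRAL_CHANNELS + CELLULAR_CHANNELS

DEFAULT_MIN_LENGTH = 2500
DEFAULT_MIN_CRITERIA = 3
AMG_EVALUE_CUTOFF = 1e-5


def gene_origin_vote(profile: Mapping[str, float]) -> str:
    """Origin of a gene from its per-channel best bit scores.

    Returns ``"viral"``, ``"cellular"`` or ``"unassigned"`` (empty profile).
    The winning class is that of the maximum bit score; a tie between a viral
    and a cellular channel resolves to cellular.
    """
    best_viral = -math.inf
    best_cellular = -math.inf
    for ch, score in profile.items():
        if score is None or (isinstance(score, float) and math.isnan(score)):
            continue
        if score < 0:
            raise ValueError(f"negative bit score for channel {ch!r}")
        if ch in VIRAL_CHANNELS:
            best_viral = max(best_viral, score)
        elif ch in CELLULAR_CHANNELS:
            best_cellular = max(best_cellular, score)
        else:
            raise ValueError(f"unknown channel {ch!r}")
    if best_viral == -math.inf and best_cellular == -math.inf:
        return "unassigned"
    return "viral" if best_viral > best_cellular else "cellular"


def criterion_probabilistic(labels: Iterable[str]) -> bool:
    """True iff strictly more viral- than cellular-origin genes (c1)."""
    n_viral = n_cellular = 0
    for lab in labels:
        if lab == "viral":
            n_viral += 1
        elif lab == "cellular":
            n_cellular += 1
    return n_viral > n_cellular


@dataclass(frozen=True)
class CriterionVector:
    """The four boolean criteria plus the raw channel values behind c2–c4."""

    c1_probabilistic: bool
    c2_virsorter: bool
    c3_imgvr: bool
    c4_virfinder: bool
    virsorter_category: float = math.nan
    imgvr_evalue: float = math.nan
    virfinder_score: float = math.nan
    virfinder_p: float = math.nan

    @property
    def n_criteria(self) -> int:
        return sum((self.c1_probabilistic, self.c2_virsorter,
                    self.c3_imgvr, self.c4_virfinder))


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def evaluate_criteria(gene_labels: Iterable[str],
                      virsorter_category: float = math.nan,
                      imgvr_evalue: float = math.nan,
                      virfinder_score: float = math.nan,
                      virfinder_p: float = math.nan) -> CriterionVector:
    """Evaluate the four screening criteria from raw channel values.

    c2: category in {1, 2, 3}; c3: E <= 1.0e-05; c4: p < 0.05 AND
    score > 0.90 (strict).  A missing channel yields False.
    """
    c2 = (not _is_missing(virsorter_category)
          and float(virsorter_category) in (1.0, 2.0, 3.0))
    c3 = not _is_missing(imgvr_evalue) and imgvr_evalue <= 1.0e-05
    c4 = (not _is_missing(virfinder_p) and not _is_missing(virfinder_score)
          and virfinder_p < 0.05 and virfinder_score > 0.90)
    return CriterionVector(
        c1_probabilistic=criterion_probabilistic(gene_labels),
        c2_virsorter=c2, c3_imgvr=c3, c4_virfinder=c4,
        virsorter_category=(math.nan if _is_missing(virsorter_category)
                            else float(virsorter_category)),
        imgvr_evalue=(math.nan if _is_missing(imgvr_evalue)
                      else float(imgvr_evalue)),
        virfinder_score=(math.nan if _is_missing(virfinder_score)
                         else float(virfinder_score)),
        virfinder_p=(math.nan if _is_missing(virfinder_p)
                     else float(virfinder_p)),
    )


def classify_contig(vec: CriterionVector, length: int,
                    min_length: int = DEFAULT_MIN_LENGTH,
                    min_criteria: int = DEFAULT_MIN_CRITERIA) -> bool:
    """Final viral call: length strictly above 2500 bp and >= 3/4 criteria."""
    if length <= 0:
        raise ValueError("contig length must be positive")
    return length > min_length and vec.n_criteria >= min_criteria


def flag_amg(gene_labels: Sequence[tuple[str, str, float | None]],
             evalue_cutoff: float = AMG_EVALUE_CUTOFF) -> list[str]:
    """Flag auxiliary metabolic genes on a viral contig.

    ``gene_labels`` is the contig's genes ordered by start position as
    (gene_id, origin label, metabolic annotation E-value or None).  A gene is
    flagged iff its metabolic E-value is <= the cutoff and viral-labeled
    genes exist both strictly before and strictly after it.
    """
    viral_pos = [i for i, (_, lab, _) in enumerate(gene_labels)
                 if lab == "viral"]
    if not viral_pos:
        return []
    first_viral, last_viral = viral_pos[0], viral_pos[-1]
    flagged = []
    for i, (gid, _, ev) in enumerate(gene_labels):
        if ev is None or (isinstance(ev, float) and math.isnan(ev)):
            continue
        if ev <= evalue_cutoff and first_viral < i < last_viral:
            flagged.append(gid)
    return flagged


def screen_contigs(contigs: Sequence[ContigRecord], evidence: pd.DataFrame,
                   min_length: int = DEFAULT_MIN_LENGTH,
                   min_criteria: int = DEFAULT_MIN_CRITERIA) -> pd.DataFrame:
    """Apply the four-criterion screen to an assembly with an evidence table.

    The evidence table has one row per gene with the five bit-score columns
    and contig-level channel columns (virsorter_category, imgvr_evalue,
    virfinder_score, virfinder_p; optional metabolic_evalue per gene).
    Returns one row per contig with the criteria, the viral call, and the
    flagged AMG gene ids (comma-joined).
    """
    by_contig = dict(tuple(evidence.groupby("contig_id", sort=False)))
    rows = []
    for contig in contigs:
        ev = by_contig.get(contig.id)
        if ev is None or ev.empty:
            vec = evaluate_criteria([])
            amgs: list[str] = []
        else:
            order = {g.gene_id: g.start for g in (contig.genes or [])}
            ev = ev.assign(_start=ev["gene_id"].map(order)).sort_values(
                ["_start", "gene_id"], na_position="last")
            labels = [
                gene_origin_vote({ch: row[ch] for ch in ALL_CHANNELS
                                  if ch in ev.columns})
                for _, row in ev.iterrows()
            ]
            head = ev.iloc[0]
            vec = evaluate_criteria(
                labels,
                virsorter_category=head.get("virsorter_category", math.nan),
                imgvr_evalue=head.get("imgvr_evalue", math.nan),
                virfinder_score=head.get("virfinder_score", math.nan),
                virfinder_p=head.get("virfinder_p", math.nan),
            )
            triples = [
                (row["gene_id"], lab, row.get("metabolic_evalue"))
                for (_, row), lab in zip(ev.iterrows(), labels)
            ]
            amgs = flag_amg(triples)
        rows.append({
            "contig_id": contig.id,
            "length": len(contig),
            "c1_probabilistic": vec.c1_probabilistic,
            "c2_virsorter": vec.c2_virsorter,
            "c3_imgvr": vec.c3_imgvr,
            "c4_virfinder": vec.c4_virfinder,
            "n_criteria": vec.n_criteria,
            "viral": classify_contig(vec, len(contig), min_length,
                                     min_criteria),
            "amg_genes": ",".join(amgs),
        })
    return pd.DataFrame(rows)
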