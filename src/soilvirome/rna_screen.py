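"""RNA virus identification in metatranscriptome assemblies and abundances.

Contigs are screened through two channels.  The marker-gene route translates
all six reading frames, keeps stop-free peptides above a minimum length, and
scans them against RNA-dependent RNA polymerase (RdRP) motif profiles —
ungapped position-specific score matrices with thresholds calibrated to a
null percentile on random peptides.  Contigs the marker route misses fall
through to a reference-similarity route: the best hit against a reference
RNA viral genome table qualifies at E <= 1e-5 and its taxon is adopted.

Per-contig abundance is the average base coverage after the same stringent
alignment filter used for DNA viral activity (identity > 0.95, aligned
fraction > 0.80 — the shared code path in :mod:`soilvirome.activity`);
per-taxon abundance is the mean over member contigs, reported alongside a
log10(x + 1) transform.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .activity import DEFAULT_FRAC_CUT, DEFAULT_ID_CUT, depth_and_activity, \
    filter_alignments
from .io_formats import AlignmentRecord, ContigRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

REFERENCE_EVALUE_CUTOFF = 1e-5
DEFAULT_MIN_ORF_AA = 30

#: Synthetic RdRP core motifs, one per emulated RNA viral taxon.  These are
#: invented stand-ins for curated profile HMM consensus sequences; the
#: generator plants them and the default profiles are built from them.
RDRP_MOTIFS: dict[str, str] = {
    "Bromoviridae":    "FQCFHHWSWYCDVCEEWIGGDDELNTPYDLNQAFLCYPSM",
    "Leviviridae":     "HHDFSKTGRVTFIGSTKGCGECSLYGIVPGDDGISILLLL",
    "Nairoviridae":    "FVECHFPEFWTNWGDDICTCHLQDFCAEQMHQHYGQGNNW",
    "Paramyxoviridae": "DKPFYGDDMLNNKNKYWMAHHQMDNAAAFWCPAAHEKCVL",
    "Reoviridae":      "ARILQNQDSTNIGKSNEGEKGDPGDDRHDKGIFADTMMEQ",
    "Secoviridae":     "WGAYVNYCNPGDDFFMIMFKGMPLMGAQWPFKLKDVIASA",
}


@dataclass(frozen=True)
class PssmProfile:
    """Ungapped amino-acid position-specific score matrix with a threshold."""

    name: str
    matrix: np.ndarray       # (L, 20) log-odds-style scores
    threshold: float
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20 \
                or self.matrix.shape[0] < 10:
            raise ValueError("profile matrix must be (L >= 10, 20)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("profile scores must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Score of the consensus peptide itself (composition-corrected)."""
        return pssm_scan(self.consensus, replace(self, threshold=np.inf))


@dataclass(frozen=True)
class RnaViralHit:
    """An RNA viral contig call with its detection route and provenance."""

    contig_id: str
    route: str               # "rdrp" or "reference"
    best_name: str           # profile or reference name
    score: float             # profile score or E-value
    taxon: str

    def __post_init__(self) -> None:
        if self.route not in ("rdrp", "reference"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "reference" and self.score > REFERENCE_EVALUE_CUTOFF:
            raise ValueError("reference route requires E <= 1e-5")


def build_profile(name: str, consensus: str, taxon: str = "",
                  match_score: float = 2.0,
                  mismatch_mean: float = -1.0) -> PssmProfile:
    """Build a PSSM from a consensus peptide (threshold left at +inf).

    Mismatch scores vary deterministically around ``mismatch_mean`` per
    (position, residue) so that null score distributions are effectively
    continuous; the consensus residue scores ``match_score`` at every
    position.
    """
    idx = [_AA_INDEX[aa] for aa in consensus]
    L = len(idx)
    jitter = np.sin(np.outer(np.arange(1, L + 1),
                             np.arange(1, 21)) * 12.9898) * 0.2
    matrix = np.full((L, 20), mismatch_mean) + jitter
    matrix[np.arange(L), idx] = match_score
    return PssmProfile(name, matrix, threshold=np.inf, taxon=taxon or name)


def calibrate_threshold(profile: PssmProfile, *, seed: int,
                        n_null: int = 2000,
                        percentile: float = 99.0,
                        null_peptide_length: int | None = None
                        ) -> PssmProfile:
    """Set the hit threshold at a percentile of the null score distribution.

    The null is the best-window score of random peptides of
    ``null_peptide_length`` (the profile's own length by default, i.e. a
    single window).  For screening whole contigs, where the scan takes the
    maximum over the many windows of every ORF, calibrate with a null length
    comparable to a contig's translated content so the per-scan false-hit
    rate matches the nominal tail.  The percentile is taken with the
    "higher" method so the hit rate of null peptides at the threshold stays
    at or below the nominal tail.
    """
    rng = np.random.default_rng(seed)
    L = len(profile)
    M = null_peptide_length or L
    if M < L:
        raise ValueError("null peptide length shorter than the profile")
    residues = rng.integers(0, 20, size=(n_null, M))
    alphabet = np.array(list(AA_ALPHABET))
    unthresholded = replace(profile, threshold=np.inf)
    scores = np.array([
        pssm_scan("".join(alphabet[row]), unthresholded) for row in residues
    ])
    thr = float(np.percentile(scores, percentile, method="higher"))
    return replace(profile, threshold=np.nextafter(thr, np.inf))


#: null calibration used for whole-contig screening: best window over a
#: peptide comparable to a contig's total translated content
SCREEN_NULL_LENGTH = 2000
SCREEN_NULL_PERCENTILE = 99.9


def default_profiles(*, seed: int = 0) -> list[PssmProfile]:
    """Calibrated profiles for the bundled RdRP motifs (contig-scale null)."""
    return [calibrate_threshold(build_profile(taxon, motif, taxon),
                                seed=seed + i, n_null=300,
                                percentile=SCREEN_NULL_PERCENTILE,
                                null_peptide_length=SCREEN_NULL_LENGTH)
            for i, (taxon, motif) in enumerate(sorted(RDRP_MOTIFS.items()))]


# ---------------------------------------------------------------------------
# ORF extraction and scanning
# ---------------------------------------------------------------------------

def six_frame_orfs(sequence: str,
                   min_aa_length: int = DEFAULT_MIN_ORF_AA) -> list[str]:
    """Stop-free translations >= min length from all six frames."""
    if min_aa_length < 10:
        raise ValueError("min_aa_length must be >= 10")
    orfs: list[str] = []
    for nt in (sequence, str(Seq(sequence).reverse_complement())):
        for frame in range(3):
            sub = nt[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            orfs.extend(p for p in aa.split("*") if len(p) >= min_aa_length)
    return orfs


def pssm_scan(peptide: str, profile: PssmProfile) -> float:
    """Best composition-corrected ungapped window score against a profile.

    Each window's raw score (sum of per-position matrix entries) is reduced
    by the score expected if the window's own residues were shuffled — the
    mean, over the window's residue composition, of the matrix column sums.
    This first-order composition correction cancels the spurious high scores
    of low-complexity peptides rich in a residue the consensus repeats,
    without touching genuinely position-ordered signal.

    Residues outside the 20-letter alphabet score the column minimum.
    Raises when the peptide is shorter than the profile.
    """
    L = len(profile)
    if len(peptide) < L:
        raise ValueError("peptide shorter than the profile")
    col_min = profile.matrix.min(axis=1)
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in peptide])
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    pos = np.arange(L)
    raw = np.where(windows >= 0,
                   profile.matrix[pos, windows],
                   col_min[pos]).sum(axis=1)
    colsum = profile.matrix.sum(axis=0)
    per_residue = np.where(idx >= 0, colsum[idx], col_min.sum())
    expected = np.lib.stride_tricks.sliding_window_view(
        per_residue, L).mean(axis=1)
    return float((raw - expected).max())


def classify_rna_contig(contig: ContigRecord,
                        profiles: Sequence[PssmProfile],
                        reference_hits: pd.DataFrame | None = None,
                        min_orf_aa: int = DEFAULT_MIN_ORF_AA
                        ) -> RnaViralHit | None:
    """Two-route RNA viral call for one contig.

    The RdRP route wins if any ORF reaches any profile's threshold (taxon
    from the best-margin profile); otherwise the best reference hit at
    E <= 1e-5 is adopted; otherwise None.
    """
    orfs = six_frame_orfs(contig.sequence, min_orf_aa)
    best: tuple[float, PssmProfile] | None = None
    for profile in profiles:
        for orf in orfs:
            if len(orf) < len(profile):
                continue
            s = pssm_scan(orf, profile)
            margin = s - profile.threshold
            if s >= profile.threshold and (best is None or margin > best[0]):
                best = (margin, profile)
    if best is not None:
        profile = best[1]
        return RnaViralHit(contig.id, "rdrp", profile.name,
                           best[0] + profile.threshold, profile.taxon)
    if reference_hits is not None and not reference_hits.empty:
        mine = reference_hits[reference_hits["contig_id"] == contig.id]
        if not mine.empty:
            row = mine.loc[mine["evalue"].idxmin()]
            if row["evalue"] <= REFERENCE_EVALUE_CUTOFF:
                return RnaViralHit(contig.id, "reference", row["ref_name"],
                                   float(row["evalue"]), row["taxon"])
    return None


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def rna_abundance(hits: Sequence[RnaViralHit],
                  alignments: Iterable[AlignmentRecord],
                  contig_lengths: Mapping[str, int],
                  total_reads_in_sample: int,
                  id_cut: float = DEFAULT_ID_CUT,
                  frac_cut: float = DEFAULT_FRAC_CUT
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-contig and per-taxon abundance of identified RNA viruses.

    Per-contig abundance is the average base coverage of retained (filtered)
    alignments; per-taxon abundance is the mean over the taxon's member
    contigs, with a log10(value + 1) column for reporting.  Taxa with no
    member contigs are absent, not zero.
    """
    retained = filter_alignments(alignments, id_cut, frac_cut)
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for a in retained:
        by_contig.setdefault(a.contig_id, []).append(a)
    contig_rows = []
    for h in hits:
        L = contig_lengths[h.contig_id]
        prof = depth_and_activity(by_contig.get(h.contig_id, []),
                                  h.contig_id, L, total_reads_in_sample,
                                  per_million=False)
        contig_rows.append({"contig_id": h.contig_id, "taxon": h.taxon,
                            "route": h.route,
                            "coverage": prof.average_base_coverage})
    per_contig = pd.DataFrame(
        contig_rows, columns=["contig_id", "taxon", "route", "coverage"])
    if per_contig.empty:
        per_taxon = pd.DataFrame(columns=["taxon", "abundance",
                                          "log10_abundance"])
    else:
        per_taxon = (per_contig.groupby("taxon", sort=True)["coverage"]
                     .mean().rename("abundance").reset_index())
        per_taxon["log10_abundance"] = np.log10(per_taxon["abundance"] + 1.0)
    return per_contig, per_taxon
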