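"""Viral sequence catalog: dereplication and relatedness clustering.

Two complementary relatedness measures are implemented.  Average amino acid
identity (AAI) — the mean percent identity over reciprocal best-hit protein
pairs between two contigs — drives single-linkage clustering at a 70% cutoff.
Because fragmented assemblies can leave related contigs without shared
proteins, contigs left as singletons can be rescued into clusters through
tetranucleotide composition: each contig is summarised as 256 z-scores of
observed 4-mer counts against their maximal-order Markov expectation, and an
orphan joins the cluster of the member whose z-score vector it correlates
with best (Pearson).

Numerical conventions: tetranucleotide counting pools both strands; windows
containing N are skipped; percent identity of a protein pair is computed over
all aligned columns (matches, mismatches and internal gaps) of the best
local BLOSUM62 alignment; reciprocal best hits qualify at >= 20 aligned
residues and >= 20% identity.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ContigRecord

log = logging.getLogger("soilvirome")

AAI_CUTOFF = 70.0
RBH_MIN_ALIGNED = 20      # aligned columns
RBH_MIN_IDENTITY = 20.0   # percent


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------

def dereplicate(records: Sequence[ContigRecord]) -> list[ContigRecord]:
    """Remove exact duplicates and substrings (forward strand).

    Among duplicates the longest sequence is retained; ties break to the
    lexicographically smallest id.  Idempotent.
    """
    for r in records:
        if not r.id:
            raise ValueError("dereplicate requires non-empty ids")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    kept: list[ContigRecord] = []
    for rec in ordered:
        seq = rec.sequence.upper()
        if any(seq in k.sequence.upper() for k in kept):
            continue
        kept.append(rec)
    kept.sort(key=lambda r: r.id)
    return kept


# ---------------------------------------------------------------------------
# AAI
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _best_local_identity(aligner: Align.PairwiseAligner,
                         a: str, b: str) -> tuple[float, int]:
    """(percent identity, aligned columns) of the best local alignment."""
    if aligner.score(a, b) <= 0:
        return 0.0, 0
    aln = aligner.align(a, b)[0]
    identities, mismatches = aln.counts().identities, aln.counts().mismatches
    gaps = aln.counts().gaps
    columns = identities + mismatches + gaps
    if columns == 0:
        return 0.0, 0
    return 100.0 * identities / columns, columns


def pairwise_aai(proteins_a: Sequence[str], proteins_b: Sequence[str],
                 min_aligned: int = RBH_MIN_ALIGNED,
                 min_identity: float = RBH_MIN_IDENTITY) -> float | None:
    """AAI% between two protein sets, or None when no reciprocal best hits.

    Every A-vs-B protein pair is aligned locally under BLOSUM62; pairs that
    are best hits in both directions and pass the alignment-length and
    identity thresholds contribute their percent identity to the mean.
    """
    if not proteins_a or not proteins_b:
        log.warning("pairwise_aai: empty protein set, AAI undefined")
        return None
    aligner = _make_aligner()
    ident = np.zeros((len(proteins_a), len(proteins_b)))
    cols = np.zeros_like(ident, dtype=int)
    score = np.zeros_like(ident)
    for i, a in enumerate(proteins_a):
        for j, b in enumerate(proteins_b):
            s = aligner.score(a, b)
            score[i, j] = s
            if s > 0:
                ident[i, j], cols[i, j] = _best_local_identity(aligner, a, b)
    best_b = score.argmax(axis=1)   # best hit of each A protein
    best_a = score.argmax(axis=0)   # best hit of each B protein
    identities = []
    for i, j in enumerate(best_b):
        if best_a[j] != i or score[i, j] <= 0:
            continue
        if cols[i, j] >= min_aligned and ident[i, j] >= min_identity:
            identities.append(ident[i, j])
    if not identities:
        return None
    return float(np.mean(identities))


def aai_matrix(protein_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Symmetric AAI matrix (percent, NaN where undefined, diagonal 100)."""
    ids = sorted(protein_sets)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for cid in ids:
        mat.loc[cid, cid] = 100.0
    for a, b in itertools.combinations(ids, 2):
        aai = pairwise_aai(protein_sets[a], protein_sets[b])
        if aai is not None:
            mat.loc[a, b] = mat.loc[b, a] = aai
    return mat


# ---------------------------------------------------------------------------
# single-linkage clustering
# ---------------------------------------------------------------------------

def single_linkage(matrix: pd.DataFrame,
                   cutoff: float = AAI_CUTOFF) -> dict[str, str]:
    """Connected components of the graph with edges AAI >= cutoff.

    Missing entries count as below the cutoff.  Cluster ids are deterministic:
    each cluster is named by its lexicographically smallest member id.
    """
    ids = list(matrix.index)
    if not ids:
        return {}
    vals = matrix.to_numpy(dtype=float)
    adj = np.nan_to_num(vals, nan=-np.inf) >= cutoff
    np.fill_diagonal(adj, True)
    n, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, list[str]] = {}
    for cid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(cid)
    out: dict[str, str] = {}
    for members in clusters.values():
        name = min(members)
        for m in members:
            out[m] = name
    return out


# ---------------------------------------------------------------------------
# tetranucleotide z-scores
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# index permutation mapping a k-mer code to its reverse complement code
def _rc_perm(k: int) -> np.ndarray:
    idx = np.arange(4 ** k)
    out = np.zeros_like(idx)
    for pos in range(k):
        digit = (idx >> (2 * (k - 1 - pos))) & 3
        out |= (3 - digit) << (2 * pos)
    return out


_RC = {k: _rc_perm(k) for k in (2, 3, 4)}


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """k-mer counts pooled over both strands; windows containing N skipped."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(codes) < k:
        return np.zeros(4 ** k, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    kidx = (win[valid] * powers).sum(axis=1)
    counts = np.bincount(kidx, minlength=4 ** k)
    return counts + counts[_RC[k]]


@dataclass(frozen=True)
class TetraProfile:
    """256 tetranucleotide z-scores for one contig (lexicographic 4-mer order)."""

    contig_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != (256,) or not np.all(np.isfinite(self.z)):
            raise ValueError("tetranucleotide profile must be 256 finite values")


def tetra_zscores(sequence: str, contig_id: str = "") -> TetraProfile:
    """Tetranucleotide z-scores under the maximal-order Markov expectation.

    For a 4-mer w = n1 n2 n3 n4 the expected count is
    E(w) = O(n1n2n3) * O(n2n3n4) / O(n2n3) from the observed tri- and
    dinucleotide counts, with variance
    var(w) = E(w) * (1 - O(n1n2n3)/O(n2n3)) * (1 - O(n2n3n4)/O(n2n3)),
    and z = (O - E) / sqrt(var).  Counts are pooled over both strands.
    """
    if len(sequence.replace("N", "")) < 7:
        raise ValueError("sequence too short for tetranucleotide z-scores")
    o4 = _kmer_counts(sequence, 4).astype(float)
    o3 = _kmer_counts(sequence, 3).astype(float)
    o2 = _kmer_counts(sequence, 2).astype(float)
    i4 = np.arange(256)
    left = i4 >> 2          # n1 n2 n3
    right = i4 & 63         # n2 n3 n4
    mid = (i4 >> 2) & 15    # n2 n3
    with np.errstate(divide="ignore", invalid="ignore"):
        e = o3[left] * o3[right] / o2[mid]
        var = e * (1.0 - o3[left] / o2[mid]) * (1.0 - o3[right] / o2[mid])
        z = (o4 - e) / np.sqrt(var)
    z[~np.isfinite(z)] = 0.0
    return TetraProfile(contig_id, z)


def profile_correlation(a: TetraProfile, b: TetraProfile) -> float | None:
    """Pearson correlation of two z-score vectors; None if either is constant."""
    if np.std(a.z) == 0.0 or np.std(b.z) == 0.0:
        return None
    return float(np.corrcoef(a.z, b.z)[0, 1])


def rescue_assign(orphan: TetraProfile,
                  members: Sequence[tuple[str, TetraProfile]]) -> str | None:
    """Assign an orphan contig to the cluster of its best-correlated member.

    ``members`` pairs each clustered contig's cluster id with its profile.
    Ties break to the smallest cluster id; if every correlation is undefined
    the orphan stays a singleton (None, logged).
    """
    if not members:
        raise ValueError("rescue_assign requires at least one clustered member")
    best: tuple[float, str] | None = None
    for cluster_id, profile in members:
        r = profile_correlation(orphan, profile)
        if r is None:
            continue
        if best is None or r > best[0] or (r == best[0]
                                           and cluster_id < best[1]):
            best = (r, cluster_id)
    if best is None:
        log.info("rescue_assign: all correlations undefined for %s; "
                 "orphan stays singleton", orphan.contig_id)
        return None
    return best[1]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def translate_genes(contig: ContigRecord) -> list[str]:
    """Conceptual protein set of a contig: translated gene intervals."""
    from Bio.Seq import Seq

    proteins = []
    for g in contig.genes or []:
        nt = contig.sequence[g.start:g.end]
        if g.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        nt = nt[: len(nt) - len(nt) % 3]
        aa = str(Seq(nt).translate()).split("*")[0]
        if len(aa) >= 10:
            proteins.append(aa)
    return proteins


def cluster_contigs(protein_sets: Mapping[str, Sequence[str]],
                    profiles: Mapping[str, TetraProfile],
                    cutoff: float = AAI_CUTOFF,
                    rescue_min_r: float = 0.9) -> pd.DataFrame:
    """Full clustering stage: AAI single linkage plus tetranucleotide rescue.

    Singleton contigs are reassigned to the best-correlated multi-member
    cluster only when the best correlation reaches ``rescue_min_r`` (the
    rescue operation itself is threshold-free; the gate keeps genuinely
    unrelated singletons apart at the pipeline level).
    Returns a table (contig_id, cluster_id, method in {aai, tetra_rescue}).
    """
    mat = aai_matrix(protein_sets)
    assignment = single_linkage(mat, cutoff)
    sizes: dict[str, int] = {}
    for cl in assignment.values():
        sizes[cl] = sizes.get(cl, 0) + 1
    members = [(assignment[cid], profiles[cid]) for cid in sorted(assignment)
               if sizes[assignment[cid]] > 1 and cid in profiles]
    rows = []
    for cid in sorted(assignment):
        cluster, method = assignment[cid], "aai"
        if sizes[cluster] == 1 and members and cid in profiles:
            scored = [(profile_correlation(profiles[cid], p), cl)
                      for cl, p in members]
            scored = [(r, cl) for r, cl in scored if r is not None]
            if scored:
                r, cl = max(scored, key=lambda t: (t[0], t[1]))
                if r >= rescue_min_r:
                    cluster, method = rescue_assign(
                        profiles[cid], members), "tetra_rescue"
        rows.append({"contig_id": cid, "cluster_id": cluster,
                     "method": method})
    return pd.DataFrame(rows, columns=["contig_id", "cluster_id", "method"])
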