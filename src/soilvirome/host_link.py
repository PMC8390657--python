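"""Host assignment for DNA viral contigs by four methods and their consensus.

Method 1 (*spacer*): CRISPR arrays are detected on host contigs as >= 3
identical repeat copies (23–47 nt) separated by spacers (26–50 nt); a spacer
occurring verbatim — on either strand — in a viral contig links that contig
to the spacer's source host.  Method 2 (*host_similarity*) and Method 3
(*ref_virus*) consume tabular similarity-search hits (E <= 1e-3 and bit
score >= 50) against host contigs and reference viruses respectively; they
apply only to contigs the spacer method left unassigned (the nested
workflow).  Method 4 (*markov*) scores each viral contig under per-host
homogeneous Markov models (alignment-free composition likelihood) and pairs
it with the top-ranked host.

Only pairings where the nested workflow (Methods 1–3) and the Markov method
agree — compared at the phylum rank — carry the consensus flag and are
reported as final.  A viral contig may retain more than one consensus host.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ContigRecord
from .synthetic_data import revcomp

log = logging.getLogger("soilvirome")

BLASTN_MAX_EVALUE = 1e-3
BLASTN_MIN_BITSCORE = 50.0
REPEAT_LENGTH = (23, 47)
SPACER_LENGTH = (26, 50)
MIN_REPEATS = 3
DEFAULT_MARKOV_ORDER = 2


@dataclass(frozen=True)
class SpacerRecord:
    """A CRISPR spacer with its source host contig and taxon."""

    sequence: str
    source_host: str
    taxon: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        if not 20 <= len(self.sequence) <= 60:
            raise ValueError(
                f"spacer length {len(self.sequence)} outside 20-60 nt"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("spacer must be uppercase ACGT")


@dataclass
class HostPairing:
    """A (viral contig, host taxon) link with the methods that produced it."""

    viral_id: str
    host_taxon: str
    methods: frozenset[str]
    consensus: bool = False


# ---------------------------------------------------------------------------
# Method 1: CRISPR spacers
# ---------------------------------------------------------------------------

def detect_crispr(contig: ContigRecord,
                  min_repeats: int = MIN_REPEATS,
                  repeat_length: tuple[int, int] = REPEAT_LENGTH,
                  spacer_length: tuple[int, int] = SPACER_LENGTH,
                  taxon: str = "") -> list[SpacerRecord]:
    """Find CRISPR arrays by exact-word seeding and extension.

    Seeds are exact 23-mers (the minimum repeat length) recurring at array-
    compatible periods; a chain of >= ``min_repeats`` occurrences is extended
    rightward while all copies stay identical and the inter-repeat spacers
    stay within bounds.  The spacers — the inter-repeat sequences — are
    returned.
    """
    seq = contig.sequence
    k = repeat_length[0]
    if len(seq) < 150 or len(seq) < k + spacer_length[0]:
        return []
    min_period = k + spacer_length[0]
    max_period = repeat_length[1] + spacer_length[1]

    occ: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        occ.setdefault(seq[i:i + k], []).append(i)

    spacers: list[SpacerRecord] = []
    i = 0
    end_of_last = -1
    while i < len(seq) - k + 1:
        if i <= end_of_last:
            i = end_of_last + 1
            continue
        positions = occ.get(seq[i:i + k], [])
        if len(positions) < min_repeats or positions[0] != i:
            i += 1
            continue
        chain = [positions[0]]
        for p in positions[1:]:
            gap = p - chain[-1]
            if min_period <= gap <= max_period:
                chain.append(p)
            elif gap > max_period:
                break
        if len(chain) < min_repeats:
            i += 1
            continue
        # extend the repeat rightward while every copy agrees and spacers
        # stay long enough
        L = k
        while L < repeat_length[1]:
            nxt = {seq[c + L] for c in chain if c + L < len(seq)}
            if len(nxt) != 1 or len(nxt & set("ACGT")) != 1:
                break
            gaps_ok = all(chain[j + 1] - (chain[j] + L + 1) >= spacer_length[0]
                          for j in range(len(chain) - 1))
            if not gaps_ok or chain[-1] + L + 1 > len(seq):
                break
            L += 1
        found = [seq[chain[j] + L:chain[j + 1]]
                 for j in range(len(chain) - 1)]
        if all(spacer_length[0] <= len(s) <= spacer_length[1]
               and not set(s) - set("ACGT") for s in found):
            for j, s in enumerate(found):
                spacers.append(SpacerRecord(s, contig.id, taxon,
                                            chain[j] + L))
            end_of_last = chain[-1] + L
            i = end_of_last + 1
        else:
            i += 1
    return spacers


def spacer_match(spacers: Iterable[SpacerRecord],
                 viral_contigs: Sequence[ContigRecord]) -> list[HostPairing]:
    """Exact spacer-to-virus matches on either strand (Method 1)."""
    pairings: list[HostPairing] = []
    seen: set[tuple[str, str]] = set()
    for sp in spacers:
        rc = revcomp(sp.sequence)
        for v in viral_contigs:
            if sp.sequence in v.sequence or rc in v.sequence:
                key = (v.id, sp.taxon)
                if key not in seen:
                    seen.add(key)
                    pairings.append(HostPairing(v.id, sp.taxon,
                                                frozenset({"spacer"})))
    return pairings


# ---------------------------------------------------------------------------
# Methods 2 and 3: similarity to host contigs / reference viruses
# ---------------------------------------------------------------------------

def _qualifies(row: pd.Series) -> bool:
    return (row["evalue"] <= BLASTN_MAX_EVALUE
            and row["bitscore"] >= BLASTN_MIN_BITSCORE)


def similarity_host(hits: pd.DataFrame,
                    taxonomy: Mapping[str, str]) -> list[HostPairing]:
    """Host pairings from BLASTN-style hits to host contigs (Method 2)."""
    pairings: list[HostPairing] = []
    seen: set[tuple[str, str]] = set()
    for _, row in hits.iterrows():
        if row.isna().any():
            log.warning("similarity_host: row with missing fields skipped")
            continue
        if not _qualifies(row):
            continue
        taxon = taxonomy.get(row["host_id"])
        if taxon is None:
            continue
        key = (row["viral_id"], taxon)
        if key not in seen:
            seen.add(key)
            pairings.append(HostPairing(row["viral_id"], taxon,
                                        frozenset({"host_similarity"})))
    return pairings


def ref_virus_host(hits: pd.DataFrame,
                   ref_hosts: Mapping[str, str]) -> list[HostPairing]:
    """Adopt the host of the single closest reference virus (Method 3).

    Among qualifying hits per viral contig the best is the highest bit score;
    ties break to the lowest E-value, then the smallest reference id.
    References lacking host metadata are skipped.
    """
    best: dict[str, tuple[float, float, str]] = {}
    for _, row in hits.iterrows():
        if row.isna().any() or not _qualifies(row):
            continue
        if row["ref_id"] not in ref_hosts:
            log.warning("ref_virus_host: reference %s lacks host metadata",
                        row["ref_id"])
            continue
        key = (-row["bitscore"], row["evalue"], row["ref_id"])
        vid = row["viral_id"]
        if vid not in best or key < best[vid]:
            best[vid] = key
    return [HostPairing(vid, ref_hosts[key[2]], frozenset({"ref_virus"}))
            for vid, key in sorted(best.items())]


# ---------------------------------------------------------------------------
# Method 4: homogeneous Markov models
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass
class MarkovModel:
    """Order-k homogeneous Markov model of one host genome.

    ``log_probs`` has shape (4**k, 4); each context row's probabilities sum
    to 1 (pseudocount-smoothed, both strands pooled).
    """

    host_id: str
    order: int
    log_probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.exp(self.log_probs)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-context probabilities must sum to 1")


def _transition_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(context index, next base) for every valid window, linear scan."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(codes) <= k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k + 1)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    ctx = (win[valid, :k] * powers).sum(axis=1)
    return ctx, win[valid, k]


def markov_train(sequence: str, order: int = DEFAULT_MARKOV_ORDER,
                 pseudocount: float = 1.0, host_id: str = "",
                 double_strand: bool = True) -> MarkovModel:
    """Train an order-k model; counts pooled over both strands by default.

    ``double_strand=False`` trains on the given strand only (useful for
    strand-specific sources; note a homopolymer then yields a degenerate
    single-transition chain, whereas double-strand pooling adds the
    complementary base).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(sequence) < 4 ** order * 10:
        log.warning("markov_train(%s): sequence short relative to 4^%d "
                    "contexts", host_id, order)
    counts = np.zeros((4 ** order, 4))
    strands = (sequence, revcomp(sequence)) if double_strand else (sequence,)
    for s in strands:
        ctx, nxt = _transition_codes(s, order)
        np.add.at(counts, (ctx, nxt), 1)
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    return MarkovModel(host_id, order, np.log(probs))


def markov_score(model: MarkovModel, sequence: str) -> float:
    """Mean per-nucleotide log-likelihood of a contig under a host model.

    The contig is scored circularly (the context wraps at the end), which
    makes the score exactly invariant to concatenating the sequence with
    itself.
    """
    k = model.order
    if len(sequence) < k + 1:
        raise ValueError("contig shorter than the model order + 1")
    wrapped = sequence + sequence[:k]
    ctx, nxt = _transition_codes(wrapped, k)
    if len(ctx) == 0:
        raise ValueError("no scoreable positions (all windows contain N)")
    return float(model.log_probs[ctx, nxt].mean())


def markov_predict(contig: ContigRecord, models: Sequence[MarkovModel],
                   taxonomy: Mapping[str, str] | None = None
                   ) -> tuple[HostPairing, dict[str, float]]:
    """Pair a viral contig with the top-scoring host (Method 4)."""
    if not models:
        raise ValueError("markov_predict requires at least one model")
    scores = {m.host_id: markov_score(m, contig.sequence) for m in models}
    best = min(sorted(scores), key=lambda h: (-scores[h], h))
    taxon = taxonomy.get(best, best) if taxonomy else best
    return HostPairing(contig.id, taxon, frozenset({"markov"})), scores


# ---------------------------------------------------------------------------
# nesting and consensus
# ---------------------------------------------------------------------------

def nested_pairings(spacer_pairs: Sequence[HostPairing],
                    similarity_pairs: Sequence[HostPairing],
                    ref_pairs: Sequence[HostPairing]) -> list[HostPairing]:
    """Nested workflow: similarity/reference only where spacers said nothing."""
    spacer_ids = {p.viral_id for p in spacer_pairs}
    out = list(spacer_pairs)
    out.extend(p for p in similarity_pairs if p.viral_id not in spacer_ids)
    out.extend(p for p in ref_pairs if p.viral_id not in spacer_ids)
    return out


def consensus(nested: Sequence[HostPairing],
              markov_pairs: Sequence[HostPairing]) -> list[HostPairing]:
    """Retain pairings where the nested workflow and Markov method agree.

    Agreement is evaluated at the taxon carried by the pairings (phylum by
    construction here).  Pairings without a taxon are dropped with a warning.
    The output is a subset of both inputs' (viral, taxon) pairs.
    """
    markov_taxa: dict[str, set[str]] = {}
    for p in markov_pairs:
        markov_taxa.setdefault(p.viral_id, set()).add(p.host_taxon)
    final: list[HostPairing] = []
    seen: set[tuple[str, str]] = set()
    for p in nested:
        if not p.host_taxon:
            log.warning("consensus: pairing for %s lacks a taxon; dropped",
                        p.viral_id)
            continue
        if p.host_taxon in markov_taxa.get(p.viral_id, ()):  # agreement
            key = (p.viral_id, p.host_taxon)
            if key not in seen:
                seen.add(key)
                final.append(HostPairing(
                    p.viral_id, p.host_taxon,
                    p.methods | frozenset({"markov"}), consensus=True))
    return final


def link_hosts(viral_contigs: Sequence[ContigRecord],
               host_contigs: Sequence[ContigRecord],
               taxonomy: Mapping[str, str],
               host_hits: pd.DataFrame | None = None,
               ref_hits: pd.DataFrame | None = None,
               ref_hosts: Mapping[str, str] | None = None,
               markov_order: int = DEFAULT_MARKOV_ORDER) -> pd.DataFrame:
    """Run Methods 1–4 end to end and report consensus pairings.

    Returns a table (viral_id, host_taxon, methods, consensus) containing the
    consensus pairings only.
    """
    spacers: list[SpacerRecord] = []
    for h in host_contigs:
        spacers.extend(detect_crispr(h, taxon=taxonomy.get(h.id, "")))
    sp_pairs = spacer_match(spacers, viral_contigs)
    sim_pairs = (similarity_host(host_hits, taxonomy)
                 if host_hits is not None else [])
    rv_pairs = (ref_virus_host(ref_hits, ref_hosts or {})
                if ref_hits is not None else [])
    nested = nested_pairings(sp_pairs, sim_pairs, rv_pairs)
    models = [markov_train(h.sequence, markov_order, host_id=h.id)
              for h in host_contigs]
    markov_pairs = [markov_predict(v, models, taxonomy)[0]
                    for v in viral_contigs]
    final = consensus(nested, markov_pairs)
    rows = [{"viral_id": p.viral_id, "host_taxon": p.host_taxon,
             "methods": ",".join(sorted(p.methods)),
             "consensus": p.consensus} for p in final]
    return pd.DataFrame(rows, columns=["viral_id", "host_taxon", "methods",
                                       "consensus"])
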