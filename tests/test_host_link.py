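"""CRISPR detection, similarity channels, Markov host models, consensus."""
import numpy as np
import pandas as pd
import pytest

from soilvirome import host_link as hl
from soilvirome.io_formats import ContigRecord
from soilvirome.synthetic_data import _markov_sequence, _markov_table, revcomp


def _array_contig(rng, spacers, repeat_len=30, flank=200):
    repeat = "".join("ACGT"[i] for i in rng.integers(0, 4, repeat_len))
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    body = repeat + "".join(s + repeat for s in spacers)
    return ContigRecord("host", left + body + right), repeat


class TestDetectCrispr:
    def test_planted_array_recovered_verbatim(self, rng):
        spacers = ["".join("ACGT"[i] for i in rng.integers(0, 4, 34))
                   for _ in range(3)]
        contig, _ = _array_contig(rng, spacers)
        found = hl.detect_crispr(contig, taxon="PhylumX")
        assert [s.sequence for s in found] == spacers
        assert all(s.taxon == "PhylumX" for s in found)

    def test_contig_without_repeats_is_empty(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        assert hl.detect_crispr(ContigRecord("h", seq)) == []

    def test_two_repeat_copies_insufficient(self, rng):
        spacers = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30))]
        contig, _ = _array_contig(rng, spacers)  # 2 repeats, 1 spacer
        assert hl.detect_crispr(contig) == []


class TestSpacerMatch:
    def test_exact_and_reverse_complement_match(self, rng):
        viral = ContigRecord(
            "v", "".join("ACGT"[i] for i in rng.integers(0, 4, 500)))
        fwd = viral.sequence[100:130]
        rc = revcomp(viral.sequence[300:340])
        spacers = [hl.SpacerRecord(fwd, "h1", "P1"),
                   hl.SpacerRecord(rc, "h2", "P2")]
        pairs = hl.spacer_match(spacers, [viral])
        assert {(p.viral_id, p.host_taxon) for p in pairs} == {
            ("v", "P1"), ("v", "P2")}

    def test_single_mismatch_is_no_match(self, rng):
        viral = ContigRecord(
            "v", "".join("ACGT"[i] for i in rng.integers(0, 4, 500)))
        spacer = list(viral.sequence[100:130])
        spacer[15] = {"A": "C"}.get(spacer[15], "A")
        pairs = hl.spacer_match(
            [hl.SpacerRecord("".join(spacer), "h", "P")], [viral])
        assert pairs == []


class TestSimilarityChannels:
    TAXA = {"h1": "Proteobacteria"}

    @pytest.mark.parametrize("evalue,bits,expected", [
        (1e-5, 60.0, 1), (1e-2, 60.0, 0), (1e-5, 49.0, 0), (1e-3, 50.0, 1),
    ])
    def test_method2_thresholds(self, evalue, bits, expected):
        hits = pd.DataFrame([{"viral_id": "v", "host_id": "h1",
                              "evalue": evalue, "bitscore": bits}])
        assert len(hl.similarity_host(hits, self.TAXA)) == expected

    def test_method3_takes_single_best(self):
        hits = pd.DataFrame([
            {"viral_id": "v", "ref_id": "r1", "evalue": 1e-9, "bitscore": 60},
            {"viral_id": "v", "ref_id": "r2", "evalue": 1e-7, "bitscore": 80},
        ])
        pairs = hl.ref_virus_host(hits, {"r1": "P1", "r2": "P2"})
        assert [(p.viral_id, p.host_taxon) for p in pairs] == [("v", "P2")]

    def test_method3_no_qualifying_hit(self):
        hits = pd.DataFrame([{"viral_id": "v", "ref_id": "r1",
                              "evalue": 0.1, "bitscore": 80}])
        assert hl.ref_virus_host(hits, {"r1": "P1"}) == []

    def test_reference_without_metadata_skipped(self):
        hits = pd.DataFrame([{"viral_id": "v", "ref_id": "r1",
                              "evalue": 1e-9, "bitscore": 80}])
        assert hl.ref_virus_host(hits, {}) == []


class TestMarkov:
    def test_degenerate_order0_chain(self):
        # single-strand training on a homopolymer: P(A) -> 1 as the
        # pseudocount vanishes, so the per-nt log-likelihood of "AAA" -> 0
        model = hl.markov_train("A" * 400, order=0, pseudocount=1e-12,
                                double_strand=False)
        assert hl.markov_score(model, "AAA") == pytest.approx(0.0, abs=1e-6)

    def test_probabilities_normalized(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        model = hl.markov_train(seq, order=2)
        assert np.allclose(np.exp(model.log_probs).sum(axis=1), 1.0,
                           atol=1e-9)

    def test_score_invariant_under_self_concatenation(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        model = hl.markov_train(seq, order=2)
        probe = seq[100:1100]
        assert hl.markov_score(model, probe + probe) == pytest.approx(
            hl.markov_score(model, probe), abs=1e-9)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            hl.markov_train("ACGT", order=-1)

    def test_short_contig_rejected(self):
        model = hl.markov_train("ACGTACGTACGT" * 10, order=2)
        with pytest.raises(ValueError):
            hl.markov_score(model, "AC")

    def test_own_host_scores_higher_in_95_percent_of_trials(self):
        """An order-2 model of host A ranks 10 kb fragments of A above an
        independent host B in >= 95 of 100 trials."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ta, tb = _markov_table(rng, 1.0), _markov_table(rng, 1.0)
            model_a = hl.markov_train(_markov_sequence(rng, ta, 30000),
                                      order=2, host_id="A")
            frag_a = _markov_sequence(rng, ta, 10000)
            frag_b = _markov_sequence(rng, tb, 10000)
            wins += (hl.markov_score(model_a, frag_a)
                     > hl.markov_score(model_a, frag_b))
        assert wins >= 95


class TestConsensus:
    def _pair(self, vid, taxon, method):
        return hl.HostPairing(vid, taxon, frozenset({method}))

    def test_agreement_retained(self):
        nested = [self._pair("v", "Proteobacteria", "spacer")]
        markov = [self._pair("v", "Proteobacteria", "markov")]
        out = hl.consensus(nested, markov)
        assert len(out) == 1 and out[0].consensus
        assert out[0].methods == frozenset({"spacer", "markov"})

    def test_markov_only_dropped(self):
        assert hl.consensus([], [self._pair("v", "P", "markov")]) == []

    def test_disagreement_dropped(self):
        nested = [self._pair("v", "Actinobacteria", "spacer")]
        markov = [self._pair("v", "Proteobacteria", "markov")]
        assert hl.consensus(nested, markov) == []

    def test_nested_precedence(self):
        spacer = [self._pair("v1", "P1", "spacer")]
        sim = [self._pair("v1", "P2", "host_similarity"),
               self._pair("v2", "P3", "host_similarity")]
        nested = hl.nested_pairings(spacer, sim, [])
        assert {(p.viral_id, p.host_taxon) for p in nested} == {
            ("v1", "P1"), ("v2", "P3")}

    def test_output_subset_of_both_inputs(self, small_truth):
        """consensus output is a subset of nested and Markov pairs (exact)."""
        viral = [ContigRecord(v.id, v.sequence)
                 for v in small_truth.viral_contigs]
        hosts = [ContigRecord(h.id, h.sequence)
                 for h in small_truth.host_genomes]
        taxa = small_truth.taxonomy
        spacers = []
        for h in hosts:
            spacers.extend(hl.detect_crispr(h, taxon=taxa[h.id]))
        nested = hl.nested_pairings(hl.spacer_match(spacers, viral), [], [])
        models = [hl.markov_train(h.sequence, 2, host_id=h.id) for h in hosts]
        markov = [hl.markov_predict(v, models, taxa)[0] for v in viral]
        final = hl.consensus(nested, markov)
        nested_set = {(p.viral_id, p.host_taxon) for p in nested}
        markov_set = {(p.viral_id, p.host_taxon) for p in markov}
        final_set = {(p.viral_id, p.host_taxon) for p in final}
        assert final_set <= nested_set and final_set <= markov_set
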