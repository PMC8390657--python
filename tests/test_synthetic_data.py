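"""Ground-truth consistency and determinism of the community generator."""
import dataclasses

import numpy as np
import pytest

import soilvirome as sv
from soilvirome import synthetic_data as sd


def _community(**kw):
    defaults = dict(n_hosts=5, n_viral=10, n_rna_viral=2)
    defaults.update(kw)
    return sv.make_community(sv.CommunityConfig(**defaults), seed=11)


def test_determinism_byte_identical(tmp_path):
    """Same (config, seed) twice gives byte-identical artifacts."""
    for sub in ("a", "b"):
        sd.write_community(_community(), tmp_path / sub)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_spacers_are_substrings_of_targets():
    """10 viral, 5 hosts, 1 spacer/host: 5 planted spacers, each occurring
    verbatim (or reverse-complemented) in its target viral contig."""
    truth = _community()
    plants = [p for ps in truth.spacer_map.values() for p in ps]
    assert len(plants) == 5
    by_id = {v.id: v.sequence for v in truth.viral_contigs}
    for p in plants:
        tgt = by_id[p.target_viral_id]
        assert p.sequence in tgt or sd.revcomp(p.sequence) in tgt


def test_empty_viral_set():
    truth = _community(n_viral=0)
    assert truth.viral_contigs == [] and truth.spacer_map == {}


def test_gene_intervals_within_bounds():
    truth = _community()
    for cid, genes in truth.gene_map.items():
        L = len(next(v.sequence for v in truth.viral_contigs if v.id == cid))
        for g in genes:
            assert 0 <= g.start < g.end <= L


def test_prophages_planted_verbatim():
    truth = _community(lysogenic_fraction=1.0, prophage_fraction=1.0)
    assert truth.prophage_map
    hosts = {h.id: h.sequence for h in truth.host_genomes}
    viral = {v.id: v.sequence for v in truth.viral_contigs}
    for hid, intervals in truth.prophage_map.items():
        for start, end, vid in intervals:
            assert hosts[hid][start:end] == viral[vid]


def test_inconsistent_config_rejected():
    with pytest.raises(sd.ConfigError):
        sv.make_community(
            sv.CommunityConfig(viral_length=(30, 40), spacer_length=(26, 50)),
            seed=0)
    with pytest.raises(sd.ConfigError):
        sv.make_community(sv.CommunityConfig(n_hosts=-1), seed=0)


class TestSimulateReads:
    def test_error_rate_zero_means_no_mismatches(self, small_truth):
        reads = sd.simulate_reads(small_truth, "wet", 0.0, 100, seed=1)
        assert all(a.mismatch_count == 0 for a in reads.alignments)

    def test_zero_expression_yields_zero_reads(self, small_truth):
        truth = dataclasses.replace(small_truth)
        truth.expression = {cid: {c: 0.0 for c in e}
                            for cid, e in small_truth.expression.items()}
        vid = small_truth.viral_contigs[0].id
        truth.expression[vid] = {"wet": 2.0, "dry": 2.0}
        reads = sd.simulate_reads(truth, "wet", 0.0, 100, seed=1)
        assert set(reads.sources.values()) == {vid}

    def test_mismatch_count_matches_binomial_oracle(self):
        """error 0.02 x 100 nt: mean mismatches within 3 SE of 2.0."""
        truth = sv.make_community(
            sv.CommunityConfig(n_hosts=2, n_viral=8, n_rna_viral=0,
                               base_depth=14.0), seed=21)
        reads = sd.simulate_reads(truth, "wet", 0.02, 100, seed=2)
        n = reads.total_reads
        assert n > 5000
        mean = np.mean([a.mismatch_count for a in reads.alignments])
        se = np.sqrt(100 * 0.02 * 0.98 / n)
        assert abs(mean - 2.0) <= 3 * se

    def test_reads_match_reference_up_to_nm(self, small_truth):
        seqs = small_truth.all_sequences()
        reads = sd.simulate_reads(small_truth, "dry", 0.05, 80, seed=3)
        for a in reads.alignments[:200]:
            ref = seqs[a.contig_id][a.contig_start:a.contig_start + 80]
            diff = sum(x != y for x, y in zip(ref, reads.sequences[a.read_id]))
            assert diff == a.mismatch_count

    def test_read_conservation(self, small_truth):
        reads = sd.simulate_reads(small_truth, "wet", 0.0, 100, seed=4)
        assert len(reads.alignments) == len(reads.sequences) \
            == len(reads.sources)

    def test_unknown_condition_is_lookup_error(self, small_truth):
        with pytest.raises(KeyError, match="frozen"):
            sd.simulate_reads(small_truth, "frozen", 0.0, 100, seed=1)

    def test_invalid_error_rate(self, small_truth):
        with pytest.raises(sd.ConfigError):
            sd.simulate_reads(small_truth, "wet", 0.3, 100, seed=1)


class TestSimulatePsms:
    def test_no_decoys_means_zero_fdr(self):
        from soilvirome import proteo_filter

        psms = sd.simulate_psms(None, 200, 0, seed=5)
        assert proteo_filter.fdr_at(psms, np.inf, np.inf) == 0.0

    def test_fixed_seed_identical(self):
        a = sd.simulate_psms(None, 100, 100, seed=6)
        b = sd.simulate_psms(None, 100, 100, seed=6)
        assert a.equals(b)

    def test_decoys_come_from_null_component(self):
        psms = sd.simulate_psms(None, 100, 100, seed=7)
        assert not psms.loc[psms["is_decoy"], "is_true"].any()

    def test_separable_scores_admit_good_threshold(self):
        """Exhaustive threshold sweep: some score cut keeps FDR < 5% while
        retaining > 90% of the true-component targets."""
        psms = sd.simulate_psms(None, 1000, 1000, seed=8)
        targets = psms[~psms["is_decoy"]]
        n_true = int(targets["is_true"].sum())
        best_frac = 0.0
        for cut in np.sort(psms["score"].unique()):
            n_t = int((targets["score"] <= cut).sum())
            n_d = int((psms["is_decoy"] & (psms["score"] <= cut)).sum())
            if n_t and n_d / n_t < 0.05:
                kept_true = int((targets["is_true"]
                                 & (targets["score"] <= cut)).sum())
                best_frac = max(best_frac, kept_true / n_true)
        assert best_frac > 0.9

    def test_negative_counts_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.simulate_psms(None, -1, 0, seed=0)
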