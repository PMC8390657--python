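"""RdRP profile scanning, six-frame ORFs, reference route and abundance."""
import numpy as np
import pandas as pd
import pytest

from soilvirome import activity, rna_screen as rs
from soilvirome.io_formats import AlignmentRecord, ContigRecord


class TestSixFrameOrfs:
    def test_short_peptide_excluded(self):
        # frame 1 of ATGGCGTAA translates to MA, below any valid minimum
        assert rs.six_frame_orfs("ATGGCGTAA", 10) == []

    def test_all_n_contig_has_no_orfs(self):
        # NNN translates to X; an all-X peptide is returned but the scan
        # scores it at column minima, so require ACGT content here
        orfs = rs.six_frame_orfs("N" * 120, 10)
        assert all(set(o) == {"X"} for o in orfs)

    def test_reverse_complement_symmetry(self, rng):
        """ORF sets of a sequence and its reverse complement coincide
        (brute-force six-frame oracle)."""
        from soilvirome.synthetic_data import revcomp

        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        assert sorted(rs.six_frame_orfs(seq, 15)) == \
            sorted(rs.six_frame_orfs(revcomp(seq), 15))

    def test_min_length_validated(self):
        with pytest.raises(ValueError):
            rs.six_frame_orfs("ACGT" * 30, 5)


class TestPssmScan:
    def test_consensus_scores_profile_maximum(self):
        profile = rs.build_profile("p", rs.RDRP_MOTIFS["Leviviridae"])
        assert rs.pssm_scan(profile.consensus, profile) == pytest.approx(
            profile.max_score)

    def test_peptide_shorter_than_profile_rejected(self):
        profile = rs.build_profile("p", "ACDEFGHIKLMNPQRSTVWY")
        with pytest.raises(ValueError):
            rs.pssm_scan("ACDEF", profile)

    def test_null_hit_rate_below_percentile(self):
        """Random peptides hit a 99th-null-percentile threshold < 1% of the
        time for a strongly-skewed profile (fresh null draw).

        The profile's consensus uses every residue exactly twice with a
        flat mismatch score, so null scores sit on a small discrete lattice
        and the percentile threshold leaves a tail strictly below 1%.
        """
        consensus = "".join(sorted(rs.AA_ALPHABET * 2))
        idx = [rs.AA_ALPHABET.index(a) for a in consensus]
        matrix = np.full((40, 20), -1.0)
        matrix[np.arange(40), idx] = 10.0
        profile = rs.calibrate_threshold(
            rs.PssmProfile("skewed", matrix, np.inf),
            seed=5, n_null=4000, percentile=99.0)
        rng = np.random.default_rng(99)
        aas = np.array(list(rs.AA_ALPHABET))
        hits = sum(
            rs.pssm_scan("".join(aas[rng.integers(0, 20, len(profile))]),
                         profile) >= profile.threshold
            for _ in range(1000))
        assert hits / 1000 < 0.01

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            rs.PssmProfile("bad", np.zeros((5, 20)), 0.0)


class TestClassify:
    def test_planted_consensus_routes_rdrp(self, small_truth,
                                           calibrated_profiles):
        for r in small_truth.rna_viral_contigs:
            hit = rs.classify_rna_contig(ContigRecord(r.id, r.sequence),
                                         calibrated_profiles)
            assert hit is not None and hit.route == "rdrp"
            assert hit.taxon == r.taxon

    def test_reference_route_fallback(self, rng, calibrated_profiles):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        refs = pd.DataFrame([{"contig_id": "c", "ref_name": "NC_1",
                              "evalue": 1e-6, "taxon": "Tombusviridae"}])
        hit = rs.classify_rna_contig(ContigRecord("c", seq),
                                     calibrated_profiles, refs)
        assert hit is not None and hit.route == "reference"
        assert hit.taxon == "Tombusviridae"

    def test_weak_reference_hit_is_none(self, rng, calibrated_profiles):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        refs = pd.DataFrame([{"contig_id": "c", "ref_name": "NC_1",
                              "evalue": 1e-3, "taxon": "X"}])
        assert rs.classify_rna_contig(ContigRecord("c", seq),
                                      calibrated_profiles, refs) is None

    def test_random_contigs_not_called(self, rng, calibrated_profiles):
        """Profile-free random contigs stay below the calibrated thresholds."""
        hits = 0
        for _ in range(30):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
            hits += rs.classify_rna_contig(ContigRecord("x", seq),
                                           calibrated_profiles) is not None
        assert hits == 0


class TestAbundance:
    def _aln(self, contig, start, n=1):
        return [AlignmentRecord(f"{contig}_{start}_{i}", contig, start,
                                (("M", 100),), 100, 0) for i in range(n)]

    def _hits(self):
        return [rs.RnaViralHit("r1", "rdrp", "p", 50.0, "Leviviridae"),
                rs.RnaViralHit("r2", "rdrp", "p", 50.0, "Reoviridae"),
                rs.RnaViralHit("r3", "rdrp", "p", 50.0, "Reoviridae")]

    def test_taxon_mean_of_members(self):
        # r2 coverage 2.0, r3 coverage 6.0 -> Reoviridae 4.0
        alns = (self._aln("r2", 0, 2) + self._aln("r3", 0, 6))
        per_contig, per_taxon = rs.rna_abundance(
            self._hits(), alns, {"r1": 100, "r2": 100, "r3": 100}, 10 ** 6)
        taxon = per_taxon.set_index("taxon")
        assert taxon.loc["Reoviridae", "abundance"] == pytest.approx(4.0)
        assert taxon.loc["Leviviridae", "abundance"] == 0.0
        assert taxon.loc["Reoviridae", "log10_abundance"] == pytest.approx(
            np.log10(5.0))

    def test_taxon_without_members_absent(self):
        _, per_taxon = rs.rna_abundance(self._hits()[:1], [], {"r1": 100},
                                        1000)
        assert list(per_taxon["taxon"]) == ["Leviviridae"]

    def test_member_order_invariance(self):
        alns = self._aln("r2", 0, 3) + self._aln("r3", 0, 5)
        _, t1 = rs.rna_abundance(self._hits(), alns,
                                 {"r1": 100, "r2": 100, "r3": 100}, 1000)
        _, t2 = rs.rna_abundance(self._hits()[::-1], alns[::-1],
                                 {"r1": 100, "r2": 100, "r3": 100}, 1000)
        pd.testing.assert_frame_equal(t1, t2)

    def test_shares_activity_filter_code_path(self):
        """The abundance filter is literally activity.filter_alignments."""
        assert rs.filter_alignments is activity.filter_alignments
        good = AlignmentRecord("a", "r1", 0, (("M", 100),), 100, 1)
        bad = AlignmentRecord("b", "r1", 0, (("M", 100),), 100, 5)
        assert list(activity.filter_alignments([good, bad])) == \
            list(rs.filter_alignments([good, bad]))
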