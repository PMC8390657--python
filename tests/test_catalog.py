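"""Dereplication, AAI clustering and tetranucleotide composition."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilvirome import catalog
from soilvirome.io_formats import ContigRecord


class TestDereplicate:
    def test_exact_duplicates_collapse(self):
        out = catalog.dereplicate([ContigRecord("a", "ACGT"),
                                   ContigRecord("b", "ACGT")])
        assert [r.id for r in out] == ["a"]

    def test_substrings_removed(self):
        out = catalog.dereplicate([ContigRecord("long", "ACGTACGT"),
                                   ContigRecord("short", "GTAC")])
        assert [r.id for r in out] == ["long"]

    def test_empty(self):
        assert catalog.dereplicate([]) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=12),
                    min_size=0, max_size=8))
    def test_idempotent_and_substring_free(self, seqs):
        recs = [ContigRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        once = catalog.dereplicate(recs)
        twice = catalog.dereplicate(once)
        assert [(r.id, r.sequence) for r in once] == \
            [(r.id, r.sequence) for r in twice]
        for a, b in itertools.permutations(once, 2):
            assert a.sequence not in b.sequence


# conservative substitutions scoring positive under BLOSUM62 so the local
# alignment spans the full sequence while identity drops
_SUBS = {"L": "I", "I": "V", "K": "R", "R": "K", "D": "E", "E": "D",
         "S": "T", "T": "S", "F": "Y", "Y": "F", "V": "I", "Q": "E",
         "M": "L", "H": "Y", "N": "D", "W": "F"}


def _mutate(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = _SUBS[out[p]]
    return "".join(out)


class TestPairwiseAai:
    def test_identical_sets_are_100(self):
        prots = ["MKLVDQWSRTAGHKEFYPNC", "AAADDDKKKLLLWWWYYYCC"]
        assert catalog.pairwise_aai(prots, prots) == 100.0

    def test_mean_identity_over_rbh_pairs(self):
        """Two RBH pairs engineered at 80% and 60% identity average to 70%."""
        a1 = "MKLVDQWSRTMKLVDQWSRT"              # 20 aa
        b1 = _mutate(a1, [0, 4, 11, 15])         # 16/20 identical = 80%
        a2 = "HEFYKNDLSTQVMHEFYKNDLSTQV"         # 25 aa
        b2 = _mutate(a2, [0, 2, 4, 6, 8, 12, 14, 16, 18, 22])  # 15/25 = 60%
        aai = catalog.pairwise_aai([a1, a2], [b1, b2])
        assert aai == pytest.approx(70.0, abs=0.5)

    def test_empty_set_is_missing(self):
        assert catalog.pairwise_aai([], ["MKLV" * 6]) is None

    def test_no_qualifying_alignment_is_missing(self):
        # unrelated short peptides: no alignment reaches 20 aligned columns
        assert catalog.pairwise_aai(["MKWWWWHHH"], ["DDDDEEEGGG"]) is None


class TestSingleLinkage:
    @staticmethod
    def _matrix(ids, edges):
        import pandas as pd

        ids = list(ids)
        mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
        for i in ids:
            mat.loc[i, i] = 100.0
        for a, b, v in edges:
            mat.loc[a, b] = mat.loc[b, a] = v
        return mat

    def test_transitive_chain(self):
        mat = self._matrix("ABC", [("A", "B", 75), ("B", "C", 72),
                                   ("A", "C", 30)])
        clusters = catalog.single_linkage(mat, 70)
        assert clusters == {"A": "A", "B": "A", "C": "A"}

    def test_all_below_cutoff_are_singletons(self):
        mat = self._matrix("ABC", [("A", "B", 50), ("B", "C", 69.9)])
        assert catalog.single_linkage(mat, 70) == {
            "A": "A", "B": "B", "C": "C"}

    def test_empty_matrix(self):
        import pandas as pd

        assert catalog.single_linkage(pd.DataFrame()) == {}


class TestTetra:
    def test_homopolymer_z_near_zero(self):
        """E ~ O for a homopolymer, so |z(AAAA)| < 0.1 in closed form."""
        z = catalog.tetra_zscores("A" * 1000).z
        assert abs(z[0]) < 0.1

    def test_self_correlation_is_one(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        p = catalog.tetra_zscores(seq)
        assert catalog.profile_correlation(p, p) == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            catalog.tetra_zscores("ACGTN")

    def test_n_windows_skipped(self):
        # N-containing windows must not contribute counts
        z1 = catalog.tetra_zscores("ACGTACGTACGT" * 50)
        z2 = catalog.tetra_zscores("ACGTACGTACGT" * 50 + "N" * 3)
        assert np.allclose(z1.z, z2.z)


class TestRescue:
    def _profile(self, rng, table, cid, n=20000):
        from soilvirome.synthetic_data import _markov_sequence

        return catalog.tetra_zscores(_markov_sequence(rng, table, n), cid)

    def test_argmax_assignment(self, rng):
        from soilvirome.synthetic_data import _markov_table

        t1, t2 = _markov_table(rng, 1.0), _markov_table(rng, 1.0)
        orphan = self._profile(rng, t1, "o")
        members = [("cluster1", self._profile(rng, t1, "m1")),
                   ("cluster2", self._profile(rng, t2, "m2"))]
        assert catalog.rescue_assign(orphan, members) == "cluster1"

    def test_single_cluster_available(self, rng):
        from soilvirome.synthetic_data import _markov_table

        t = _markov_table(rng, 1.0)
        orphan = self._profile(rng, t, "o", 8000)
        assert catalog.rescue_assign(
            orphan, [("only", self._profile(rng, t, "m", 8000))]) == "only"

    def test_no_members_rejected(self, rng):
        with pytest.raises(ValueError):
            catalog.rescue_assign(
                catalog.tetra_zscores("ACGT" * 100, "o"), [])

    def test_same_source_recovered_in_95_percent_of_trials(self):
        """Contigs simulated from the same order-2 source join the
        same-source cluster in >= 95% of 100 seeded trials."""
        from soilvirome.synthetic_data import _markov_sequence, _markov_table

        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ta, tb = _markov_table(rng, 1.0), _markov_table(rng, 1.0)
            orphan = catalog.tetra_zscores(
                _markov_sequence(rng, ta, 12000), "o")
            members = [("A", catalog.tetra_zscores(
                            _markov_sequence(rng, ta, 12000), "a")),
                       ("B", catalog.tetra_zscores(
                            _markov_sequence(rng, tb, 12000), "b"))]
            hits += catalog.rescue_assign(orphan, members) == "A"
        assert hits >= 95
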