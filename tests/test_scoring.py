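"""Evidence merging and MS/PS/FS scoring."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from pinot.idmap import IdTriple
from pinot.qc import EvidenceUnit
from pinot.scoring import aggregate, canonical_pair, score_threshold

S = IdTriple("SEED1", "P10001", "500001")
X = IdTriple("PROT1", "P20001", "600001")
Y = IdTriple("PROT2", "P20002", "600002")
S2 = IdTriple("SEED2", "P10002", "500002")

triples = st.builds(
    IdTriple,
    st.sampled_from([f"G{i}" for i in range(6)]),
    st.sampled_from([f"P{10000 + i}" for i in range(6)]),
    st.sampled_from([str(100 + i) for i in range(6)]),
)


def unit(a=S, b=X, cat="Two Hybrid (2Hyb)", pmid="111", db="intact"):
    return EvidenceUnit(a, b, cat, pmid, db)


class TestCanonicalPair:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(triples, triples)
    def test_symmetry(self, a, b):
        assert canonical_pair(a, b) == canonical_pair(b, a)

    def test_self_pair_valid(self):
        assert canonical_pair(S, S) == (S, S)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(triples, triples, triples, triples)
    def test_key_equality_iff_unordered_equality(self, a, b, c, d):
        same_key = canonical_pair(a, b) == canonical_pair(c, d)
        same_set = {a, b} == {c, d}
        assert same_key == same_set


class TestAggregate:
    def test_single_unit_scores_two(self):
        (si,) = aggregate([unit()], {S})
        assert (si.ms, si.ps, si.fs) == (1, 1, 2)
        assert si.seed_triple == S and si.partner_triple == X

    def test_shared_category_multiple_codes_counts_once(self):
        # three two-hybrid variants converge on one category upstream
        units = [unit(pmid="111", db=db) for db in ("intact", "mint", "biogrid")]
        (si,) = aggregate(units, {S})
        assert (si.ms, si.ps, si.fs) == (1, 1, 2)

    def test_cross_provider_duplicates_count_once(self):
        units = [unit(db="intact"), unit(db="biogrid")]
        (si,) = aggregate(units, {S})
        assert (si.ms, si.ps, si.fs) == (1, 1, 2)

    def test_non_seed_pairs_excluded(self):
        units = [unit(), unit(a=X, b=Y)]
        out = aggregate(units, {S})
        assert len(out) == 1
        assert {out[0].seed_triple, out[0].partner_triple} == {S, X}

    def test_seed_seed_pair_single_row_earlier_seed_first(self):
        units = [unit(a=S2, b=S)]
        out = aggregate(units, {S, S2})
        assert len(out) == 1
        assert out[0].seed_triple == S  # SEED1 sorts before SEED2

    def test_orientation_restored_for_reversed_evidence(self):
        out = aggregate([unit(a=X, b=S)], {S})
        assert out[0].seed_triple == S

    def test_brute_force_oracle_on_random_units(self):
        """Merged (ms, ps) must match a naive nested-loop recount."""
        rng = random.Random(42)
        partners = [IdTriple(f"PROT{i}", f"P{20000 + i}", str(600000 + i))
                    for i in range(20)]
        cats = ["Two Hybrid (2Hyb)", "Affinity Purification (AP)",
                "Structure (Struct)", "MI:9999"]
        pmids = [str(30000000 + i) for i in range(15)]
        units = [
            unit(b=rng.choice(partners), cat=rng.choice(cats),
                 pmid=rng.choice(pmids), db=rng.choice(["intact", "mint"]))
            for _ in range(200)
        ]
        result = aggregate(units, {S})
        for si in result:
            want_cats = set()
            want_pmids = set()
            for u in units:  # independent recount
                if {u.triple_a, u.triple_b} == {si.seed_triple, si.partner_triple}:
                    want_cats.add(u.category)
                    want_pmids.add(u.pmid)
            assert si.ms == len(want_cats)
            assert si.ps == len(want_pmids)
            assert si.fs == si.ms + si.ps

    def test_monotonicity_adding_evidence_never_lowers_scores(self):
        units = [unit()]
        (before,) = aggregate(units, {S})
        (after,) = aggregate(units + [unit(cat="Structure (Struct)", pmid="222")],
                             {S})
        assert after.ms >= before.ms
        assert after.ps >= before.ps
        assert after.fs >= before.fs

    def test_duplicating_unit_list_is_idempotent(self):
        units = [unit(), unit(cat="Structure (Struct)"), unit(b=Y, pmid="333")]
        assert aggregate(units, {S}) == aggregate(units + units, {S})

    def test_output_sorted_by_names(self):
        units = [unit(b=Y), unit(b=X)]
        out = aggregate(units, {S})
        names = [(si.seed_triple.gene_name, si.partner_triple.gene_name)
                 for si in out]
        assert names == sorted(names)


class TestScoreComposition:
    def test_exhaustive_small_enumeration(self):
        """FS = MS + PS over all 1..3-method x 1..3-publication sets,
        with the floor of 2 attained exactly at (1 method, 1 publication)."""
        cats = ["A", "B", "C"]
        pmids = ["1", "2", "3"]
        seen_fs = []
        for nm, np_ in itertools.product(range(1, 4), range(1, 4)):
            units = [
                unit(cat=c, pmid=p)
                for c, p in itertools.product(cats[:nm], pmids[:np_])
            ]
            (si,) = aggregate(units, {S})
            assert si.ms == nm and si.ps == np_ and si.fs == nm + np_
            seen_fs.append(si.fs)
        assert min(seen_fs) == 2
        assert seen_fs.count(2) == 1  # only the (1, 1) cell


class TestThreshold:
    def _mixed(self):
        return aggregate(
            [unit(), unit(b=Y, cat="A", pmid="1"), unit(b=Y, cat="B", pmid="2")],
            {S},
        )

    def test_default_is_identity(self):
        interactions = self._mixed()
        assert score_threshold(interactions, 2) == interactions

    def test_three_removes_unreplicated_only(self):
        kept = score_threshold(self._mixed(), 3)
        assert all(si.fs >= 3 for si in kept)
        assert len(kept) == 1

    def test_above_max_gives_empty(self):
        assert score_threshold(self._mixed(), 10) == []

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            score_threshold([], 1)
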