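import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmskit import (
    RatioProfile,
    ScoringConfig,
    build_interactome,
    classify_protein,
    mean_nsaf,
    nsaf,
    rank_by_nsaf,
    spectral_ratio,
)

from conftest import make_table


def oracle_category(bait, ctrl, peptides, threshold=5.0, min_unique=2):
    """Independent re-statement of the selection rule, straight from its text:

    a replicate passes when the bait/control spectral-count ratio reaches the
    fold threshold (a protein absent from the control but present in the bait
    passes any threshold) and the bait run has at least ``min_unique`` unique
    peptides; all replicates passing = strict, all but one = relaxed.
    """
    n_pass = 0
    for b, c, p in zip(bait, ctrl, peptides):
        if c > 0:
            ratio_ok = b / c >= threshold
        else:
            ratio_ok = b > 0
        if ratio_ok and p >= min_unique:
            n_pass += 1
    n = len(bait)
    if n_pass == n:
        return "strict"
    if n >= 2 and n_pass == n - 1:
        return "relaxed"
    return "none"


class TestSpectralRatio:
    @pytest.mark.parametrize(
        "b,c,pc,expected",
        [
            (10, 2, 0, 5.0),
            (7, 0, 0, math.inf),
            (0, 0, 0, 0.0),
            (7, 0, 1, 8.0),
            (0, 5, 0, 0.0),
            (3, 3, 0.5, 1.0),
        ],
    )
    def test_values(self, b, c, pc, expected):
        assert spectral_ratio(b, c, pc) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            spectral_ratio(-1, 2)


class TestClassify:
    @pytest.mark.parametrize(
        "ratios,peptides,expected",
        [
            ((10, 8, 12), (3, 3, 2), "strict"),
            ((10, 8, 2), (3, 3, 3), "relaxed"),
            ((10, 2, 2), (3, 3, 3), "none"),
            ((math.inf, 6, 7), (2, 2, 2), "strict"),
            ((10, 8, 12), (3, 3, 1), "relaxed"),  # peptide gate drops one replicate
            ((10, 8, 12), (1, 1, 1), "none"),
        ],
    )
    def test_rule_table(self, ratios, peptides, expected):
        prof = RatioProfile("P1", ratios, n_pass=sum(r >= 5 for r in ratios))
        assert classify_protein(prof, peptides) == expected

    def test_mismatched_lengths_rejected(self):
        prof = RatioProfile("P1", (10.0, 8.0), n_pass=2)
        with pytest.raises(ValueError):
            classify_protein(prof, [3, 3, 3])

    def test_gt_comparator_excludes_boundary(self):
        prof = RatioProfile("P1", (5.0, 5.0, 5.0), n_pass=3)
        assert classify_protein(prof, (3, 3, 3)) == "strict"
        assert classify_protein(prof, (3, 3, 3), comparator="gt") == "none"


class TestNSAF:
    @pytest.mark.parametrize(
        "counts,lengths,expected",
        [
            ((10, 5), (100, 50), (50.0, 50.0)),
            ((10, 10), (100, 50), (100 / 3, 200 / 3)),
            ((7, 0), (33, 999), (100.0, 0.0)),
        ],
    )
    def test_hand_computed(self, counts, lengths, expected):
        np.testing.assert_allclose(nsaf(counts, lengths), expected, rtol=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            nsaf([0, 0], [10, 10])

    @given(
        counts=st.lists(st.integers(0, 1000), min_size=2, max_size=30),
        lengths_seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_sums_to_100_and_scale_invariant(self, counts, lengths_seed):
        if sum(counts) == 0:
            counts[0] = 1
        rng = np.random.default_rng(lengths_seed)
        lengths = rng.integers(50, 2000, size=len(counts))
        v = nsaf(counts, lengths)
        assert abs(v.sum() - 100.0) < 1e-9
        v3 = nsaf([3 * c for c in counts], lengths)
        np.testing.assert_allclose(v, v3, atol=1e-9)

    def test_mean_nsaf(self):
        assert mean_nsaf([2.0, 3.0, 4.0]) == 3.0
        assert mean_nsaf([0, 0, 0]) == 0.0
        assert mean_nsaf([1.5]) == 1.5
        with pytest.raises(ValueError):
            mean_nsaf([])


def random_small_table(rng, n_prot):
    spc = rng.integers(0, 15, size=(n_prot, 6))
    spc[rng.random(size=spc.shape) < 0.3] = 0
    pep = np.minimum(spc, rng.integers(0, 6, size=spc.shape))
    pep = np.where(spc > 0, np.maximum(pep, 1), 0)
    return make_table(spc, pep)


class TestBuildInteractome:
    def lengths_for(self, table):
        return {a: 100 + 10 * i for i, a in enumerate(table.accessions)}

    def test_planted_tenfold_protein_is_strict(self):
        spc = np.array([[20, 20, 20, 2, 2, 2], [5, 5, 5, 5, 5, 5], [3, 4, 3, 4, 3, 4]])
        t = make_table(spc)
        entries = build_interactome(t, self.lengths_for(t))
        cats = {e.accession: e.category for e in entries}
        assert cats == {"P1": "strict", "P2": "none", "P3": "none"}

    def test_identical_bait_and_control_yields_nothing(self):
        half = np.random.default_rng(0).integers(1, 20, size=(5, 3))
        t = make_table(np.hstack([half, half]))
        entries = build_interactome(t, self.lengths_for(t))
        assert all(e.category == "none" for e in entries)

    def test_two_of_three_passing_is_relaxed(self):
        spc = np.array([[20, 20, 3, 2, 2, 2], [5, 5, 5, 5, 5, 5]])
        t = make_table(spc)
        entries = build_interactome(t, self.lengths_for(t))
        assert entries[0].category == "relaxed"

    def test_matches_brute_force_oracle_on_small_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            t = random_small_table(rng, rng.integers(1, 7))
            if (t.spc[:, 3:].sum(axis=0) == 0).any() or (
                t.spc[:, :3].sum(axis=0) == 0
            ).any():
                continue  # NSAF undefined for an all-zero sample
            entries = build_interactome(t, self.lengths_for(t))
            for i, e in enumerate(entries):
                expected = oracle_category(
                    t.spc[i, :3], t.spc[i, 3:], t.unique_peptides[i, :3]
                )
                assert e.category == expected, (t.spc[i], t.unique_peptides[i])

    def test_threshold_monotonicity_and_disjointness(self):
        rng = np.random.default_rng(3)
        t = random_small_table(rng, 30)
        t.spc[:, :] += 1  # avoid all-zero samples
        lengths = self.lengths_for(t)
        prev_strict = None
        for thr in (2, 3, 5, 8, 13):
            entries = build_interactome(t, lengths, ScoringConfig(threshold=thr))
            strict = {e.accession for e in entries if e.category == "strict"}
            relaxed = {e.accession for e in entries if e.category == "relaxed"}
            assert not strict & relaxed
            if prev_strict is not None:
                assert strict <= prev_strict
            # strict at a higher threshold stays within strict+relaxed here
            prev_entries = build_interactome(
                t, lengths, ScoringConfig(threshold=thr)
            )
            prev_strict = strict

    def test_strict_at_t_subset_of_strict_union_relaxed_at_t(self):
        rng = np.random.default_rng(11)
        t = random_small_table(rng, 40)
        t.spc[:, :] += 1
        lengths = self.lengths_for(t)
        entries = build_interactome(t, lengths)
        strict = {e.accession for e in entries if e.category == "strict"}
        both = {e.accession for e in entries if e.category in ("strict", "relaxed")}
        assert strict <= both


class TestRankByNSAF:
    def test_descending_with_accession_tiebreak(self):
        from apmskit import InteractomeEntry

        def entry(acc, v):
            return InteractomeEntry(acc, acc, "strict", RatioProfile(acc, (9.0,), 1), v, 0.0, 3)

        ranked = rank_by_nsaf([entry("B", 1.0), entry("A", 1.0), entry("C", 2.0)])
        assert [e.accession for e in ranked] == ["C", "A", "B"]

    def test_empty(self):
        assert rank_by_nsaf([]) == []
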