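import dataclasses
import random

import pytest

from hairpinforge.folding import pair_table
from hairpinforge.hairpin_discovery import (
    DiscoveryParams,
    DuplexStats,
    HairpinCandidate,
    TranscriptLocus,
    annotate_candidate,
    compute_mfei,
    detect_features,
    discover,
    duplex_stats,
    excise_candidates,
    homology_discover,
    map_exact,
    merge_candidates,
    predict_star,
)
from hairpinforge.preprocess import UniqueTag
from hairpinforge.seqs import reverse_complement, to_rna


class TestMapExact:
    TRANSCRIPT = "AAGGCCAAUUGGCCAAUUACGUACGUACGUACGUACGGCCAAGGAAUU"

    def test_forward_hit(self):
        tag = UniqueTag(self.TRANSCRIPT[10:30], 2)
        loci = map_exact([tag], {"t1": self.TRANSCRIPT})
        assert loci[tag.sequence] == [TranscriptLocus("t1", "+", 10, 30)]

    def test_reverse_complement_hit(self):
        tag = UniqueTag(reverse_complement(self.TRANSCRIPT[10:30]), 2)
        loci = map_exact([tag], {"t1": self.TRANSCRIPT})
        assert loci[tag.sequence] == [TranscriptLocus("t1", "-", 10, 30)]

    def test_uniqueness_drop(self):
        unit = "ACGUGGCAUCGAUCGGAUCCA"
        repeat = unit * 300
        tag = UniqueTag(unit, 5)
        assert map_exact([tag], {"rep": repeat}, uniqueness=280) == {}
        assert len(map_exact([tag], {"rep": repeat}, uniqueness=500)[unit]) == 300

    def test_strand_symmetry(self):
        tags = [UniqueTag(self.TRANSCRIPT[5:25], 1)]
        rc_tags = [UniqueTag(reverse_complement(self.TRANSCRIPT[5:25]), 1)]
        fwd = map_exact(tags, {"t1": self.TRANSCRIPT})
        rev = map_exact(rc_tags, {"t1": self.TRANSCRIPT})
        fwd_loci = next(iter(fwd.values()))
        rev_loci = next(iter(rev.values()))
        assert [(l.start, l.end) for l in fwd_loci] == [(l.start, l.end) for l in rev_loci]
        assert {l.strand for l in fwd_loci} == {"+"}
        assert {l.strand for l in rev_loci} == {"-"}


class TestExciseCandidates:
    def test_tag_at_transcript_start(self):
        params = DiscoveryParams()
        locus = TranscriptLocus("t", "+", 0, 21)
        windows = excise_candidates(locus, "A" * 400, params)
        assert windows and all(w[0] == 0 for w in windows)

    def test_windows_respect_bounds(self):
        params = DiscoveryParams()
        transcript = "A" * 300
        locus = TranscriptLocus("t", "+", 150, 171)
        for start, end in excise_candidates(locus, transcript, params):
            assert 0 <= start < end <= 300
            assert end - start >= 50

    def test_planted_precursor_contained(self, small_sim):
        _, transcripts, truth, _ = small_sim
        rec = next(r for r in truth if not r.is_decoy and r.strand == "+")
        params = DiscoveryParams()
        locus = TranscriptLocus(rec.transcript_id, "+", rec.mature_start, rec.mature_end)
        windows = excise_candidates(locus, transcripts[rec.transcript_id], params)
        assert any(
            start <= rec.precursor_start and end >= rec.precursor_end
            for start, end in windows
        )

    def test_small_max_space_misses_planted(self, small_sim):
        _, transcripts, truth, _ = small_sim
        rec = next(r for r in truth if not r.is_decoy and r.strand == "+")
        params = DiscoveryParams(max_space=5, flank=5)
        locus = TranscriptLocus(rec.transcript_id, "+", rec.mature_start, rec.mature_end)
        windows = excise_candidates(locus, transcripts[rec.transcript_id], params)
        assert not any(
            start <= rec.precursor_start and end >= rec.precursor_end
            for start, end in windows
        )


class TestComputeMfei:
    def test_threshold_boundary(self):
        assert compute_mfei(-42.5, 100, 0.50) == pytest.approx(0.85)

    def test_unit_case(self):
        assert compute_mfei(-30, 100, 0.30) == pytest.approx(1.00)

    def test_random_tuples_against_oracle(self):
        rng = random.Random(1)
        for _ in range(100):
            dg = -rng.uniform(1, 120)
            length = rng.randint(50, 400)
            gc = rng.uniform(0.05, 0.95)
            oracle = (abs(dg) / length * 100.0) / (gc * 100.0)
            assert compute_mfei(dg, length, gc) == pytest.approx(oracle)

    def test_zero_gc_undefined(self):
        with pytest.raises(ValueError):
            compute_mfei(-30, 100, 0.0)


def oracle_duplex(structure, mature, star):
    """Independent pairing-table walk (stack parser + naive loops)."""
    stack, partner = [], {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    m0, m1 = mature
    s0, s1 = star
    paired = [i for i in range(m0, m1) if partner.get(i, -1) >= s0 and partner.get(i, -1) < s1]
    unpaired = (m1 - m0) - len(paired)
    bulges, asym, gm_total, gs_total = [], 0, 0, 0
    for a, b in zip(paired, paired[1:]):
        gm = b - a - 1
        gs = abs(partner[a] - partner[b]) - 1
        gm_total += gm
        gs_total += gs
        if gm > 0:
            bulges.append(("mature", gm))
        if gs > 0:
            bulges.append(("star", gs))
        if (gm or gs) and gm != gs:
            asym += 1
    return len(paired), unpaired, tuple(bulges), asym, abs(gm_total - gs_total)


class TestDuplexStats:
    def test_perfect_duplex(self):
        structure = "(" * 21 + "...." + ")" * 21
        stats = duplex_stats(structure, (0, 21), (25, 46))
        assert stats.paired == 21
        assert stats.mature_unpaired == 0
        assert stats.bulges == ()
        assert stats.asym_bulge_count == 0

    def test_single_asymmetric_bulge(self):
        # 10 pairs, 2-nt bulge on the mature arm, 10 more pairs
        structure = "(" * 10 + ".." + "(" * 10 + "...." + ")" * 20
        stats = duplex_stats(structure, (0, 22), (26, 46))
        assert stats.paired == 20
        assert stats.mature_unpaired == 2
        assert stats.bulges == (("mature", 2),)
        assert stats.asym_bulge_count == 1
        assert stats.total_asymmetry == 2

    def test_five_unpaired_fails_criterion(self):
        structure = "(" * 8 + "....." + "(" * 8 + "...." + ")" * 16
        stats = duplex_stats(structure, (0, 21), (25, 41))
        assert stats.mature_unpaired == 5

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError):
            duplex_stats("(((..)", (0, 3), (3, 6))

    def test_interval_bounds_checked(self):
        with pytest.raises(ValueError):
            duplex_stats("(...)", (0, 3), (4, 9))

    def test_oracle_equivalence_on_folded_structures(self, engine):
        rng = random.Random(3)
        checked = 0
        while checked < 100:
            arm = "".join(rng.choice("ACGU") for _ in range(25))
            mid = "".join(rng.choice("ACGU") for _ in range(rng.randint(4, 12)))
            seq = arm + mid + reverse_complement(arm)
            # random mutations to create bulges
            chars = list(seq)
            for _ in range(rng.randint(0, 6)):
                pos = rng.randrange(len(chars))
                chars[pos] = rng.choice("ACGU")
            structure, _ = engine.fold("".join(chars))
            mature = (2, 23)
            star = predict_star(pair_table(structure), mature)
            if star is None:
                continue
            stats = duplex_stats(structure, mature, star)
            expected = oracle_duplex(structure, mature, star)
            assert (
                stats.paired,
                stats.mature_unpaired,
                stats.bulges,
                stats.asym_bulge_count,
                stats.total_asymmetry,
            ) == expected
            checked += 1


def make_candidate(**overrides):
    base = dict(
        locus=TranscriptLocus("t", "+", 0, 100),
        sequence="G" * 100,
        dot_bracket="." * 100,
        dg=-50.0,
        gc=0.5,
        mfei=1.0,
        mature_w=(20, 41),
        star_w=(60, 83),
        mature_seq="G" * 21,
        support=10,
        engine="maxpair",
    )
    base.update(overrides)
    return HairpinCandidate(**base)


def good_stats(**overrides):
    base = dict(paired=20, mature_unpaired=1, bulges=(), asym_bulge_count=0,
                total_asymmetry=0, space=19)
    base.update(overrides)
    return DuplexStats(**base)


class TestAnnotateCandidate:
    def test_all_pass(self):
        verdict = annotate_candidate(make_candidate(), good_stats(), DiscoveryParams())
        assert verdict.accepted
        assert all(verdict.flags.values())

    def test_weak_energy_rejected(self):
        verdict = annotate_candidate(make_candidate(dg=-25.0), good_stats(), DiscoveryParams())
        assert not verdict.accepted
        assert not verdict.flags["energy"]
        assert sum(not v for v in verdict.flags.values()) == 1

    def test_mfei_exactly_085_passes(self):
        verdict = annotate_candidate(make_candidate(mfei=0.85), good_stats(), DiscoveryParams())
        assert verdict.flags["mfei"]

    def test_boundary_dg_exactly_minus_30_fails(self):
        # criterion is strictly "less than -30"
        verdict = annotate_candidate(make_candidate(dg=-30.0), good_stats(), DiscoveryParams())
        assert not verdict.flags["energy"]

    def test_low_support_rejected(self):
        verdict = annotate_candidate(make_candidate(support=1), good_stats(), DiscoveryParams())
        assert not verdict.flags["reads"]

    def test_five_mismatches_rejected(self):
        stats = good_stats(paired=16, mature_unpaired=5)
        verdict = annotate_candidate(make_candidate(), stats, DiscoveryParams())
        assert not verdict.flags["mature_mismatch"]

    def test_three_asym_bulges_rejected(self):
        stats = good_stats(bulges=(("mature", 1),) * 3, asym_bulge_count=3)
        verdict = annotate_candidate(make_candidate(), stats, DiscoveryParams())
        assert not verdict.flags["asym_bulges"]

    def test_monotone_under_tightening(self):
        """Tightening any threshold never turns a rejection into an acceptance."""
        rng = random.Random(8)
        defaults = DiscoveryParams()
        tighter = dict(
            min_reads=defaults.min_reads + 2,
            max_dg=defaults.max_dg - 10,
            max_mature_mismatch=defaults.max_mature_mismatch - 2,
            max_asym_bulges=defaults.max_asym_bulges - 1,
            min_mfei=defaults.min_mfei + 0.3,
            min_mature_pair=defaults.min_mature_pair + 2,
            max_mature_bulge=defaults.max_mature_bulge - 1,
            max_duplex_asymmetry=defaults.max_duplex_asymmetry - 2,
        )
        for _ in range(200):
            cand = make_candidate(
                dg=-rng.uniform(10, 90),
                mfei=rng.uniform(0.2, 2.0),
                support=rng.randint(0, 6),
            )
            stats = good_stats(
                paired=rng.randint(10, 21),
                mature_unpaired=rng.randint(0, 8),
                bulges=tuple(("mature", rng.randint(1, 5)) for _ in range(rng.randint(0, 3))),
                asym_bulge_count=rng.randint(0, 3),
                total_asymmetry=rng.randint(0, 7),
                space=rng.randint(0, 500),
            )
            loose = annotate_candidate(cand, stats, defaults)
            for name, value in tighter.items():
                params = dataclasses.replace(defaults, **{name: value})
                tight = annotate_candidate(cand, stats, params)
                assert not (tight.accepted and not loose.accepted), name


@pytest.fixture(scope="module")
def discovery(small_sim, small_sim_tags, engine):
    _, transcripts, _, _ = small_sim
    candidates = discover(small_sim_tags, transcripts, DiscoveryParams(), engine)
    accepted = [c for c in candidates if c.verdict.accepted]
    return candidates, accepted


class TestDiscoveryOnSimulation:
    def test_planted_recovered(self, small_sim, discovery):
        _, _, truth, _ = small_sim
        _, accepted = discovery
        planted = [r for r in truth if not r.is_decoy]
        recovered = 0
        for rec in planted:
            if any(
                c.locus.transcript_id == rec.transcript_id
                and c.locus.strand == rec.strand
                and abs(c.mature_fwd[0] - rec.mature_start) <= 3
                and abs(c.mature_fwd[1] - rec.mature_end) <= 3
                for c in accepted
            ):
                recovered += 1
        assert recovered / len(planted) >= 0.9

    def test_no_decoys_accepted(self, small_sim, discovery):
        _, _, truth, _ = small_sim
        _, accepted = discovery
        decoys = [r for r in truth if r.is_decoy]
        for rec in decoys:
            hits = [
                c
                for c in accepted
                if c.locus.transcript_id == rec.transcript_id
                and c.mature_fwd[0] < rec.precursor_end
                and c.mature_fwd[1] > rec.precursor_start
            ]
            assert hits == [], rec.name

    def test_decoys_fail_at_least_one_criterion(self, small_sim, discovery):
        _, _, truth, _ = small_sim
        candidates, _ = discovery
        decoy_transcripts = {r.transcript_id for r in truth if r.is_decoy}
        evaluated = [c for c in candidates if c.locus.transcript_id in decoy_transcripts]
        assert evaluated, "decoy loci were never evaluated"
        for c in evaluated:
            assert not c.verdict.accepted
            assert any(not v for v in c.verdict.flags.values())

    def test_features_detected(self, small_sim, discovery):
        config, _, truth, _ = small_sim
        _, accepted = discovery
        precursors = merge_candidates(accepted)
        features = detect_features(precursors)
        assert len(features.clusters) == config.n_clusters
        assert len(features.multi_mature_precursors) == config.n_multi_mature
        assert len(features.antisense_pairs) == config.n_antisense

    def test_detect_features_requires_input(self):
        with pytest.raises(ValueError):
            detect_features([])


class TestHomologyMode:
    def test_known_mature_recovers_planted_hairpin(self, small_sim, engine):
        _, transcripts, truth, _ = small_sim
        rec = next(r for r in truth if not r.is_decoy and r.strand == "+")
        candidates = homology_discover(
            {"known-mir": to_rna(rec.mature_seq)},
            {rec.transcript_id: transcripts[rec.transcript_id]},
            DiscoveryParams(),
            engine,
        )
        accepted = [c for c in candidates if c.verdict.accepted]
        assert any(
            abs(c.mature_fwd[0] - rec.mature_start) <= 3 for c in accepted
        )
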