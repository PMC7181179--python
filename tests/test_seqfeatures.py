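"""Sequence-feature battery: worked examples, brute-force oracles,
and purity/consistency properties."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from conftest import make_random_cds
from gcsplice._codons import AA_TO_CODONS, CODON_TO_AA, STOP_CODONS
from gcsplice.folding import available_backends, mfe
from gcsplice.pssm import ARE_PSSM, POLY_A_PSSM, PSSM, scan_pssm
from gcsplice.seqdesign import CodingSequence, design_panel
from gcsplice.seqfeatures import (
    FeatureConfig,
    are_top_score,
    cai,
    count_iupac_motif,
    cpg_count,
    feature_table,
    folding_energy_start,
    gc3,
    gc4,
    regional_gc3,
    tai,
)

FOURFOLD = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}


def oracle_gc3(cds: str) -> float:
    hits = total = 0
    for i in range(2, len(cds), 3):
        if cds[i] in "ACGT":
            total += 1
            hits += cds[i] in "GC"
    return hits / total


def oracle_gc4(cds: str) -> float:
    hits = total = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon[:2] in FOURFOLD and codon[2] in "ACGT":
            total += 1
            hits += codon[2] in "GC"
    return hits / total if total else math.nan


def oracle_scan(seq: str, pssm: PSSM, p_threshold: float) -> tuple[int, float]:
    """Brute force: per-offset loop scoring + exhaustive null enumeration."""
    lo = pssm.log_odds
    L = len(pssm)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    # exhaustive null distribution over all 4^L words
    word_scores = []
    for word in itertools.product("ACGT", repeat=L):
        s = sum(lo[i, idx[b]] for i, b in enumerate(word))
        p = np.prod([pssm.background[idx[b]] for b in word])
        word_scores.append((s, p))

    def pvalue(score):
        return sum(p for s, p in word_scores if s >= score - 1e-9)

    count, best = 0, -np.inf
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if any(b not in idx for b in window):
            continue
        s = sum(lo[i, idx[b]] for i, b in enumerate(window))
        best = max(best, s)
        if pvalue(s) <= p_threshold:
            count += 1
    return count, best


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [("ATGGGC", 1.0), ("ATGGGA", 0.5)])
    def test_gc3_examples(self, seq, expected):
        assert gc3(seq) == expected

    @pytest.mark.parametrize("seq,expected", [("ATGGGC", 1.0), ("AAAGGT", 0.0)])
    def test_gc4_examples(self, seq, expected):
        assert gc4(seq) == expected

    def test_gc4_undefined_without_fourfold_codons(self):
        assert math.isnan(gc4("ATGTGGTAA"))

    def test_frame_check(self):
        with pytest.raises(ValueError):
            gc3("ATGC")

    def test_against_oracles(self, rng):
        for _ in range(50):
            cds = make_random_cds(rng, 240)
            assert gc3(cds) == oracle_gc3(cds)
            assert gc4(cds) == oracle_gc4(cds)

    def test_gc4_equals_gc3_restricted_to_fourfold_codons(self, rng):
        cds = make_random_cds(rng, 500)
        fourfold_only = "".join(
            cds[i : i + 3]
            for i in range(0, len(cds), 3)
            if cds[i : i + 2] in FOURFOLD
        )
        assert gc4(cds) == pytest.approx(gc3(fourfold_only))


class TestRegionalGC3:
    def test_full_range_matches_whole_gene(self, rng):
        cds = make_random_cds(rng, 100)
        assert regional_gc3(cds, 1, len(cds)) == gc3(cds)

    def test_codon_range_example(self):
        assert regional_gc3("ATGGGAGGC", 4, 9) == 0.5

    def test_halves_recombine_to_whole(self, rng):
        cds = make_random_cds(rng, 240)  # 720 nt
        first, second = regional_gc3(cds, 1, 360), regional_gc3(cds, 361, 720)
        assert (first * 120 + second * 120) / 240 == pytest.approx(gc3(cds))

    def test_unaligned_range_rejected(self):
        with pytest.raises(ValueError, match="codon-aligned"):
            regional_gc3("ATGGGAGGC", 2, 7)


class TestCpG:
    @pytest.mark.parametrize("seq,expected", [("CGCG", 2), ("GC", 0), ("CCGG", 1)])
    def test_examples(self, seq, expected):
        assert cpg_count(seq) == expected

    def test_against_window_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        brute = sum(seq[i : i + 2] == "CG" for i in range(len(seq) - 1))
        assert cpg_count(seq) == brute


class TestFolding:
    @pytest.mark.parametrize("backend", available_backends())
    def test_unstructured_window_scores_zero(self, backend):
        cs = CodingSequence("a", "A" * 120, context5="AAAA")
        assert folding_energy_start(cs, backend=backend) == 0.0

    @pytest.mark.parametrize("backend", available_backends())
    def test_hairpin_is_negative(self, backend):
        stem = "GCGCGCGCGCGCGCG"
        comp = stem.translate(str.maketrans("GC", "CG"))[::-1]
        hairpin = stem + "AAAA" + comp
        cds = (hairpin + "A" * (38 - len(hairpin)))
        cs = CodingSequence("h", cds + "AA" * 0, context5="AAAA")
        assert folding_energy_start(cs, backend=backend) < 0

    @pytest.mark.parametrize("backend", available_backends())
    def test_extending_a_hairpin_lowers_mfe(self, backend):
        short = "GGGGGAAAACCCCC" + "A" * 20
        longer = "GGGGGGAAAACCCCCC" + "A" * 18
        assert mfe(longer, backend=backend) < mfe(short, backend=backend)

    def test_missing_context_rejected(self):
        with pytest.raises(ValueError, match="5' context"):
            folding_energy_start(CodingSequence("x", "ATG" * 20, context5="AA"))


class TestAdaptationIndices:
    def test_all_optimal_codons_score_one(self):
        weights = {c: 1.0 for c in CODON_TO_AA}
        cds = make_random_cds(np.random.default_rng(0), 50)
        assert cai(cds, weights) == pytest.approx(1.0)
        assert tai(cds, weights) == pytest.approx(1.0)

    def test_single_degenerate_codon_returns_its_weight(self):
        weights = {c: 1.0 for c in CODON_TO_AA}
        weights["GGA"] = 0.37
        # ATG and TGG carry no synonymous signal; GGA is the only scorer
        assert cai("ATGTGGGGA", weights) == pytest.approx(0.37)

    def test_geometric_mean_oracle(self, rng):
        weights = {c: float(w) for c, w in zip(sorted(CODON_TO_AA), rng.uniform(0.05, 1.0, 61))}
        cds = make_random_cds(rng, 200)
        logs = [
            math.log(weights[cds[i : i + 3]])
            for i in range(0, len(cds), 3)
            if cds[i : i + 3] not in STOP_CODONS
            and len(AA_TO_CODONS[CODON_TO_AA[cds[i : i + 3]]]) > 1
        ]
        assert cai(cds, weights) == pytest.approx(math.exp(np.mean(logs)))

    def test_missing_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            cai("ATGGGA", {"ATG": 1.0})

    def test_bounds(self, rng):
        for _ in range(10):
            cds = make_random_cds(rng, 100)
            assert 0 < cai(cds) <= 1
            assert 0 < tai(cds) <= 1


class TestPSSMScan:
    def test_single_position_matrix(self):
        p = PSSM(matrix=((1, 0, 0, 0),))
        count, best = scan_pssm("AAA", p, p_threshold=0.5)
        assert count == 3
        assert best == pytest.approx(p.max_score)

    def test_dinucleotide_matrix_matches_enumeration(self):
        p = PSSM(matrix=((3, 1, 1, 1), (1, 1, 1, 5)))
        seq = "".join("".join(x) for x in itertools.product("ACGT", repeat=2))
        for thr in (1e-4, 0.05, 0.2, 1.0):
            assert scan_pssm(seq, p, thr) == pytest.approx(oracle_scan(seq, p, thr))

    def test_poly_a_matrix_matches_bruteforce(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        for thr in (1e-4, 0.01):
            got = scan_pssm(seq, POLY_A_PSSM, thr)
            want = oracle_scan(seq, POLY_A_PSSM, thr)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1])

    def test_count_invariant_to_nonmatching_flanks(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        count, _ = scan_pssm(seq, POLY_A_PSSM, 1e-2)
        padded, _ = scan_pssm("G" * 20 + seq + "G" * 20, POLY_A_PSSM, 1e-2)
        assert padded == count

    def test_ambiguous_bases_match_nothing(self):
        p = PSSM(matrix=((1, 0, 0, 0),))
        count, _ = scan_pssm("ANA", p, p_threshold=0.5)
        assert count == 2

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="motif length"):
            scan_pssm("AC", POLY_A_PSSM, 1e-4)


class TestIUPACMotifs:
    @pytest.mark.parametrize(
        "seq,pattern,expected",
        [
            ("AGGTCATT", "RSGTNNHT", 1),
            ("TTTTTTTT", "RSGTNNHT", 0),
            ("AT" * 9, "AT" * 9, 1),
            ("AT" * 10, "AT" * 9, 2),  # overlapping occurrences count (offsets 0 and 2)
        ],
    )
    def test_examples(self, seq, pattern, expected):
        assert count_iupac_motif(seq, pattern) == expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            count_iupac_motif("ACGT", "AXGT")

    def test_are_top_score(self, rng):
        assert are_top_score("GGGATTTAGGG") == pytest.approx(ARE_PSSM.max_score)
        assert are_top_score("G" * 20) == pytest.approx(ARE_PSSM.min_score)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        _, best = scan_pssm(seq, ARE_PSSM, 1.0)
        assert are_top_score(seq) == pytest.approx(best)


class TestFeatureTable:
    def test_rows_match_single_feature_calls(self, rng):
        panel = [
            CodingSequence(f"v{i}", make_random_cds(rng, 240), context5="GCCACC")
            for i in range(2)
        ]
        cfg = FeatureConfig(folding_backend="basic")
        table = feature_table(panel, cfg)
        assert len(table) == 2
        for _, row in table.iterrows():
            var = next(v for v in panel if v.id == row["id"])
            assert row["gc3"] == gc3(var.cds)
            assert row["gc4"] == pytest.approx(gc4(var.cds), nan_ok=True)
            assert row["cpg"] == cpg_count(var.cds)
            assert row["cai"] == pytest.approx(cai(var.cds, cfg.cai_weights))
            assert row["gc3_first_half"] == regional_gc3(var.cds, 1, 360)
            assert row["gc3_second_half"] == regional_gc3(var.cds, 361, len(var.cds))

    def test_determinism(self, rng):
        panel = [CodingSequence("v", make_random_cds(rng, 120), context5="ACGTAC")]
        cfg = FeatureConfig(folding_backend="basic")
        a = feature_table(panel, cfg)
        b = feature_table(panel, cfg)
        assert a.equals(b)

    def test_gc3_ranks_follow_design_targets(self, template_240):
        targets = [0.25, 0.45, 0.65, 0.85]
        panel = design_panel(template_240, targets, seed=3)
        table = feature_table(panel, FeatureConfig(folding_backend="basic"))
        assert list(table["gc3"]) == sorted(table["gc3"])
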