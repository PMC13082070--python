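"""Charge patterning, hydropathy, complexity, distances, motif scanning."""

import itertools
import math

import numpy as np
import pytest

from idiomkit import metrics as m
from idiomkit.fim import CANONICAL_AA
from idiomkit.metrics import (
    MotifPattern,
    composition_enrichment,
    fcr,
    kappa,
    load_motif_patterns,
    metric_table,
    motif_cooccurrence,
    motif_scan,
    ncpr_profile,
    ptm_density,
    seg_complexity,
    shd,
    wasserstein1,
)


class TestFcrNcpr:
    @pytest.mark.parametrize(
        "seq,expected", [("EKEK", 1.0), ("GGGG", 0.0), ("EKGGG", 0.4)]
    )
    def test_fcr_counts(self, seq, expected):
        assert fcr(seq) == pytest.approx(expected, abs=1e-12)

    def test_ncpr_homopolymers(self):
        assert np.allclose(ncpr_profile("KKKKK", 5), 1.0)
        assert np.allclose(ncpr_profile("EEEEE", 5), -1.0)

    def test_ncpr_windowed_mean_oracle(self):
        seq = "EKEKEK"
        w = 2
        charges = {"E": -1, "K": 1}
        got = ncpr_profile(seq, w)
        for i in range(len(seq)):
            lo = max(0, i - (w - 1) // 2)
            hi = min(len(seq), i + w // 2 + 1)
            expected = np.mean([charges[c] for c in seq[lo:hi]])
            assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_histidine_neutral(self):
        assert fcr("HHHH") == 0.0


class TestKappa:
    def test_fully_segregated_is_one(self):
        assert kappa("E" * 25 + "K" * 25) == pytest.approx(1.0, abs=1e-12)

    def test_strict_alternation_is_near_zero(self):
        assert kappa("EK" * 25) < 0.1

    def test_exhaustive_enumeration_never_exceeds_one(self):
        # all placements of 3 E and 3 K in a 12-mer (rest G): kappa <= 1 and
        # the most segregated arrangement comes out on top
        vals = {}
        for pos_sites in itertools.combinations(range(12), 3):
            rest = [i for i in range(12) if i not in pos_sites]
            for neg_sites in itertools.combinations(rest, 3):
                s = ["G"] * 12
                for i in pos_sites:
                    s[i] = "K"
                for i in neg_sites:
                    s[i] = "E"
                seq = "".join(s)
                vals[seq] = kappa(seq)
        assert max(vals.values()) <= 1.0 + 1e-12
        best = max(vals, key=vals.get)
        # winner has contiguous charge blocks
        assert "KKK" in best and "EEE" in best

    def test_reversal_and_charge_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            seq = "".join(rng.choice(list("EKGSA"), size=40))
            if np.isnan(kappa(seq)):
                continue
            swapped = seq.translate(str.maketrans("EK", "KE"))
            assert kappa(seq) == pytest.approx(kappa(seq[::-1]), abs=1e-9)
            assert kappa(seq) == pytest.approx(kappa(swapped), abs=1e-9)

    def test_range_where_defined(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = "".join(rng.choice(list(CANONICAL_AA), size=60))
            k = kappa(seq)
            if not math.isnan(k):
                assert 0.0 <= k <= 1.0 + 1e-9

    def test_undefined_cases(self):
        assert math.isnan(kappa("GGGGGGGG"))
        with pytest.raises(ValueError):
            kappa("EKG")


class TestShd:
    def test_two_residue_exact(self):
        table = m.HYDROPATHY_SCALES["kd_unit"]
        assert shd("AW") == pytest.approx((table["A"] + table["W"]) / 2, abs=1e-12)

    def test_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        table = m.HYDROPATHY_SCALES["kd_unit"]
        for _ in range(100):
            seq = "".join(rng.choice(list(CANONICAL_AA), size=rng.integers(2, 40)))
            h = [table[c] for c in seq]
            n = len(seq)
            expected = sum(
                (h[i] + h[j]) / (j - i) for i in range(n) for j in range(i + 1, n)
            ) / n
            assert shd(seq) == pytest.approx(expected, abs=1e-9)

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            shd("A")


class TestSegComplexity:
    def test_homopolymer_zero(self):
        assert seg_complexity("A" * 30) == 0.0

    def test_all_distinct_window(self):
        assert seg_complexity("ACDEFGHIKLMN", window=12) == pytest.approx(
            math.log2(12), abs=1e-12
        )

    def test_two_symbol_balanced(self):
        assert seg_complexity("AAAAAAGGGGGG", window=12) == pytest.approx(1.0, abs=1e-12)

    def test_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            seq = "".join(rng.choice(list("ASGPE"), size=rng.integers(5, 50)))
            w = 12
            spans = (
                [seq]
                if len(seq) < w
                else [seq[i : i + w] for i in range(len(seq) - w + 1)]
            )
            ents = []
            for s in spans:
                ps = [s.count(c) / len(s) for c in set(s)]
                ents.append(-sum(p * math.log2(p) for p in ps))
            assert seg_complexity(seq, w) == pytest.approx(np.mean(ents), abs=1e-9)


class TestCompositionEnrichment:
    def test_self_comparison_is_unity(self):
        seqs = ["ACDEFG", "KKPQRS"]
        ratios = composition_enrichment(seqs, seqs)
        present = [a for a in CANONICAL_AA if a in "".join(seqs)]
        assert np.allclose(ratios[present], 1.0)

    def test_pure_proline_vs_uniform(self):
        ratios = composition_enrichment(["P" * 50], [CANONICAL_AA * 3])
        assert ratios["P"] == pytest.approx(20.0, abs=1e-12)
        others = [a for a in CANONICAL_AA if a != "P"]
        assert np.allclose(ratios[others], 0.0)

    def test_pooled_not_per_sequence(self):
        # one long A-rich sequence must dominate a short one: pooled counts
        seqs = ["A" * 99 + "G", "G"]
        ref = [CANONICAL_AA]
        joined = "".join(seqs)
        expected_a = (joined.count("A") / len(joined)) / (1 / 20)
        assert composition_enrichment(seqs, ref)["A"] == pytest.approx(
            expected_a, abs=1e-12
        )

    def test_absent_in_reference_flagged_infinite(self):
        ratios = composition_enrichment(["W"], ["ACDE"])
        assert np.isinf(ratios["W"])


class TestWasserstein:
    def test_identical_samples_zero(self):
        x = [1.0, 2.0, 5.0]
        assert wasserstein1(x, x, normalizer=1.0) == 0.0

    def test_point_mass_translation(self):
        assert wasserstein1([0.0] * 10, [3.5] * 10, normalizer=1.0) == pytest.approx(3.5)

    def test_sorted_coupling_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=100)
            b = rng.normal(1.0, 2.0, size=100)
            expected = np.abs(np.sort(a) - np.sort(b)).mean()
            assert wasserstein1(a, b, normalizer=1.0) == pytest.approx(expected, abs=1e-9)

    def test_default_normalizer_is_reference_sd(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        b = rng.normal(2.0, 3.0, size=200)
        assert wasserstein1(a, b) == pytest.approx(
            wasserstein1(a, b, normalizer=1.0) / b.std(), abs=1e-12
        )

    def test_symmetry_unnormalized(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=50), rng.normal(size=80)
        assert wasserstein1(a, b, 1.0) == pytest.approx(wasserstein1(b, a, 1.0), abs=1e-12)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            wasserstein1([1.0, 2.0], [5.0, 5.0])


RGG = MotifPattern("rgg", "RGG", "RNA")


class TestMotifs:
    def test_adjacent_matches_counted(self):
        hits = motif_scan("RGGRGG", [RGG])
        assert [(h[1], h[2]) for h in hits] == [(1, 3), (4, 6)]

    def test_overlapping_matches_counted(self):
        pat = MotifPattern("aa", "AA", "MOD")
        hits = motif_scan("AAAA", [pat])
        assert [(h[1], h[2]) for h in hits] == [(1, 2), (2, 3), (3, 4)]

    def test_basic_nls_needs_basic_residues(self):
        patterns = [p for p in load_motif_patterns() if p.tag == "NLS"]
        assert motif_scan("ASGPSTQMNDE" * 5, patterns) == []

    def test_planted_motifs_recovered_exactly(self):
        from idiomkit.fixtures import plant_motifs

        seqs, manifests = plant_motifs(30, 60, "RGG", rate=2.0, seed=8)
        for s, manifest in zip(seqs, manifests):
            hits = [start for _, start, _ in motif_scan(s, [RGG])]
            assert hits == [start for _, start in manifest]

    def test_ptm_density_of_planted_sites(self):
        from idiomkit.fixtures import plant_motifs

        pat = MotifPattern("spm", "SPK", "MOD")
        seqs, manifests = plant_motifs(300, 90, "SPK", rate=3.0, seed=9)
        expected = np.mean([len(mf) for mf in manifests])
        assert ptm_density(seqs, [pat]) == pytest.approx(expected, abs=1e-12)
        lam = 3.0
        se = math.sqrt(lam / len(seqs))
        # planting is Poisson(3) truncated by slot count; allow 3 SE
        assert abs(ptm_density(seqs, [pat]) - lam) < 3 * se + 0.35

    def test_cooccurrence_boundaries(self):
        seq1 = "RGG" + "A" * 7 + "RGG" + "A" * 47  # starts 1 and 11: within 30
        assert motif_cooccurrence(seq1, [RGG], span=30) == (True, True)
        seq2 = "RGG" + "A" * 28 + "RGG" + "A" * 26  # starts 1 and 32: 31 apart
        assert motif_cooccurrence(seq2, [RGG], span=30) == (True, False)
        seq3 = "RGG" + "A" * 57
        assert motif_cooccurrence(seq3, [RGG], span=30) == (True, False)

    def test_default_pattern_table_loads(self):
        pats = load_motif_patterns()
        tags = {p.tag for p in pats}
        assert tags == {"NLS", "MOD", "RNA"}
        assert len({p.name for p in pats}) == len(pats)


class TestMetricTable:
    def test_frequencies_sum_to_one(self):
        from idiomkit.fixtures import CorpusSpec, synth_idr_corpus

        seqs = synth_idr_corpus(CorpusSpec(n_sequences=20, seed=3))
        table = metric_table(seqs)
        fcols = [c for c in table.columns if c.startswith("f_")]
        sums = table[fcols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert ((table["fcr"] >= 0) & (table["fcr"] <= 1)).all()
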