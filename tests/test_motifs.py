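"""PWM scanning (both strands, threshold rule) and promoter enrichment."""

import numpy as np
import pandas as pd
import pytest

from k9me import motifs
from k9me.expression import GeneSet
from k9me.genomic_io import GeneModel, GenomeSequence, Interval, PWMatrix


def scan_oracle(genome, pwm, min_score):
    """Exhaustive per-position, per-strand scoring, independent of the
    vectorized implementation."""
    comp = str.maketrans("ACGT", "TGCA")
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    thresh = min(min_score, pwm.max_score)
    L = pwm.length
    hits = []
    for chrom, seq in genome.sequences.items():
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            if "N" in window:
                continue
            fwd = sum(pwm.weights[idx[b], i] for i, b in enumerate(window))
            if fwd >= thresh:
                hits.append((chrom, start, "+", fwd))
            rc = window.translate(comp)[::-1]
            rev = sum(pwm.weights[idx[b], i] for i, b in enumerate(rc))
            if rev >= thresh:
                hits.append((chrom, start, "-", rev))
    return sorted(hits)


def as_tuples(hits):
    return sorted((h.chrom, h.start, h.strand, h.score) for h in hits)


class TestPromoterWindows:
    def _gene(self, strand, tss):
        if strand == "+":
            return GeneModel("g", "c1", "+", ((tss, tss + 200),))
        return GeneModel("g", "c1", "-", ((tss - 200, tss),))

    def test_plus_strand_default_window(self):
        out = motifs.promoter_windows([self._gene("+", 10_000)])
        assert (out["g"].start, out["g"].end) == (8_500, 10_500)

    def test_minus_strand_mirror(self):
        out = motifs.promoter_windows([self._gene("-", 10_000)])
        assert (out["g"].start, out["g"].end) == (9_500, 11_500)

    def test_clipping_at_chromosome_start(self):
        out = motifs.promoter_windows([self._gene("+", 1_000)])
        assert (out["g"].start, out["g"].end) == (0, 1_500)

    def test_accessibility_promoter_definition(self):
        out = motifs.promoter_windows(
            [self._gene("+", 10_000)], upstream=1_000, downstream=100
        )
        assert (out["g"].start, out["g"].end) == (9_000, 10_100)


class TestScanPWM:
    def _pwm(self):
        w = np.zeros((4, 2))
        w[0, 0] = 5.0  # A at position 0
        w[1, 1] = 5.0  # C at position 1
        return PWMatrix(["X"], w)

    def test_forward_hit(self):
        hits = motifs.scan_pwm(GenomeSequence({"c1": "AC"}), self._pwm())
        assert as_tuples(hits) == [("c1", 0, "+", 10.0)]

    def test_reverse_hit_reported_on_forward_coordinates(self):
        hits = motifs.scan_pwm(GenomeSequence({"c1": "GT"}), self._pwm())
        assert as_tuples(hits) == [("c1", 0, "-", 10.0)]

    def test_low_max_score_requires_perfect_match(self):
        w = np.zeros((4, 2))
        w[0, 0] = 3.0
        w[1, 1] = 3.0  # max score 6 < 10
        pwm = PWMatrix(["X"], w)
        hits = motifs.scan_pwm(GenomeSequence({"c1": "ACAAAG"}), pwm, min_score=10)
        assert as_tuples(hits) == [("c1", 0, "+", 6.0)]

    def test_window_with_n_never_hits(self):
        hits = motifs.scan_pwm(GenomeSequence({"c1": "ANCAC"}), self._pwm())
        assert as_tuples(hits) == [("c1", 3, "+", 10.0)]

    def test_pwm_longer_than_chromosome_gives_no_hits(self):
        pwm = PWMatrix(["X"], np.ones((4, 10)))
        assert motifs.scan_pwm(GenomeSequence({"c1": "ACGT"}), pwm) == []

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2_000)) + "N" + "".join(
            rng.choice(list("ACGT"), size=500)
        )
        genome = GenomeSequence({"c1": seq})
        for trial in range(5):
            L = int(rng.integers(4, 10))
            weights = rng.normal(1.5, 1.5, size=(4, L))
            pwm = PWMatrix([f"R{trial}"], weights)
            got = as_tuples(motifs.scan_pwm(genome, pwm, min_score=10))
            want = [
                (c, s, st, pytest.approx(sc))
                for c, s, st, sc in scan_oracle(genome, pwm, 10)
            ]
            assert got == want

    def test_strand_symmetry_under_reverse_complement(self):
        """Scanning the reverse-complemented genome yields the mirror
        image hit set."""
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        weights = rng.normal(1.0, 2.0, size=(4, 6))
        pwm = PWMatrix(["X"], weights)
        fwd_hits = motifs.scan_pwm(GenomeSequence({"c": seq}), pwm, min_score=8)
        rc_hits = motifs.scan_pwm(GenomeSequence({"c": rc}), pwm, min_score=8)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (h.chrom, len(seq) - (h.start + pwm.length), flip[h.strand],
             round(h.score, 6))
            for h in rc_hits
        )
        assert sorted(
            (h.chrom, h.start, h.strand, round(h.score, 6)) for h in fwd_hits
        ) == mirrored


class TestPromoterHitCounts:
    def _hit(self, start, tf="X"):
        return motifs.MotifHit((tf,), "c1", "+", start, 10.0)

    def test_hit_inside_single_promoter(self):
        promoters = {"g1": Interval("c1", 100, 300)}
        out = motifs.promoter_hit_counts({"X": [self._hit(150)]}, promoters, {"X": 8})
        assert out.loc["X", "g1"] == 1

    def test_hit_overlapping_two_promoters_counts_for_both(self):
        promoters = {
            "g1": Interval("c1", 100, 300),
            "g2": Interval("c1", 295, 500),
        }
        out = motifs.promoter_hit_counts({"X": [self._hit(292)]}, promoters, {"X": 8})
        assert out.loc["X", "g1"] == 1 and out.loc["X", "g2"] == 1

    def test_one_bp_overlap_counts(self):
        promoters = {"g1": Interval("c1", 100, 300)}
        assert motifs.promoter_hit_counts(
            {"X": [self._hit(299)]}, promoters, {"X": 8}
        ).loc["X", "g1"] == 1
        assert motifs.promoter_hit_counts(
            {"X": [self._hit(300)]}, promoters, {"X": 8}
        ).loc["X", "g1"] == 0

    def test_no_hits_gives_zeros(self):
        out = motifs.promoter_hit_counts(
            {"X": []}, {"g1": Interval("c1", 0, 100)}, {"X": 8}
        )
        assert (out.values == 0).all()

    def test_matches_per_base_overlap_oracle(self):
        rng = np.random.default_rng(13)
        promoters = {}
        for i in range(20):
            s = int(rng.integers(0, 9_000))
            promoters[f"g{i}"] = Interval("c1", s, s + int(rng.integers(100, 800)))
        hits = [self._hit(int(rng.integers(0, 9_900))) for _ in range(50)]
        out = motifs.promoter_hit_counts({"X": hits}, promoters, {"X": 8})
        for gid, prom in promoters.items():
            want = sum(
                1 for h in hits if h.start < prom.end and prom.start < h.start + 8
            )
            assert out.loc["X", gid] == want


class TestMotifEnrichment:
    def _counts(self):
        return pd.DataFrame(
            {"g1": [4, 0], "g2": [4, 1], "g3": [0, 0], "g4": [0, 1]},
            index=["planted", "decoy"],
        )

    def test_set_equal_to_universe_gives_zero_enrichment(self):
        out = motifs.motif_enrichment(
            self._counts(), ["g1", "g2", "g3", "g4"], {"planted": 500, "decoy": 500}
        )
        np.testing.assert_allclose(out["log2_enrichment"], 0.0)

    def test_direct_ratio_arithmetic(self):
        # rate_set = 4.0, rate_all = 2.0 (eps = 1/4): log2(4.25/2.25) ~ 0.92
        out = motifs.motif_enrichment(
            self._counts(), ["g1", "g2"], {"planted": 500, "decoy": 500}
        )
        assert out.loc["planted", "log2_enrichment"] == pytest.approx(
            np.log2((4 + 0.25) / (2 + 0.25))
        )

    def test_enrichment_call_requires_both_thresholds(self):
        out = motifs.motif_enrichment(
            self._counts(), ["g1", "g2"], {"planted": 500, "decoy": 100}
        )
        assert bool(out.loc["planted", "enriched"])
        assert not bool(out.loc["decoy", "enriched"])
        # abundant but unenriched motif stays uncalled
        out_low = motifs.motif_enrichment(
            self._counts(), ["g1", "g2"], {"planted": 100, "decoy": 500}
        )
        assert not bool(out_low.loc["planted", "enriched"])  # log2(101) < 8

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motifs.motif_enrichment(self._counts(), [], {"planted": 1, "decoy": 1})

    def test_adding_set_hit_never_decreases_enrichment(self):
        counts = self._counts()
        base = motifs.motif_enrichment(
            counts, ["g1", "g2"], {"planted": 500, "decoy": 500}
        )
        bumped = counts.copy()
        bumped.loc["planted", "g1"] += 1
        out = motifs.motif_enrichment(
            bumped, ["g1", "g2"], {"planted": 501, "decoy": 500}
        )
        assert (
            out.loc["planted", "log2_enrichment"]
            >= base.loc["planted", "log2_enrichment"]
        )


class TestTruthRecovery:
    def test_planted_tfs_enriched_decoys_not(self, world, motif_scan):
        hits, promoters, counts = motif_scan
        genome_hits = {tf: len(h) for tf, h in hits.items()}
        derep = frozenset(world.genes_of_class("silenced_derepressible"))
        out = motifs.motif_enrichment(counts, GeneSet(derep), genome_hits)
        planted = world.planted_tf_names
        assert out.loc[planted, "enriched"].all()
        decoys = [tf for tf in out.index if tf not in planted]
        assert not out.loc[decoys, "enriched"].any()

    def test_label_permutation_centres_enrichment_at_zero(self, world, motif_scan):
        hits, promoters, counts = motif_scan
        genome_hits = {tf: len(h) for tf, h in hits.items()}
        n_set = len(world.genes_of_class("silenced_derepressible"))
        rng = np.random.default_rng(17)
        gene_ids = np.array(counts.columns)
        planted = world.planted_tf_names
        perm_values = []
        for _ in range(100):
            fake = rng.choice(gene_ids, size=n_set, replace=False)
            out = motifs.motif_enrichment(counts, list(fake), genome_hits)
            perm_values.extend(out.loc[planted, "log2_enrichment"])
        assert abs(float(np.mean(perm_values))) < 0.15
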