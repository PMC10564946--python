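"""Consensus peak funnel: calling, merging, filtering, annotation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pandas as pd

from m6ascape.genome import GenomeSequence, GenomicInterval, PeakCall, TranscriptModel
from m6ascape.peaks import (
    annotate_peaks, assign_region, call_enrichment_peaks, filter_recurrence,
    flag_m6am, merge_consensus, metagene_profile, motif_fraction,
    region_distribution,
)


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def calls(*intervals, caller="A"):
    return [PeakCall(i, "s1", caller) for i in intervals]


class TestEnrichmentCaller:
    def test_no_enrichment_yields_no_peaks(self):
        rng = np.random.default_rng(0)
        track = rng.poisson(5.0, size=5000).astype(float)
        assert call_enrichment_peaks(track, track.copy(), 50, 1e-6) == []

    def test_planted_region_recovered_and_matches_window_oracle(self):
        # flat noiseless background with one 10x region: the window decisions
        # are then fully determined by the Poisson tail
        n = 50_000
        inp = np.full(n, 5.0)
        ip = np.full(n, 5.0)
        ip[10_000:10_200] = 50.0
        peaks = call_enrichment_peaks(ip, inp, window=50, p_cutoff=1e-6)
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (10_000, 10_200)
        # oracle: exact Poisson tail on each 50-bp window
        scale = ip.sum() / inp.sum()
        sig_windows = []
        for w in range(n // 50):
            ip_c = ip[w * 50:(w + 1) * 50].sum()
            mu = inp[w * 50:(w + 1) * 50].sum() * scale
            if stats.poisson.sf(ip_c - 1, mu) < 1e-6:
                sig_windows.append(w)
        assert sig_windows == list(range(200, 204))

        # one-sided test: swapping IP and input gives nothing
        assert call_enrichment_peaks(inp, ip, window=50, p_cutoff=1e-6) == []

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length"):
            call_enrichment_peaks(np.ones(100), np.ones(50), 50, 1e-6)
        with pytest.raises(ValueError, match="window"):
            call_enrichment_peaks(np.ones(100), np.ones(100), 5, 1e-6)
        with pytest.raises(ValueError, match="depth"):
            call_enrichment_peaks(np.ones(100), np.zeros(100), 50, 1e-6)


class TestMergeConsensus:
    @pytest.mark.parametrize("a, b, expected", [
        ([iv(100, 200)], [iv(500, 600)], []),                  # disjoint
        ([iv(100, 300)], [iv(250, 400)], [iv(100, 400)]),      # union of overlap
        ([iv(100, 200)], [iv(100, 200)], [iv(100, 200)]),      # identity
        ([iv(100, 200, "+")], [iv(100, 200, "-")], []),        # strand mismatch
    ])
    def test_two_caller_examples(self, a, b, expected):
        assert merge_consensus(calls(*a), calls(*b, caller="B")) == expected

    small_intervals = st.lists(
        st.tuples(st.integers(0, 40), st.integers(1, 15)), min_size=0, max_size=6,
    ).map(lambda xs: [iv(s, s + l) for s, l in xs])

    @given(a=small_intervals, b=small_intervals)
    @settings(max_examples=100, deadline=None)
    def test_commutative_and_matches_bruteforce_cover(self, a, b):
        left = merge_consensus(calls(*a), calls(*b, caller="B"))
        right = merge_consensus(calls(*b, caller="B"), calls(*a))
        assert left == right
        # brute-force oracle: the merged output covers exactly the union of
        # bases of every overlapping A/B pair
        covered = set()
        for x in a:
            for y in b:
                if x.overlaps(y):
                    covered |= set(range(min(x.start, y.start), max(x.end, y.end)))
        out_bases = set()
        for m in left:
            out_bases |= set(range(m.start, m.end))
        assert out_bases == covered

    @given(a=small_intervals)
    @settings(max_examples=50, deadline=None)
    def test_idempotent_on_identical_inputs(self, a):
        once = merge_consensus(calls(*a), calls(*a, caller="B"))
        twice = merge_consensus(
            [PeakCall(i, "s1", "A") for i in once],
            [PeakCall(i, "s1", "B") for i in once],
        )
        assert once == twice


class TestRecurrenceFilter:
    def make_presence(self, counts, n_samples=98):
        rows = {
            f"p{i}": [j < c for j in range(n_samples)]
            for i, c in enumerate(counts)
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_boundary_of_the_five_sample_rule(self):
        presence = self.make_presence([5, 4, 98, 0])
        assert filter_recurrence(presence, 5) == ["p0", "p2"]

    def test_min_one_keeps_everything_present(self):
        presence = self.make_presence([5, 4, 1, 0])
        assert filter_recurrence(presence, 1) == ["p0", "p1", "p2"]

    def test_monotone_in_threshold(self):
        presence = self.make_presence([0, 1, 3, 5, 7, 20, 98])
        kept = [set(filter_recurrence(presence, k)) for k in range(1, 10)]
        for a, b in zip(kept, kept[1:]):
            assert b <= a

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            filter_recurrence(self.make_presence([1]), 0)


@pytest.fixture
def toy_coding_tx():
    # + strand: 0-300 5'UTR, CDS 300-900 with intron 500-600, 3'UTR 900-1200
    exons = [iv(0, 500), iv(600, 1200)]
    return TranscriptModel("g1", "t1", iv(0, 1200), exons,
                           cds_start=300, cds_end=900, is_canonical=True)


class TestAnnotation:
    def test_region_examples(self, toy_coding_tx):
        tx = toy_coding_tx
        assert assign_region(iv(510, 590), tx) == "intron"
        assert assign_region(iv(10, 50), tx) == "5UTR"
        # straddles CDS/3'UTR boundary at 900 -> stop-codon vicinity wins
        assert assign_region(iv(880, 920), tx) == "stop_codon_vicinity"
        assert assign_region(iv(290, 330), tx) == "start_codon_vicinity"
        assert assign_region(iv(420, 480), tx) == "CDS"

    def test_intergenic_and_exactly_one_region_each(self, toy_coding_tx):
        peaks = [iv(10, 50), iv(510, 590), iv(1300, 1400), iv(1050, 1070)]
        ann = annotate_peaks(peaks, [toy_coding_tx])
        assert [a.region for a in ann] == ["5UTR", "intron", "intergenic", "3UTR"]
        assert ann[2].gene_id is None
        assert region_distribution(ann).sum() == len(peaks)

    def test_noncoding_transcript_regions(self):
        tx = TranscriptModel("g2", "t2", iv(0, 300), [iv(0, 100), iv(200, 300)],
                             is_canonical=True)
        assert assign_region(iv(10, 50), tx) == "noncoding"
        assert assign_region(iv(120, 180), tx) == "intron"


class TestM6amFlag:
    def build(self, tss_base, upstream_base, strand="+"):
        # 1000-bp chromosome, gene at 100-600, 5'UTR 100-300 (plus strand)
        seq = list("A" * 1000)
        if strand == "+":
            start, end, cds = 100, 600, (300, 550)
            seq[99], seq[100] = upstream_base, tss_base
        else:
            from m6ascape.genome import reverse_complement as rc
            start, end, cds = 100, 600, (150, 400)
            seq[599], seq[600] = rc(tss_base), rc(upstream_base)
        genome = GenomeSequence({"chr1": "".join(seq)})
        tx = TranscriptModel("g", "t", iv(start, end, strand),
                             [iv(start, end, strand)],
                             cds_start=cds[0], cds_end=cds[1], is_canonical=True)
        utr5_peak = iv(start + 10, start + 60, strand) if strand == "+" else \
            iv(end - 60, end - 10, strand)
        return genome, tx, utr5_peak

    def test_bca_context_flags_m6am(self):
        genome, tx, peak = self.build("A", "C")
        assert flag_m6am([peak], [tx], genome) == [True]

    def test_non_a_tss_is_not_m6am(self):
        genome, tx, peak = self.build("G", "C")
        assert flag_m6am([peak], [tx], genome) == [False]

    def test_a_upstream_base_breaks_bca(self):
        genome, tx, peak = self.build("A", "A")
        assert flag_m6am([peak], [tx], genome) == [False]

    def test_cds_peak_is_never_m6am(self):
        genome, tx, _ = self.build("A", "C")
        cds_peak = iv(320, 380)
        assert flag_m6am([cds_peak], [tx], genome) == [False]

    def test_minus_strand_equivalent(self):
        genome, tx, peak = self.build("A", "C", strand="-")
        assert flag_m6am([peak], [tx], genome) == [True]

    def test_invariant_under_genome_reverse_complement(self):
        genome, tx, peak = self.build("A", "C")
        flags = flag_m6am([peak], [tx], genome)
        # mirror the whole coordinate system: reverse-complement the genome
        # and flip every interval and strand
        n = genome.chrom_length("chr1")

        def mirror(i):
            return GenomicInterval(i.chrom, n - i.end, n - i.start,
                                   "-" if i.strand == "+" else "+")

        tx_m = TranscriptModel(
            tx.gene_id, tx.transcript_id, mirror(tx.interval),
            [mirror(e) for e in tx.exons],
            cds_start=n - tx.cds_end, cds_end=n - tx.cds_start,
            is_canonical=True,
        )
        assert flag_m6am([mirror(peak)], [tx_m], genome.reverse_complemented()) == flags


class TestMotifFraction:
    def test_planted_fraction_matches_regex_oracle(self, toy_annotation):
        transcripts, genome, truth = toy_annotation
        windows = truth["motif_windows"]
        # 7 of 10 windows keep their planted GGACH; 3 are replaced by
        # motif-free decoy intervals in a motif-free part of the spacer
        import re
        chrom_seq = genome.chroms["chrT"]
        decoys = []
        pos = 0
        while len(decoys) < 3:
            seg = chrom_seq[pos:pos + 30]
            rc_seg = seg[::-1].translate(str.maketrans("ACGT", "TGCA"))
            pattern = re.compile("GGAC[ACT]")
            if not pattern.search(seg) and not pattern.search(rc_seg):
                decoys.append(GenomicInterval("chrT", pos, pos + 30, "+"))
            pos += 30
        chosen = windows[:7] + decoys
        assert motif_fraction(chosen, genome, "GGACH") == pytest.approx(0.7)

    def test_extremes(self, toy_annotation):
        _, genome, truth = toy_annotation
        assert motif_fraction(truth["motif_windows"], genome) == 1.0
        assert motif_fraction([], genome) == 0.0


class TestMetagene:
    def test_stop_codon_peaks_concentrate_at_cds_utr_junction(self, toy_coding_tx):
        tx = toy_coding_tx
        peaks = [iv(895, 905)] * 5  # midpoints at the stop codon
        density, _ = metagene_profile(peaks, [tx], bins_per_region=10)
        assert density.sum() == pytest.approx(1.0, abs=1e-9)
        junction = np.argmax(density)
        assert junction in (19, 20)  # last CDS bin or first 3'UTR bin

    def test_uniform_peaks_give_flat_profile(self, toy_coding_tx):
        tx = toy_coding_tx
        rng = np.random.default_rng(3)
        # peaks with exonic midpoints uniform over the transcript
        mids = []
        while len(mids) < 3000:
            m = int(rng.integers(2, 1198))
            if not 500 <= m < 600:
                mids.append(m)
        peaks = [iv(m - 2, m + 2) for m in mids]
        density, _ = metagene_profile(peaks, [tx], bins_per_region=10)
        # expected mass per bin given exonic region sizes (300/500/300 of
        # 1100 exonic bases, 10 bins per region)
        n = len(mids)
        se = np.sqrt(density * (1 - density) / n)
        expected = np.concatenate([
            np.full(10, 300 / 1100 / 10), np.full(10, 500 / 1100 / 10),
            np.full(10, 300 / 1100 / 10),
        ])
        assert np.all(np.abs(density - expected) < 3 * np.maximum(se, 0.004))

    def test_empty_peaks_warns_and_returns_zeros(self, toy_coding_tx):
        with pytest.warns(UserWarning):
            density, _ = metagene_profile([], [toy_coding_tx], bins_per_region=5)
        assert density.sum() == 0
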