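import numpy as np
import pytest

from chirpdyn import chirp_truepeaks as ctp
from chirpdyn import genome_io as gio
from chirpdyn.genome_io import CoverageTrack, GenomicInterval, Peak


def track_from(values, library_size=None, chrom="chr1", norm="raw"):
    arr = np.asarray(values, dtype=float)
    lib = library_size if library_size is not None else max(arr.sum(), 1.0)
    return CoverageTrack({chrom: arr}, {chrom: len(arr)}, lib, 1, norm)


class TestCandidateCalling:
    def test_null_noise_yields_no_peaks(self):
        rng = np.random.default_rng(11)
        noise = rng.poisson(1.0, 100_000).astype(float)
        track = track_from(noise)
        assert ctp.call_candidate_peaks(track, track) == []

    def test_strong_region_called_once(self):
        rng = np.random.default_rng(12)
        sig = rng.poisson(1.0, 100_000).astype(float)
        sig[50_000:50_500] += 10.0  # ~50 reads per window over expectation ~3
        inp = rng.poisson(1.0, 100_000).astype(float)
        peaks = ctp.call_candidate_peaks(track_from(sig), track_from(inp))
        assert len(peaks) == 1
        (p,) = peaks
        assert p.interval.start <= 50_000 and p.interval.end >= 50_500
        assert p.interval.start <= p.summit < p.interval.end

    def test_all_zero_signal_yields_no_peaks(self):
        zero = track_from(np.zeros(10_000), library_size=1.0)
        inp = track_from(np.ones(10_000))
        assert ctp.call_candidate_peaks(zero, inp) == []

    def test_mismatched_chromosomes_rejected(self):
        a = track_from(np.ones(1000), chrom="chr1")
        b = track_from(np.ones(1000), chrom="chr2")
        with pytest.raises(ValueError, match="chromosome"):
            ctp.call_candidate_peaks(a, b)


def mk_peak(start, end, summit, lane="even", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), summit, 10.0, 3.0, lane)


def brute_force_match(even, odd, min_recip=0.5, max_sd=500):
    """Independent greedy assignment: rescan the full pair matrix each step."""
    used_e, used_o, out = set(), set(), []
    while True:
        best = None
        for i, pe in enumerate(even):
            if i in used_e:
                continue
            for j, po in enumerate(odd):
                if j in used_o:
                    continue
                ov = pe.interval.overlap(po.interval)
                if ov <= 0:
                    continue
                recip = min(ov / len(pe.interval), ov / len(po.interval))
                sd = abs(pe.summit - po.summit)
                if recip < min_recip or sd > max_sd:
                    continue
                key = (-recip, sd, pe.interval.start, i, j)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            return out
        _, i, j = best
        used_e.add(i)
        used_o.add(j)
        out.append((i, j))


class TestRawPeakMatching:
    def setup_method(self):
        self.combined = track_from(np.ones(50_000))

    def test_identical_lists_self_concordant(self):
        peaks = [mk_peak(100, 400, 200), mk_peak(1000, 1500, 1200)]
        raw = ctp.match_raw_peaks(peaks, peaks, self.combined)
        assert len(raw) == len(peaks)
        for rp, p in zip(raw, peaks):
            assert rp.interval == p.interval

    def test_unpaired_peak_excluded(self):
        even = [mk_peak(100, 400, 200), mk_peak(10_000, 10_300, 10_100)]
        odd = [mk_peak(150, 450, 250, "odd")]
        raw = ctp.match_raw_peaks(even, odd, self.combined)
        assert len(raw) == 1
        assert raw[0].interval.start == 100 and raw[0].interval.end == 450

    def test_matches_equal_bruteforce_assignment(self):
        rng = np.random.default_rng(13)
        even, odd = [], []
        for _ in range(20):
            s = int(rng.integers(0, 40_000))
            e = s + int(rng.integers(200, 800))
            even.append(mk_peak(s, e, s + int(rng.integers(0, e - s))))
            s2 = s + int(rng.integers(-300, 300))
            s2 = max(0, s2)
            e2 = s2 + int(rng.integers(200, 800))
            odd.append(mk_peak(s2, e2, s2 + int(rng.integers(0, e2 - s2)), "odd"))
        raw = ctp.match_raw_peaks(even, odd, self.combined)
        expected = brute_force_match(even, odd)
        got = {
            (rp.even_peak.interval.start, rp.odd_peak.interval.start) for rp in raw
        }
        want = {
            (even[i].interval.start, odd[j].interval.start) for i, j in expected
        }
        assert got == want


def hand_pearson(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


class TestConcordanceScoring:
    def _score(self, even_vals, odd_vals, input_vals=None, lib=1e6):
        n = len(even_vals)
        even = track_from(even_vals, lib)
        odd = track_from(odd_vals, lib)
        combined = gio.combine_tracks(even, odd)
        inp = track_from(
            input_vals if input_vals is not None else np.ones(n), lib
        )
        rp = ctp.RawPeak(
            GenomicInterval("chr1", 0, n),
            int(np.argmax(even_vals)),
            mk_peak(0, n, 0),
            mk_peak(0, n, 0, "odd"),
        )
        return ctp.score_concordance(rp, even, odd, combined, inp)

    def test_identical_lanes_have_r_one(self):
        vals = np.array([1.0, 5, 2, 8, 3, 1, 0, 4, 2, 6])
        assert self._score(vals, vals).pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_r_matches_hand_formula(self):
        x = np.array([0.0, 1, 2, 3, 4, 5, 4, 3, 2, 1])
        y = x[::-1].copy()
        sc = self._score(x, y)
        assert sc.pearson_r == pytest.approx(hand_pearson(x, y), abs=1e-12)

    def test_fold_enrichment_arithmetic(self):
        # combined mean 3 rpm, input 1 rpm, eps 0.25 -> 3.25/1.25 = 2.6
        even = track_from(np.full(100, 1.5), 1e6)
        odd = track_from(np.full(100, 1.6), 1e6)
        combined = track_from(np.full(100, 3.0), 1e6)
        inp = track_from(np.full(100, 1.0), 1e6)
        rp = ctp.RawPeak(
            GenomicInterval("chr1", 0, 100), 50,
            mk_peak(0, 100, 50), mk_peak(0, 100, 50, "odd"),
        )
        sc = ctp.score_concordance(rp, even, odd, combined, inp)
        assert sc.fold_enrichment == pytest.approx(2.6)

    def test_constant_lane_scores_zero_correlation(self):
        vals = np.array([1.0, 5, 2, 8, 3, 1, 0, 4, 2, 6])
        assert self._score(vals, np.full(10, 2.0)).pearson_r == 0.0

    def test_pearson_scale_invariant(self):
        rng = np.random.default_rng(14)
        x = rng.poisson(3.0, 200).astype(float)
        y = x + rng.poisson(1.0, 200)
        r1 = self._score(x, y).pearson_r
        r2 = self._score(x * 37.5, y * 37.5).pearson_r
        assert r1 == pytest.approx(r2, abs=1e-12)


def random_scored_candidates(n, rng):
    out = []
    for i in range(n):
        start = i * 1000
        rp = ctp.RawPeak(
            GenomicInterval("chr1", start, start + 500),
            start + 100,
            mk_peak(start, start + 400, start + 100),
            mk_peak(start + 50, start + 500, start + 150, "odd"),
        )
        sc = ctp.ConcordanceScore(
            float(rng.uniform(0, 4)),
            float(rng.uniform(0, 5)),
            float(rng.uniform(-1, 1)),
            rp.interval,
        )
        out.append((rp, sc))
    return out


class TestTruePeakFilter:
    def test_passing_candidate_retained(self):
        cands = random_scored_candidates(1, np.random.default_rng(0))
        rp, _ = cands[0]
        sc = ctp.ConcordanceScore(2.0, 3.0, 0.5, rp.interval)
        assert len(ctp.filter_true_peaks([(rp, sc)])) == 1

    @pytest.mark.parametrize(
        "cov,fe,r",
        [(1.5, 3.0, 0.5), (2.0, 2.0, 0.5), (2.0, 3.0, 0.3)],
    )
    def test_boundary_values_rejected(self, cov, fe, r):
        cands = random_scored_candidates(1, np.random.default_rng(0))
        rp, _ = cands[0]
        sc = ctp.ConcordanceScore(cov, fe, r, rp.interval)
        assert ctp.filter_true_peaks([(rp, sc)]) == []

    def test_matches_bruteforce_three_predicate_filter(self):
        rng = np.random.default_rng(15)
        cands = random_scored_candidates(1000, rng)
        kept = ctp.filter_true_peaks(cands)
        expected = [
            rp.interval.start
            for rp, sc in cands
            if sc.avg_coverage > 1.5 and sc.fold_enrichment > 2 and sc.pearson_r > 0.3
        ]
        assert sorted(tp.interval.start for tp in kept) == sorted(expected)

    def test_raising_thresholds_monotone(self):
        rng = np.random.default_rng(16)
        cands = random_scored_candidates(300, rng)
        base = len(ctp.filter_true_peaks(cands))
        for filt in (
            ctp.TruePeakFilter(min_avg_coverage=2.5),
            ctp.TruePeakFilter(min_fold_enrichment=3.0),
            ctp.TruePeakFilter(min_pearson=0.6),
        ):
            assert len(ctp.filter_true_peaks(cands, filt)) <= base


class TestRpkm:
    def test_definition(self):
        vals = np.zeros(5000)
        vals[1000:2000] = 0.1  # 100 reads over a 1000-bp peak
        track = track_from(vals, 1e6)
        p = mk_peak(1000, 2000, 1500)
        assert ctp.quantify_peak_rpkm(track, [p])[0] == pytest.approx(100.0)

    def test_doubling_library_halves_rpkm(self):
        vals = np.random.default_rng(17).poisson(2.0, 5000).astype(float)
        p = mk_peak(1000, 2000, 1500)
        r1 = ctp.quantify_peak_rpkm(track_from(vals, 1e6), [p])[0]
        r2 = ctp.quantify_peak_rpkm(track_from(vals, 2e6), [p])[0]
        assert r2 == pytest.approx(r1 / 2)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(18)
        vals = rng.poisson(3.0, 50_000).astype(float)
        track = track_from(vals, 5e6)
        peaks = []
        for _ in range(50):
            s = int(rng.integers(0, 49_000))
            e = s + int(rng.integers(100, 1000))
            peaks.append(mk_peak(s, e, s))
        got = ctp.quantify_peak_rpkm(track, peaks)
        for p, val in zip(peaks, got):
            s, e = p.interval.start, p.interval.end
            assert val == pytest.approx(vals[s:e].sum() * 1e9 / ((e - s) * 5e6),
                                        abs=1e-12)


def make_gene(gene_id, chrom, start, end, strand, exon_bounds):
    exons = tuple(
        gio.GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds
    )
    return gio.GeneModel(
        gene_id, gio.GenomicInterval(chrom, start, end, strand, gene_id), exons
    )


class TestAnnotation:
    @pytest.fixture()
    def genes(self):
        return [
            make_gene("gA", "chr1", 10_000, 20_000, "+",
                      [(10_000, 11_000), (14_000, 15_000), (19_000, 20_000)]),
            make_gene("gB", "chr1", 40_000, 50_000, "-",
                      [(40_000, 42_000), (48_000, 50_000)]),
        ]

    def _annotate_at(self, summit, genes):
        p = mk_peak(summit - 50, summit + 50, summit)
        annos, _ = ctp.annotate_peaks([p], genes)
        return annos[0]

    def test_upstream_400bp_is_promoter_1kb(self, genes):
        a = self._annotate_at(9_600, genes)
        assert a.category == "promoter<=1kb" and a.target_gene_id == "gA"

    def test_summit_in_internal_exon(self, genes):
        a = self._annotate_at(14_500, genes)
        assert a.category == "exon" and a.target_gene_id == "gA"

    def test_intron_and_distal(self, genes):
        assert self._annotate_at(13_500, genes).category == "intron"
        assert self._annotate_at(30_000, genes).category == "distal_intergenic"

    def test_minus_strand_downstream(self, genes):
        # gB TSS = 49_999, TTS = 40_000; downstream is below 40_000
        a = self._annotate_at(38_500, genes)
        assert a.category == "downstream<=3kb" and a.target_gene_id == "gB"

    def test_fractions_sum_to_one(self, genes):
        rng = np.random.default_rng(19)
        peaks = [mk_peak(s, s + 100, s + 50)
                 for s in rng.integers(0, 60_000, 40)]
        _, hist = ctp.annotate_peaks(peaks, genes)
        assert sum(hist.values()) == pytest.approx(1.0)

    def test_matches_bruteforce_classifier(self, genes):
        rng = np.random.default_rng(20)
        for summit in rng.integers(0, 60_000, 200):
            summit = int(summit)
            a = self._annotate_at(summit, genes)
            assert a.category == brute_force_classify(summit, genes)


def brute_force_classify(summit, genes):
    d_tss = min(abs(summit - g.tss) for g in genes)
    if d_tss <= 1000:
        return "promoter<=1kb"
    if d_tss <= 2000:
        return "promoter1-2kb"
    if d_tss <= 3000:
        return "promoter2-3kb"
    for g in genes:
        if any(e.start <= summit < e.end for e in g.exons):
            return "exon"
    for g in genes:
        if g.interval.start <= summit < g.interval.end:
            return "intron"
    for g in genes:
        if g.strand == "+" and g.tts < summit <= g.tts + 3000:
            return "downstream<=3kb"
        if g.strand == "-" and g.tts - 3000 <= summit < g.tts:
            return "downstream<=3kb"
    return "distal_intergenic"


class TestTargetGenes:
    def test_peak_inside_gene(self):
        g = make_gene("g1", "chr1", 10_000, 20_000, "+", [(10_000, 20_000)])
        p = mk_peak(12_000, 12_500, 12_200)
        assert ctp.assign_target_genes([p], [g]) == {"g1"}

    def test_peak_1kb_upstream_within_extension(self):
        g = make_gene("g1", "chr1", 10_000, 20_000, "+", [(10_000, 20_000)])
        p = mk_peak(8_800, 9_000, 8_900)
        assert ctp.assign_target_genes([p], [g]) == {"g1"}
        assert ctp.assign_target_genes([p], [g], upstream_ext=500) == set()

    def test_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(21)
        genes = []
        for i in range(20):
            s = int(rng.integers(0, 180_000))
            genes.append(
                make_gene(f"g{i}", "chr1", s, s + 5000,
                          "+" if rng.random() < 0.5 else "-", [(s, s + 5000)])
            )
        peaks = [mk_peak(int(s), int(s) + 300, int(s) + 100)
                 for s in rng.integers(0, 190_000, 50)]
        got = ctp.assign_target_genes(peaks, genes)
        want = set()
        for g in genes:
            lo = g.interval.start - (2000 if g.strand == "+" else 0)
            hi = g.interval.end + (2000 if g.strand == "-" else 0)
            for p in peaks:
                if p.interval.start < hi and p.interval.end > max(0, lo):
                    want.add(g.gene_id)
        assert got == want


class TestReplicateSets:
    def test_worked_example(self):
        res = ctp.replicate_gene_sets({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert res["common"] == {"b", "c"}
        assert res["gain"] == {"b"}
        assert res["venn"]["all_three"] == 1

    def test_disjoint_replicates(self):
        res = ctp.replicate_gene_sets({"a"}, {"b"}, set())
        assert res["common"] == set() and res["gain"] == set()

    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(22)
        pool = [f"g{i}" for i in range(300)]
        r1 = set(rng.choice(pool, 100, replace=False))
        r2 = set(rng.choice(pool, 100, replace=False))
        c = set(rng.choice(pool, 100, replace=False))
        venn = ctp.replicate_gene_sets(r1, r2, c)["venn"]
        assert sum(venn.values()) == len(r1 | r2 | c)
        assert venn["rep1_rep2_only"] == len((r1 & r2) - c)
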