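"""Tests for off-target enumeration, genome scanning and candidate ranking."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from sifted.energy_model import PWM, EnergyMatrix, relative_kd, site_ddg
from sifted.offtarget_scan import (
    EnumeratedSite,
    design_pipeline,
    correlation_metrics,
    enumerate_sites,
    hits_to_bed,
    naive_scan,
    read_fasta,
    reverse_complement,
    roc_curve,
    scan_genome,
    summary_score,
    talen_pair_score,
    write_fasta,
)
from sifted.synthetic_data import simulate_genome


def brute_force_sites(em: EnergyMatrix, kd_threshold: float) -> list[EnumeratedSite]:
    """Exhaustive 4^L oracle for enumerate_sites (small L only)."""
    bound = np.log(kd_threshold) + 1e-12
    out = []
    for tup in itertools.product("ACGT", repeat=em.length):
        seq = "".join(tup)
        e = site_ddg(em, seq)
        if e <= bound:
            out.append(EnumeratedSite(seq, e, relative_kd(e)))
    out.sort(key=lambda s: (s.ddg, s.sequence))
    return out


class TestReverseComplement:
    def test_known(self):
        assert reverse_complement("TACG") == "CGTA"
        assert reverse_complement("AANT") == "ANTT"

    def test_involution(self):
        assert reverse_complement(reverse_complement("TGCATTAG")) == "TGCATTAG"


class TestEnumerateSites:
    def test_matches_brute_force(self, random_em):
        for thr in (1.0, 2.0, 10.0):
            got = enumerate_sites(random_em, thr)
            want = brute_force_sites(random_em, thr)
            assert [s.sequence for s in got] == [s.sequence for s in want]
            np.testing.assert_allclose([s.ddg for s in got],
                                       [s.ddg for s in want], atol=1e-9)

    def test_threshold_one_is_canonical_site_only(self, random_em):
        sites = enumerate_sites(random_em, 1.0)
        # anchored EM: the only zero-energy site is the canonical one
        # (random off-anchor entries are strictly positive here)
        assert len(sites) == 1
        assert sites[0].ddg == pytest.approx(0.0, abs=1e-12)
        assert sites[0].rel_kd == pytest.approx(1.0)
        canonical = "".join("ACGT"[a] for a in random_em.anchors)
        assert sites[0].sequence == canonical

    def test_sorted_and_within_bound(self, random_em):
        sites = enumerate_sites(random_em, 10.0)
        ddgs = [s.ddg for s in sites]
        assert ddgs == sorted(ddgs)
        assert max(ddgs) <= np.log(10.0) + 1e-9
        assert len({s.sequence for s in sites}) == len(sites)

    def test_boundary_site_included(self):
        # one free position with energy exactly ln(threshold)
        vals = np.zeros((3, 4))
        vals[1, 1] = np.log(5.0)
        em = EnergyMatrix(vals, np.array([3, 0, 2]))
        seqs = {s.sequence for s in enumerate_sites(em, 5.0)}
        assert "TCG" in seqs

    def test_requires_anchored(self, random_em):
        em = EnergyMatrix(random_em.values + 1.0, random_em.anchors)
        with pytest.raises(ValueError, match="anchored"):
            enumerate_sites(em)

    def test_threshold_below_one_rejected(self, random_em):
        with pytest.raises(ValueError, match=">= 1"):
            enumerate_sites(random_em, 0.5)


@pytest.fixture(scope="module")
def genome_and_sites(random_em):
    sites = enumerate_sites(random_em, 10.0)
    planted = [
        (sites[0].sequence, 500, "+"),
        (sites[0].sequence, 1200, "-"),
        (sites[min(3, len(sites) - 1)].sequence, 2000, "+"),
    ]
    g1 = simulate_genome(5000, gc=0.5, planted=planted, seed=42, name="chrA")
    g2 = simulate_genome(2000, gc=0.35, seed=43, name="chrB")
    return {**g1, **g2}, sites


class TestScanGenome:
    @staticmethod
    def _key(h):
        return (h.chrom, h.start, h.end, h.strand, h.matched_sequence)

    def test_matches_naive_oracle(self, genome_and_sites):
        genome, sites = genome_and_sites
        fast = scan_genome(sites, genome)
        slow = naive_scan(sites, genome)
        assert sorted(map(self._key, fast)) == sorted(map(self._key, slow))

    def test_planted_hits_found_with_coordinates(self, genome_and_sites):
        genome, sites = genome_and_sites
        hits = {(h.chrom, h.start, h.strand): h for h in scan_genome(sites, genome)}
        best = sites[0].sequence
        L = len(best)
        fwd = hits[("chrA", 500, "+")]
        assert fwd.matched_sequence == best and fwd.end == 500 + L
        rev = hits[("chrA", 1200, "-")]
        assert rev.matched_sequence == best
        # minus-strand hit reports the forward-strand footprint
        assert genome["chrA"][1200:1200 + L] == reverse_complement(best)

    def test_lowercase_and_n_handling(self):
        genome = {"c": "ttTACGAAcgNACGA"}
        hits = scan_genome(["TACG"], genome)
        keys = {(h.start, h.strand) for h in hits}
        assert (2, "+") in keys          # case-insensitive match
        assert all(0 <= h.start <= len(genome["c"]) - 4 for h in hits)
        # the window overlapping N never matches
        assert not any(h.start in (9, 10) for h in hits)

    def test_plain_string_sites_get_nan_kd(self):
        hits = scan_genome(["TACG"], {"c": "ATACGA"})
        assert len(hits) == 1 and np.isnan(hits[0].rel_kd)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_genome([], {"c": "ACGT"})

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            scan_genome(["TAC", "TACG"], {"c": "ACGT"})


class TestBedOutput:
    def test_bed6_fields_and_score_cap(self):
        from sifted.offtarget_scan import GenomicHit

        hits = [
            GenomicHit("chr1", 10, 14, "+", "TACG", 1.0),
            GenomicHit("chr1", 30, 34, "-", "TACG", 4.0),
        ]
        lines = hits_to_bed(hits).strip().split("\n")
        assert lines[0].split("\t") == ["chr1", "10", "14", "TACG", "1000", "+"]
        assert lines[1].split("\t") == ["chr1", "30", "34", "TACG", "250", "-"]

    def test_empty(self):
        assert hits_to_bed([]) == ""


class TestSummaryScore:
    def test_formula_and_monotonicity(self):
        from sifted.offtarget_scan import GenomicHit

        h = lambda kd: GenomicHit("c", 0, 4, "+", "TACG", kd)
        assert summary_score([]) == 0.0
        assert summary_score([h(1.0), h(2.0), h(4.0)]) == pytest.approx(1.75)
        base = summary_score([h(5.0)])
        assert summary_score([h(5.0), h(9.0)]) > base


@pytest.fixture(scope="module")
def ctx_model(small_panel):
    import pandas as pd

    from sifted.sifted_model import (
        ContextModel,
        Standardizer,
        _fit_single,
        build_feature_matrix,
    )

    fp = build_feature_matrix(small_panel)
    std = Standardizer.fit(fp.X)
    Xs = std.transform(fp.X)
    coef, inter = _fit_single(Xs, fp.y.to_numpy(), fp.weights, 0.01, 0.95)
    return ContextModel(
        coefficients=pd.Series(coef, index=std.means.index),
        intercept=inter, alpha=0.95, lambda_chosen=0.01,
        means=std.means, scales=std.scales,
    )


@pytest.fixture(scope="module")
def setup(ctx_model):
    region = {"reg": "GGTACGTTACCATGCTTAAGGCG"}
    genome = simulate_genome(3000, gc=0.45, seed=7, name="chrZ")
    # embed the region at a known locus
    seq = genome["chrZ"]
    start = 1000
    genome = {"chrZ": seq[:start] + region["reg"] + seq[start + len(region["reg"]):]}
    reports = design_pipeline(region, genome, ctx_model, repeat_count=9,
                              kd_threshold=4.0)
    return region, genome, start, reports


class TestDesignPipeline:
    def test_candidate_set_matches_construction(self, setup):
        region, _, start, reports = setup
        seq = region["reg"]
        L = 10  # repeat_count + 1
        expected = set()
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for off in range(len(s) - L + 1):
                w = s[off:off + L]
                if w.startswith("T"):
                    if strand == "+":
                        expected.add(("chrZ", start + off, "+", w))
                    else:
                        expected.add(
                            ("chrZ", start + len(seq) - L - off, "-", w))
        got = {(*r.location, r.intended_site) for r in reports}
        assert got == expected
        assert len(reports) == len(expected) > 0

    def test_minus_strand_coordinates_point_at_site(self, setup):
        _, genome, _, reports = setup
        for r in reports:
            chrom, g_start, strand = r.location
            sub = genome[chrom][g_start:g_start + len(r.intended_site)]
            if strand == "+":
                assert sub == r.intended_site
            else:
                assert reverse_complement(sub) == r.intended_site

    def test_intended_locus_excluded_from_hits(self, setup):
        _, _, _, reports = setup
        for r in reports:
            chrom, g_start, strand = r.location
            assert not any(h.chrom == chrom and h.start == g_start
                           and h.strand == strand for h in r.hits)
            assert r.summary_score == pytest.approx(summary_score(r.hits))

    def test_sorted_ascending_by_score(self, setup):
        _, _, _, reports = setup
        scores = [r.summary_score for r in reports]
        assert scores == sorted(scores)

    def test_protein_matches_canonical_code(self, setup):
        _, _, _, reports = setup
        code = {"A": "NI", "C": "HD", "G": "NN", "T": "NG"}
        for r in reports:
            assert list(r.protein.repeats) == [code[b] for b in r.intended_site[1:]]

    def test_planted_duplicate_raises_score(self, setup, ctx_model):
        region, genome, _, reports = setup
        target = reports[0]
        dup = target.intended_site if target.location[2] == "+" \
            else reverse_complement(target.intended_site)
        genome2 = {"chrZ": genome["chrZ"] + "AAAA" + dup + "AAAA"}
        reports2 = design_pipeline(region, genome2, ctx_model, repeat_count=9,
                                   kd_threshold=4.0)
        match = next(r for r in reports2 if r.location == target.location)
        # the sequence-identical copy elsewhere counts with rel_kd = 1
        assert match.summary_score >= target.summary_score + 1.0 - 1e-9

    def test_explicit_region_location_used(self, setup, ctx_model):
        region, genome, start, reports = setup
        reports2 = design_pipeline(region, genome, ctx_model, repeat_count=9,
                                   kd_threshold=4.0,
                                   region_location=("chrZ", start))
        assert {(*r.location, r.summary_score) for r in reports2} == \
            {(*r.location, r.summary_score) for r in reports}

    def test_unlocatable_region_warns(self, ctx_model, caplog):
        region = {"reg": "GGTACGTTACCATGCTTAAGGCG"}
        genome = simulate_genome(500, gc=0.5, seed=99)
        with caplog.at_level("WARNING", logger="sifted.offtarget_scan"):
            design_pipeline(region, genome, ctx_model, repeat_count=9,
                            kd_threshold=2.0)
        assert any("not located" in rec.message for rec in caplog.records)

    def test_empty_region_rejected(self, ctx_model):
        with pytest.raises(ValueError, match="empty"):
            design_pipeline({}, {"c": "ACGT"}, ctx_model, repeat_count=9)


class TestTalenPairScore:
    @pytest.fixture()
    def pwm(self):
        return PWM(np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.4, 0.2, 0.2, 0.2],
        ]))

    def test_optimal_vs_optimal_total_two(self, pwm):
        ps = talen_pair_score(pwm, pwm, "AA", "AA")
        assert ps.left_score == pytest.approx(1.0)
        assert ps.right_score == pytest.approx(1.0)
        assert ps.total == pytest.approx(2.0)

    def test_hand_arithmetic(self, pwm):
        s_opt = -np.log(0.7) - np.log(0.4)
        s_site = -np.log(0.7) - np.log(0.2)
        want = (s_opt / s_site) ** 0.6
        ps = talen_pair_score(pwm, pwm, "AC", "AA")
        assert ps.left_score == pytest.approx(want)
        assert ps.right_score == pytest.approx(1.0)

    def test_monotone_degradation(self):
        # sharply peaked PWM: each additional mismatch lowers the partial
        probs = np.tile([0.85, 0.05, 0.05, 0.05], (6, 1))
        pwm = PWM(probs)
        sites = ["AAAAAA", "CAAAAA", "CCAAAA", "CCCAAA", "CCCCAA"]
        scores = [talen_pair_score(pwm, pwm, s, "AAAAAA").left_score
                  for s in sites]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert all(0 < s <= 1 for s in scores)

    def test_caller_supplied_optimal(self, pwm):
        ps = talen_pair_score(pwm, pwm, "AC", "AC", optimal="AC")
        assert ps.total == pytest.approx(2.0)

    def test_length_mismatch(self, pwm):
        with pytest.raises(ValueError, match="length"):
            talen_pair_score(pwm, pwm, "A", "AA")


class TestRocCurve:
    def test_auc_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(17)
        labels = rng.random(200) < 0.4
        scores = np.round(labels * 1.0 + rng.normal(0, 1, 200), 1)  # many ties
        tpr, spec, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(18)
        labels = np.r_[np.ones(30, bool), np.zeros(40, bool)]
        scores = rng.normal(labels.astype(float), 1.0)
        tpr, spec, auc = roc_curve(scores, labels)
        assert tpr[0] == 0.0 and spec[0] == 1.0
        assert tpr[-1] == 1.0 and spec[-1] == 0.0
        assert np.all(np.diff(tpr) >= 0)
        assert np.all(np.diff(spec) <= 0)

    def test_perfect_separation(self):
        _, _, auc = roc_curve([3.0, 2.0, 1.0, 0.0], [1, 1, 0, 0])
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], [1, 1])


class TestCorrelationMetrics:
    def test_log_pearson_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, 50)
        y = x ** 1.3 * rng.lognormal(0, 0.2, 50)
        r = correlation_metrics(x, y, "log_pearson")
        assert r == pytest.approx(stats.pearsonr(np.log(x), np.log(y))[0])

    def test_spearman_perfect_monotone(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        assert correlation_metrics(x, np.exp(x), "spearman") == pytest.approx(1.0)

    def test_nonpositive_rejected_in_log_mode(self):
        with pytest.raises(ValueError, match="positive"):
            correlation_metrics([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            correlation_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "kendall")


class TestFastaIO:
    def test_roundtrip_wrapped(self, tmp_path):
        recs = {"chr1": "ACGT" * 40, "chr2": "TTTACG"}
        path = tmp_path / "g.fa"
        write_fasta(recs, path, width=50)
        assert read_fasta(path) == recs
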