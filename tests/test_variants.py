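"""SNP candidate detection, removal cascade, cluster filter, VCF, concordance."""

import numpy as np
import pytest

from conftest import make_call, make_site
from nightcontrast import variants as V
from nightcontrast.simulate import SimConfig, simulate_pileups
from nightcontrast.variants import (
    CLUSTER_FILTER,
    ConcordanceReport,
    FilterConfig,
    PileupFormatError,
    PileupOrderError,
)


class TestCandidateDetection:
    def test_clean_biallelic_site_is_a_candidate(self):
        sites = [make_site(a1={"A": 12}, a2={"G": 9})]
        calls = V.call_candidate_snps(sites)
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref_allele, c.alt_allele) == ("A", "G")
        assert (c.depth_a1, c.depth_a2) == (12, 9)

    def test_monomorphic_site_yields_no_candidate(self):
        sites = [make_site(a1={"A": 12}, a2={"A": 10})]
        assert V.call_candidate_snps(sites) == []

    @pytest.mark.parametrize(
        "a1,a2",
        [({"A": 2}, {"G": 9}), ({"A": 12}, {"G": 2})],
    )
    def test_depth_below_minimum_suppresses_candidate(self, a1, a2):
        assert V.call_candidate_snps([make_site(a1=a1, a2=a2)]) == []

    def test_low_mapq_suppresses_candidate(self):
        sites = [make_site(a1={"A": 12}, a2={"G": 9}, mapq=10)]
        assert V.call_candidate_snps(sites) == []

    def test_unsorted_input_rejected(self):
        sites = [
            make_site(pos=20, a1={"A": 5}, a2={"A": 5}),
            make_site(pos=10, a1={"A": 5}, a2={"A": 5}),
        ]
        with pytest.raises(PileupOrderError):
            V.call_candidate_snps(sites)

    def test_non_acgt_reference_rejected(self):
        with pytest.raises(PileupFormatError):
            V.call_candidate_snps([make_site(ref="N", a1={"A": 5}, a2={"G": 5})])

    def test_quality_cap_defines_high_quality_tier(self):
        deep = V.call_candidate_snps([make_site(a1={"A": 100}, a2={"G": 100})])[0]
        assert deep.quality == V.QUALITY_CAP and deep.tier == "high_quality"
        shallow = V.call_candidate_snps([make_site(a1={"A": 3}, a2={"G": 3})])[0]
        assert shallow.quality < V.QUALITY_CAP and shallow.tier == "standard"

    def test_frame_and_site_paths_agree_on_simulated_data(self):
        cfg = SimConfig(seed=21, n_genes=10, gene_length_range=(200, 300), snp_rate=2e-3)
        _, p1, p2, _ = simulate_pileups(cfg)
        from_frames = V.call_candidates_from_frames(p1, p2)
        sites = [
            make_site(
                seq_id=r1.seq_id, pos=r1.pos, ref=r1.ref,
                a1={"A": r1.A, "C": r1.C, "G": r1.G, "T": r1.T},
                a2={"A": r2.A, "C": r2.C, "G": r2.G, "T": r2.T},
                mapq=min(r1.mapq, r2.mapq),
            )
            for r1, r2 in zip(p1.itertuples(), p2.itertuples())
        ]
        from_sites = V.call_candidate_snps(sites)
        assert [(c.seq_id, c.pos, c.alt_allele) for c in from_frames] == [
            (c.seq_id, c.pos, c.alt_allele) for c in from_sites
        ]


class TestCascade:
    def test_heterozygous_within_accession(self):
        call = make_call(a1=(6, 0, 5, 0), a2=(0, 0, 9, 0))  # a1 = {A:6, G:5}
        annotated = V.apply_cascade([call])[0]
        assert "het_within_accession" in annotated.filters

    def test_low_alt_support_both_labels(self):
        # a1 = {A:30}, a2 = {G:2, A:18}: 2 alt reads of 50 pooled = 4%
        call = make_call(a1=(30, 0, 0, 0), a2=(18, 0, 2, 0))
        annotated = V.apply_cascade([call])[0]
        assert {"low_alt_reads", "low_alt_fraction"} <= annotated.filters

    def test_triallelic_ref_discordant_site(self):
        # a1 = {C:10}, a2 = {G:8}, ref A
        call = make_call(ref="A", alt="G", a1=(0, 10, 0, 0), a2=(0, 0, 8, 0))
        annotated = V.apply_cascade([call])[0]
        assert {"ref_discordant", "not_biallelic"} <= annotated.filters

    def test_clean_call_passes(self):
        call = make_call(a1=(12, 0, 0, 0), a2=(0, 0, 9, 0))
        assert V.apply_cascade([call])[0].passed

    def test_per_accession_alt_fraction_mode(self):
        # alt is 100% of accession 2 reads but 4% pooled
        call = make_call(a1=(96, 0, 0, 0), a2=(0, 0, 4, 0))
        pooled = V.apply_cascade([call], FilterConfig())[0]
        per_acc = V.apply_cascade(
            [call], FilterConfig(alt_fraction_mode="per_accession")
        )[0]
        assert "low_alt_fraction" in pooled.filters
        assert "low_alt_fraction" not in per_acc.filters

    def test_annotation_is_order_independent(self):
        calls = [
            make_call(pos=10, a1=(6, 0, 5, 0), a2=(0, 0, 9, 0)),
            make_call(pos=20, a1=(12, 0, 0, 0), a2=(0, 0, 9, 0)),
            make_call(pos=30, a1=(30, 0, 0, 0), a2=(18, 0, 2, 0)),
        ]
        forward = V.apply_cascade(calls)
        backward = V.apply_cascade(calls[::-1])[::-1]
        assert [c.filters for c in forward] == [c.filters for c in backward]


def _pass_calls(positions, seq_id="t1"):
    return [
        make_call(seq_id=seq_id, pos=p, a1=(12, 0, 0, 0), a2=(0, 0, 9, 0))
        for p in sorted(positions)
    ]


def brute_force_cluster_flags(positions, window=100, max_snps=4):
    """Exhaustive all-windows oracle: flag every position inside any
    length-`window` interval holding more than `max_snps` calls."""
    positions = sorted(positions)
    flagged = set()
    for start in range(1, max(positions) + 1):
        inside = [p for p in positions if start <= p <= start + window - 1]
        if len(inside) > max_snps:
            flagged.update(inside)
    return flagged


class TestClusterFilter:
    def test_five_snps_in_window_all_flagged(self):
        calls = V.cluster_filter(_pass_calls([10, 30, 50, 70, 90]))
        assert all(CLUSTER_FILTER in c.filters for c in calls)

    def test_four_snps_boundary_untouched(self):
        calls = V.cluster_filter(_pass_calls([10, 30, 50, 70]))
        assert all(CLUSTER_FILTER not in c.filters for c in calls)

    def test_window_is_positional_not_count_based(self):
        # five calls but spread beyond any single 100-bp window
        calls = V.cluster_filter(_pass_calls([10, 60, 120, 180, 240]))
        assert all(CLUSTER_FILTER not in c.filters for c in calls)

    def test_failed_calls_do_not_count_toward_clusters(self):
        calls = _pass_calls([10, 30, 50, 70])
        failed = make_call(pos=90, a1=(6, 0, 5, 0), a2=(0, 0, 9, 0))
        out = V.cluster_filter(V.apply_cascade(calls + [failed]))
        assert all(CLUSTER_FILTER not in c.filters for c in out)

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 40)
            positions = sorted(rng.choice(np.arange(1, 1200), size=n, replace=False))
            out = V.cluster_filter(_pass_calls(positions))
            got = {c.pos for c in out if CLUSTER_FILTER in c.filters}
            assert got == brute_force_cluster_flags(positions)


class TestVcfRoundTrip:
    def test_empty_call_list_writes_valid_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        V.write_vcf([], path, contigs={"t1": 500})
        assert V.read_vcf(path) == []
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert text.strip().splitlines()[-1].startswith("#CHROM")

    def test_single_pass_call_single_data_line(self, tmp_path):
        call = V.apply_cascade([make_call(a1=(12, 0, 0, 0), a2=(0, 0, 9, 0))])[0]
        path = tmp_path / "one.vcf"
        V.write_vcf([call], path, contigs={"t1": 500})
        data = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(data) == 1
        assert data[0].split("\t")[6] == "PASS"

    def test_simulate_call_write_read_round_trip(self, tmp_path):
        cfg = SimConfig(seed=17, n_genes=40, snp_rate=1e-3)
        _, p1, p2, _ = simulate_pileups(cfg)
        calls = V.call_snps(p1, p2)
        assert calls
        path = tmp_path / "calls.vcf"
        contigs = p1.groupby("seq_id")["pos"].max().to_dict()
        V.write_vcf(calls, path, contigs=contigs)
        back = V.read_vcf(path)
        original = {(c.seq_id, c.pos): c for c in calls}
        assert len(back) == len(calls)
        for c in back:
            o = original[(c.seq_id, c.pos)]
            assert (c.ref_allele, c.alt_allele, c.tier) == (o.ref_allele, o.alt_allele, o.tier)
            assert c.filters == o.filters
            assert (c.counts_a1, c.counts_a2) == (o.counts_a1, o.counts_a2)
            assert c.alt_fraction == pytest.approx(o.alt_fraction, rel=1e-5)


class TestConcordance:
    def test_identical_sets_fraction_one(self):
        calls = _pass_calls([10, 20, 30])
        report = V.concordance(calls, calls)
        assert report.match_fraction == 1.0
        assert report.shared_positions == 3

    def test_disjoint_sets_share_nothing(self):
        report = V.concordance(_pass_calls([10, 20]), _pass_calls([30, 40]))
        assert report.shared_positions == 0
        assert (report.unique_to_a, report.unique_to_b) == (2, 2)

    def test_planted_allele_swap_fraction(self):
        calls = _pass_calls(range(10, 210, 2))  # 100 calls
        swapped = []
        for i, c in enumerate(calls):
            alt = "T" if i < 10 else c.alt_allele  # corrupt 10%
            swapped.append(
                make_call(seq_id=c.seq_id, pos=c.pos, alt=alt,
                          a1=(12, 0, 0, 0), a2=(0, 0, 0, 9) if i < 10 else (0, 0, 9, 0))
            )
        report = V.concordance(calls, swapped)
        assert report.shared_positions == 100
        assert report.match_fraction == pytest.approx(0.9)


class TestSimulatedRecall:
    def test_all_clean_true_snps_recalled_without_artifacts(self, clean_config):
        _, p1, p2, truth = simulate_pileups(clean_config)
        calls = V.call_snps(p1, p2)
        passed = {(c.seq_id, c.pos, c.ref_allele, c.alt_allele) for c in calls if c.passed}
        true = set(truth.true_snps)
        assert true, "generator planted no SNPs"
        assert true <= passed
        assert len(passed & true) / len(passed) >= 0.99
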