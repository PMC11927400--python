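import numpy as np
import pytest

import genedomains as gd
from genedomains.calling import fold_change_direction
from helpers import (
    dense_to_matrix,
    exact_mannwhitney_greater,
    exact_wilcoxon_two_sided,
    uniform_matrix,
)


class TestMannWhitney:
    def test_identical_constant_samples_uninformative(self):
        assert gd.mannwhitney_greater([2.0] * 5, [2.0] * 5) >= 0.5

    def test_matches_exact_permutation_small_samples(self):
        # tie-free data: the CC normal approximation is uniformly within
        # 0.02 of the exact permutation p for n, m <= 8
        rng = np.random.default_rng(0)
        cases = [(np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0]))]
        for _ in range(20):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(3, 9))
            cases.append((rng.normal(1, 1, n), rng.normal(0, 1, m)))
        for x, y in cases:
            approx = gd.mannwhitney_greater(x, y)
            exact = exact_mannwhitney_greater(x, y)
            assert approx == pytest.approx(exact, abs=0.02)

    def test_tied_data_gives_valid_conservative_p(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.poisson(3, 6).astype(float)
            y = rng.poisson(3, 6).astype(float)
            p = gd.mannwhitney_greater(x, y)
            assert 0.0 < p <= 1.0

    def test_swap_symmetry_without_ties(self):
        x = [1.2, 3.4, 5.1, 7.9]
        y = [0.3, 2.2, 4.8, 6.1]
        p = gd.mannwhitney_greater(x, y)
        q = gd.mannwhitney_greater(y, x)
        assert p + q == pytest.approx(1.0, abs=0.1)

    def test_small_samples_untestable(self):
        assert gd.mannwhitney_greater([1.0, 2.0], [1.0, 2.0, 3.0]) is None

    def test_monotone_in_target_scale(self):
        rng = np.random.default_rng(3)
        y = rng.gamma(2, 1, 12)
        x = rng.gamma(2, 1, 12)
        ps = [gd.mannwhitney_greater(x * s, y) for s in (1.0, 1.5, 2.5, 4.0)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestWilcoxon:
    def test_all_zero_untestable(self):
        assert gd.wilcoxon_signed_rank([0.0] * 8) is None

    def test_matches_exact_signflip_enumeration(self):
        # includes a case with tied |differences| (approximate path) and
        # tie-free cases (exact small-sample path)
        rng = np.random.default_rng(1)
        cases = [np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])]
        for _ in range(15):
            n = int(rng.integers(5, 9))
            cases.append(rng.normal(0.5, 1, n))
        for d in cases:
            d = d[d != 0]
            if d.size < 5:
                continue
            approx = gd.wilcoxon_signed_rank(d)
            exact = exact_wilcoxon_two_sided(d)
            assert approx == pytest.approx(exact, abs=0.02)

    def test_sign_flip_invariance(self):
        d = [1.5, -2.0, 3.0, 4.5, -5.0, 6.0]
        assert gd.wilcoxon_signed_rank(d) == pytest.approx(
            gd.wilcoxon_signed_rank([-v for v in d])
        )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert gd.bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_step_up(self):
        assert gd.bh_adjust([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.03, 0.04]
        )

    def test_all_ones(self):
        assert gd.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_untestable_excluded_from_family(self):
        out = gd.bh_adjust([0.01, None, 0.02, 0.04])
        assert out[1] is None
        assert out[0] == pytest.approx(0.03)


class TestSingleCalling:
    def test_uniform_matrix_yields_no_domains(self):
        m = uniform_matrix(200)
        e = gd.expected_profile(m)
        genes = [
            gd.GeneModel(f"g{k}", "chrT", 10_000 + 4000 * k, 12_500 + 4000 * k, "+")
            for k in range(5)
        ]
        calls = gd.call_single_domains(m, e, genes)
        assert calls and not any(c.is_domain for c in calls)

    def test_planted_enrichment_is_called(self, small_sim):
        cfg, genes, truth, m, e = small_sim
        calls = gd.call_single_domains(m, e, genes)
        called = {c.gene_id for c in calls if c.is_domain}
        planted = {
            g.gene_id for g, h in zip(genes, truth.has_single_domain) if h
        }
        # the strongly enriched simulation recovers most planted genes and
        # declares nothing among well-covered nulls beyond the FDR budget
        assert len(called & planted) / len(planted) > 0.5
        assert len(called - planted) <= max(1, int(0.1 * len(called)))

    def test_clipped_gene_absent_from_calls(self):
        m = uniform_matrix(100)
        e = gd.expected_profile(m)
        edge = gd.GeneModel("edge", "chrT", 1, 2001, "+")
        ok = gd.GeneModel("ok", "chrT", 10_000, 12_500, "+")
        calls = gd.call_single_domains(m, e, [edge, ok])
        assert [c.gene_id for c in calls] == ["ok"]


class TestMultiCalling:
    def test_uniform_matrix_yields_no_domains(self):
        m = uniform_matrix(300, resolution=500)
        e = gd.expected_profile(m)
        genes = [
            gd.GeneModel(f"g{k}", "chrT", 30_000 + 5000 * k, 33_000 + 5000 * k, "+")
            for k in range(5)
        ]
        calls = gd.call_multi_domains(m, e, genes)
        assert not any(c.is_domain for c in calls)

    def test_window_enumeration_count(self):
        m = uniform_matrix(300, resolution=500)
        e = gd.expected_profile(m)
        genes = [
            gd.GeneModel(f"g{k}", "chrT", 30_000 + 5000 * k, 33_000 + 5000 * k, "+")
            for k in range(5)
        ]
        calls = gd.call_multi_domains(m, e, genes, max_genes=10)
        assert len(calls) == 4 + 3 + 2 + 1


class TestDiffCalling:
    def test_identical_matrices_yield_no_calls(self):
        m = uniform_matrix(200)
        genes = [
            gd.GeneModel(f"g{k}", "chrT", 10_000 + 5000 * k, 13_000 + 5000 * k, "+")
            for k in range(4)
        ]
        assert gd.call_diff_domains(m, m, genes) == []

    @pytest.mark.parametrize(
        "r_body,r_surr,expected",
        [
            (0.85, 0.85, "enhanced_in_treat"),
            (0.95, 0.85, "none"),
            (0.85, 0.95, "none"),
            (1.0 / 0.85, 1.0 / 0.85, "enhanced_in_control"),
        ],
    )
    def test_fold_change_threshold(self, r_body, r_surr, expected):
        assert fold_change_direction(r_body, r_surr, 0.1) == expected

    def test_mismatched_resolution_rejected(self):
        a = uniform_matrix(100, resolution=250)
        b = uniform_matrix(50, resolution=500)
        with pytest.raises(ValueError, match="resolution"):
            gd.call_diff_domains(a, b, [])

    def test_planted_differential_insulation_recovered(self):
        diff_spec = {4: (2.0, 0.5), 12: (2.0, 0.5)}
        cfg = gd.SimulationConfig(
            chrom_length=200_000, resolution=250, n_genes=20,
            frac_single_domains=0.0, depth_c=100.0, seed=5,
            diff_spec=diff_spec,
        )
        genes, truth = gd.simulate_annotation(cfg)
        ma, mb = gd.simulate_contacts(genes, truth, cfg)
        calls = gd.call_diff_domains(
            gd.balance_matrix(ma), gd.balance_matrix(mb), genes
        )
        hits = {c.gene_id for c in calls if c.passes}
        assert {"g0004", "g0012"} <= hits
        assert all(
            c.direction == "enhanced_in_treat" for c in calls if c.passes
        )


def test_bed_export_contains_called_domains(tmp_path, small_sim):
    _, genes, _, m, e = small_sim
    calls = gd.call_single_domains(m, e, genes)
    path = tmp_path / "calls.bed"
    gd.calling.write_bed(calls, str(path))
    lines = path.read_text().strip().splitlines()
    assert len(lines) == sum(c.is_domain for c in calls)
    chrom, start, end, name, score, strand = lines[0].split("\t")
    assert chrom == m.chrom and int(score) <= 1000 and strand in "+-"
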