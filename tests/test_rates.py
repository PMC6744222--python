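"""Ka/Ks estimation: NG86 reference and YN00-style primary estimator."""

import math

import numpy as np
import pytest

from pogdiv import (
    CodonAlignment,
    RATIO_SENTINEL,
    SaturationError,
    SimulationParams,
    count_differences_ng86,
    estimate_kappa,
    estimate_ng86,
    estimate_yn00,
    simulate_codon_pair,
)


def aln(a: str, b: str, gene_id: str = "g") -> CodonAlignment:
    return CodonAlignment(gene_id, a, b, len(a.replace("-", "")) // 3)


class TestNG86:
    def test_identical_sequences_undefined_ratio(self):
        e = estimate_ng86(aln("TTTATG" * 5, "TTTATG" * 5))
        assert e.ka == e.ks == 0.0
        assert math.isnan(e.ratio)

    def test_closed_form_jc_correction(self):
        # 30 TTT codons, one synonymous difference: S = 10, ps = 0.1
        a = "TTT" * 30
        b = "TTC" + "TTT" * 29
        e = estimate_ng86(aln(a, b))
        assert e.s_sites == pytest.approx(10.0)
        assert e.ks == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert e.ka == 0.0

    def test_ratio_sentinel_for_zero_ks(self):
        # one nonsynonymous difference, no synonymous ones
        e = estimate_ng86(aln("TTT" * 10, "GTT" + "TTT" * 9))
        assert e.ks == 0.0 and e.ka > 0.0
        assert e.ratio == RATIO_SENTINEL

    def test_saturation_raises(self):
        # every codon differs synonymously: ps = 3 >> 3/4
        with pytest.raises(SaturationError):
            estimate_ng86(aln("TTT" * 10, "TTC" * 10))

    def test_conservation_and_symmetry(self):
        p = SimulationParams(n_codons=400, omega=0.5, t=0.3, seed=5)
        a, b, _ = simulate_codon_pair(p)
        e_ab = estimate_ng86(aln(a, b))
        e_ba = estimate_ng86(aln(b, a))
        assert e_ab.s_sites + e_ab.n_sites == pytest.approx(3 * 400, abs=1e-9)
        assert e_ab.ks == pytest.approx(e_ba.ks)
        assert e_ab.ka == pytest.approx(e_ba.ka)

    def test_gap_and_ambiguous_columns_dropped_pairwise(self):
        a3 = "TTTATGGGA" * 3
        b3 = "TTC" + a3[3:]
        ref = estimate_ng86(aln(a3, b3))
        with_gap = estimate_ng86(aln(a3 + "---", b3 + "AAA"))
        with_n = estimate_ng86(aln(a3 + "ANA", b3 + "AAA"))
        assert with_gap.n_codons == with_n.n_codons == ref.n_codons == 9
        assert with_gap.ks == pytest.approx(ref.ks)


class TestKappa:
    def test_no_differences_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="kappa"):
            k = estimate_kappa(aln("TTTATG" * 5, "TTTATG" * 5), default_kappa=2.0)
        assert k == 2.0

    def test_all_transition_third_positions_give_kappa_above_one(self):
        # GGT vs GGC: fourfold-degenerate third position, T<->C transition
        a = "GGT" * 10 + "ATGAAA" * 5
        b = "GGC" * 2 + "GGT" * 8 + "ATGAAA" * 5
        assert estimate_kappa(aln(a, b)) > 1.0

    def test_recovery_on_simulated_data(self):
        kappas = []
        for seed in range(15):
            p = SimulationParams(n_codons=1500, omega=0.5, kappa=2.0, t=0.4, seed=seed)
            a, b, _ = simulate_codon_pair(p)
            kappas.append(estimate_kappa(aln(a, b)))
        assert np.mean(kappas) == pytest.approx(2.0, rel=0.25)


class TestYN00:
    def test_identical_sequences(self):
        e = estimate_yn00(aln("TTTATGGGA" * 4, "TTTATGGGA" * 4))
        assert e.ka == e.ks == 0.0
        assert math.isnan(e.ratio)

    def test_conservation_and_symmetry(self):
        p = SimulationParams(n_codons=400, omega=1.5, t=0.3, seed=9)
        a, b, _ = simulate_codon_pair(p)
        e_ab = estimate_yn00(aln(a, b))
        e_ba = estimate_yn00(aln(b, a))
        assert e_ab.s_sites + e_ab.n_sites == pytest.approx(3 * 400, abs=1e-9)
        assert e_ab.ks == pytest.approx(e_ba.ks, rel=1e-9)
        assert e_ab.ka == pytest.approx(e_ba.ka, rel=1e-9)
        assert e_ab.kappa == pytest.approx(e_ba.kappa)

    def test_neutral_simulation_recovers_ratio_one(self):
        ratios = []
        for seed in range(20):
            p = SimulationParams(n_codons=1000, omega=1.0, kappa=2.0, t=0.3, seed=100 + seed)
            a, b, _ = simulate_codon_pair(p)
            ratios.append(estimate_yn00(aln(a, b)).ratio)
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.12)

    def test_difference_totals_match_ng86_totals(self):
        # pathway weighting reapportions ambiguous paths between classes but
        # conserves the total number of differences
        p = SimulationParams(n_codons=500, omega=0.5, t=0.4, seed=3)
        a, b, _ = simulate_codon_pair(p)
        sd_ng, nd_ng = count_differences_ng86(aln(a, b))
        e = estimate_yn00(aln(a, b))
        assert e.sd + e.nd == pytest.approx(sd_ng + nd_ng, rel=1e-9)


def test_mean_ks_monotone_in_branch_length():
    means = []
    for t in (0.05, 0.15, 0.3):
        ks = []
        for seed in range(10):
            p = SimulationParams(n_codons=800, omega=0.3, t=t, seed=int(1000 * t) + seed)
            a, b, _ = simulate_codon_pair(p)
            ks.append(estimate_yn00(aln(a, b)).ks)
        means.append(np.mean(ks))
    assert means[0] < means[1] < means[2]
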