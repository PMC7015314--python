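"""Constituent selection statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from cssig import (
    SimulationConfig,
    delta_saf,
    ehh,
    simulate_two_pop_panel,
    standardize_xpehh,
    weir_cockerham_fst,
    xpehh_scan,
)
from cssig.constituent import _ihh_one_side

from conftest import make_panel


# -- independent oracles (straight-from-formula, scalar) --------------------


def wc_theta_oracle(p1, n1, p2, n2):
    """Two-population Weir-Cockerham theta written directly from the
    allele-level ANOVA decomposition, one SNP at a time."""
    N = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / N
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2)
    nc = N - (n1**2 + n2**2) / N
    return (msp - msg) / (msp + (nc - 1) * msg)


def ehh_oracle(haplotypes, core, allele, offset_cols):
    """Pair enumeration: fraction of carrier pairs identical over the span."""
    carriers = [h for h in haplotypes if h[core] == allele]
    pairs = list(itertools.combinations(range(len(carriers)), 2))
    span = [core] + list(offset_cols)
    same = sum(
        all(carriers[a][j] == carriers[b][j] for j in span) for a, b in pairs
    )
    return same / len(pairs)


def pooled_ehh_oracle(haplotypes, cols):
    """Fraction of all haplotype pairs identical over cols (core included)."""
    n = len(haplotypes)
    pairs = list(itertools.combinations(range(n), 2))
    same = sum(all(haplotypes[a][j] == haplotypes[b][j] for j in cols) for a, b in pairs)
    return same / len(pairs)


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        theta, valid = weir_cockerham_fst([100], [100], [0], [100])
        assert valid[0] and theta[0] == pytest.approx(1.0)

    def test_shared_monomorphism_invalid(self):
        theta, valid = weir_cockerham_fst([0], [100], [0], [100])
        assert not valid[0] and np.isnan(theta[0])

    def test_elite_vs_comparator_counts_near_zero(self):
        # C-allele counts 61/98 vs 62/100: frequencies 0.6224 vs 0.62
        theta, valid = weir_cockerham_fst([61], [98], [62], [100])
        expected = wc_theta_oracle(61 / 98, 98, 62 / 100, 100)
        assert valid[0]
        assert theta[0] == pytest.approx(expected, rel=1e-12)
        assert abs(theta[0]) < 0.02

    def test_matches_oracle_on_random_counts(self, rng):
        an1 = rng.integers(10, 120, size=50)
        an2 = rng.integers(10, 120, size=50)
        ac1 = rng.integers(0, an1 + 1)
        ac2 = rng.integers(0, an2 + 1)
        theta, valid = weir_cockerham_fst(ac1, an1, ac2, an2)
        for j in range(50):
            if not valid[j]:
                continue
            exp = wc_theta_oracle(ac1[j] / an1[j], an1[j], ac2[j] / an2[j], an2[j])
            assert theta[j] == pytest.approx(exp, rel=1e-10, abs=1e-12)

    def test_mean_matches_generating_differentiation(self):
        """Balding-Nichols calibration: mean theta tracks the drift F."""
        panel = simulate_two_pop_panel(SimulationConfig(n_snps=10_000, seed=3))
        ac_s, an_s = panel.allele_counts("selected")
        ac_r, an_r = panel.allele_counts("reference")
        theta, valid = weir_cockerham_fst(ac_s, an_s, ac_r, an_r)
        assert 0.04 <= np.nanmean(theta[valid]) <= 0.06


class TestDeltaSAF:
    def test_simple_difference_and_null(self):
        d, v = delta_saf([0.9, 0.4], [0.4, 0.4], orientation="alt_allele")
        assert d[0] == pytest.approx(0.5) and d[1] == 0.0

    def test_elite_vs_comparator_difference(self):
        # C allele 61/98 vs 62/100; C is the major (ref) allele -> candidate
        # under ref_minor orientation is the alt allele (frequencies 1 - f)
        d, _ = delta_saf([1 - 61 / 98], [1 - 62 / 100], orientation="ref_minor")
        assert abs(abs(d[0]) - abs(61 / 98 - 62 / 100)) < 1e-12
        assert d[0] == pytest.approx(-(61 / 98 - 62 / 100), abs=1e-12)

    def test_bounds_and_antisymmetry(self, rng):
        f1 = rng.random(200)
        f2 = rng.random(200)
        d12, _ = delta_saf(f1, f2, orientation="alt_allele")
        d21, _ = delta_saf(f2, f1, orientation="alt_allele")
        assert np.all(np.abs(d12) <= 1)
        np.testing.assert_allclose(d12, -d21, atol=1e-15)

    def test_missing_flagged(self):
        d, v = delta_saf([np.nan], [0.3])
        assert not v[0] and np.isnan(d[0])


class TestEHH:
    def test_identical_carriers_no_decay(self):
        hap = np.tile(np.array([1, 1, 0, 1, 1], dtype=np.int8), (4, 1))
        curve = ehh(hap, [10, 20, 30, 40, 50], core=2, allele=0, direction="right")
        assert all(v == 1.0 for _, v in curve.offsets)
        assert curve.truncation_reason == "chromosome_end"

    def test_one_identical_pair_of_four(self):
        # carriers H1=H2 while H3, H4 differ beyond the first offset
        hap = np.array(
            [
                [1, 0, 0],
                [1, 0, 0],
                [1, 1, 0],
                [1, 0, 1],
            ],
            dtype=np.int8,
        )
        curve = ehh(hap, [10, 20, 30], core=0, allele=1, direction="right", truncate_at=0.0)
        # after two offsets only the H1/H2 pair of C(4,2)=6 is intact
        assert curve.offsets[1][1] == pytest.approx(1 / 6)

    def test_matches_pair_enumeration_oracle(self, rng):
        hap = (rng.random((10, 9)) < 0.5).astype(np.int8)
        hap[:3, 4] = 1  # ensure >=2 carriers of allele 1 at the core
        curve = ehh(hap, np.arange(9) * 10, core=4, allele=1, direction="right", truncate_at=0.0)
        for k, (_, val) in enumerate(curve.offsets):
            exp = ehh_oracle(hap.tolist(), 4, 1, range(5, 5 + k + 1))
            assert val == pytest.approx(exp, rel=1e-10, abs=1e-12)

    def test_non_increasing_property(self, rng):
        for _ in range(20):
            hap = (rng.random((12, 15)) < rng.uniform(0.2, 0.8)).astype(np.int8)
            core = int(rng.integers(0, 15))
            allele = int(hap[0, core])  # guarantees >=1 carrier; need 2
            if (hap[:, core] == allele).sum() < 2:
                continue
            curve = ehh(hap, np.arange(15), core=core, allele=allele,
                        direction="left", truncate_at=0.0)
            vals = [1.0] + [v for _, v in curve.offsets]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_too_few_carriers_rejected(self):
        hap = np.zeros((4, 3), dtype=np.int8)
        with pytest.raises(ValueError, match="carrier"):
            ehh(hap, [1, 2, 3], core=1, allele=1, direction="right")


class TestXPEHH:
    def _panel_two_cohorts(self, hap_sel, hap_ref, positions):
        hap = np.vstack([hap_sel, hap_ref]).astype(np.int8)
        n_sel = hap_sel.shape[0] // 2
        n_ref = hap_ref.shape[0] // 2
        return make_panel(hap, positions=positions,
                          cohorts=["sel"] * n_sel + ["ref"] * n_ref)

    def test_identical_cohorts_give_zero(self, rng):
        hap = (rng.random((12, 20)) < 0.5).astype(np.int8)
        panel = self._panel_two_cohorts(hap, hap.copy(), (np.arange(20) + 1) * 5000)
        raw, valid = xpehh_scan(panel, "sel", "ref")
        np.testing.assert_allclose(raw[valid], 0.0, atol=1e-12)

    def test_cohort_swap_negates(self, rng):
        hs = (rng.random((12, 20)) < 0.5).astype(np.int8)
        hr = (rng.random((12, 20)) < 0.5).astype(np.int8)
        panel = self._panel_two_cohorts(hs, hr, (np.arange(20) + 1) * 5000)
        ab, v1 = xpehh_scan(panel, "sel", "ref")
        ba, v2 = xpehh_scan(panel, "ref", "sel")
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_allclose(ab[v1], -ba[v1], atol=1e-12)

    def test_matches_hand_trapezoid_oracle(self):
        """6 haplotypes per cohort, 3-SNP span: iHH by explicit pair counts
        and trapezoid integration."""
        pos = np.array([1000, 3000, 6000])
        hs = np.array(
            [
                [0, 1, 0],
                [0, 1, 0],
                [0, 1, 1],
                [1, 0, 0],
                [1, 0, 0],
                [1, 0, 0],
            ],
            dtype=np.int8,
        )
        hr = np.array(
            [
                [0, 0, 0],
                [0, 1, 1],
                [0, 1, 0],
                [1, 0, 1],
                [1, 1, 0],
                [1, 0, 0],
            ],
            dtype=np.int8,
        )
        panel = self._panel_two_cohorts(hs, hr, pos)
        raw, valid = xpehh_scan(panel, "sel", "ref", truncate_at=0.0, gap_cap_bp=10**6)
        core = 1  # middle SNP

        def ihh(h):
            e0 = pooled_ehh_oracle(h.tolist(), [core])
            left = pooled_ehh_oracle(h.tolist(), [core, 0])
            right = pooled_ehh_oracle(h.tolist(), [core, 2])
            area_left = 0.5 * (e0 + left) * (pos[1] - pos[0])
            area_right = 0.5 * (e0 + right) * (pos[2] - pos[1])
            return area_left + area_right

        expected = np.log(ihh(hs) / ihh(hr))
        assert valid[core]
        assert raw[core] == pytest.approx(expected, rel=1e-10)

    def test_ihh_matches_oracle_on_random_spans(self, rng):
        hap = (rng.random((8, 7)) < 0.5).astype(np.int8)
        pos = np.cumsum(rng.integers(500, 3000, size=7))
        area, truncated = _ihh_one_side(hap, pos, 3, +1, 0.0, 10**9)
        exp = 0.0
        prev = pooled_ehh_oracle(hap.tolist(), [3])
        for j in range(4, 7):
            cur = pooled_ehh_oracle(hap.tolist(), list(range(3, j + 1)))
            exp += 0.5 * (prev + cur) * (pos[j] - pos[j - 1])
            prev = cur
        assert not truncated
        assert area == pytest.approx(exp, rel=1e-10)

    def test_gap_cap_truncates(self, rng):
        hap = (rng.random((8, 5)) < 0.5).astype(np.int8)
        pos = np.array([1000, 2000, 3000, 500_000, 501_000])
        area, truncated = _ihh_one_side(hap, pos, 2, +1, 0.0, 200_000)
        assert truncated

    def test_standardisation_moments(self, rng):
        raw = rng.normal(2.0, 3.0, size=500)
        z = standardize_xpehh(raw)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=0) - 1) < 1e-12
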