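"""EHH curves, iHH integration, iHS scores and standardization."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import ehh_oracle, make_matrix, random_matrix
from sweepscan.ehh_ihs import (
    EHHCurve,
    IHSScore,
    ScanOptions,
    ehh,
    ihh,
    scan_chromosome,
    standardize,
    unstandardized_ihs,
)
from sweepscan.vcf_qc import MISSING


class TestEHH:
    def test_identical_carriers_stay_at_one(self):
        # 4 derived carriers share one haplotype; EHH = 1 until the edge
        alleles = np.array(
            [
                [1, 0, 1, 0, 1],
                [1, 0, 1, 0, 1],
                [1, 0, 1, 0, 1],
                [1, 0, 1, 0, 1],
                [0, 1, 0, 1, 0],
                [0, 1, 0, 1, 0],
            ],
            dtype=np.int8,
        )
        curve = ehh(make_matrix(alleles), 0, 1, "downstream")
        assert curve.truncated == "edge"
        assert all(v == 1.0 for _, v in curve.points)

    def test_two_two_split_gives_two_sixths(self):
        # 4 carriers split 2/2 at the first extension site
        alleles = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]], dtype=np.int8
        )
        curve = ehh(make_matrix(alleles), 0, 1, "downstream", ehh_cutoff=0.5)
        assert curve.points[0] == (0, 1.0)
        assert curve.points[1][1] == pytest.approx(2 / 6, abs=1e-15)

    def test_fewer_than_two_carriers_raises(self):
        alleles = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match=">=2 carriers"):
            ehh(make_matrix(alleles), 0, 1, "downstream")

    def test_gap_truncation_and_cap_mode(self):
        alleles = np.tile(np.array([[1], [1], [1], [0], [0], [0]], np.int8), (1, 3))
        positions = np.array([1_000, 2_000, 900_000 + 2_000])
        hm = make_matrix(alleles, positions=positions)
        tr = ehh(hm, 0, 1, "downstream", ehh_cutoff=0.05, max_gap_bp=800_000)
        assert tr.truncated == "gap"
        cap = ehh(hm, 0, 1, "downstream", ehh_cutoff=0.05, max_gap_bp=800_000, gap_rule="cap")
        assert cap.truncated == "edge"  # runs to the end, gap distance capped
        assert cap.points[-1][0] == 1_000 + 800_000

    @pytest.mark.parametrize("direction", ["upstream", "downstream"])
    @pytest.mark.parametrize("core_allele", [0, 1])
    def test_matches_bruteforce_oracle(self, rng, direction, core_allele):
        step = 1 if direction == "downstream" else -1
        for _ in range(25):
            hm = random_matrix(rng, 16, 30, missing_rate=0.05)
            core = int(rng.integers(0, 30))
            carriers = (hm.alleles[:, core] == core_allele).sum()
            if carriers < 2:
                continue
            curve = ehh(hm, core, core_allele, direction, ehh_cutoff=0.0)
            for k, (dist, value) in enumerate(curve.points[1:], start=1):
                site = core + step * k
                assert value == pytest.approx(
                    ehh_oracle(hm, core, core_allele, site), abs=1e-12
                )
                assert dist == abs(int(hm.positions[site]) - int(hm.positions[core]))

    def test_monotone_non_increasing(self, rng):
        for _ in range(20):
            hm = random_matrix(rng, 20, 25)
            core = int(rng.integers(0, 25))
            if (hm.alleles[:, core] == 1).sum() < 2:
                continue
            curve = ehh(hm, core, 1, "downstream", ehh_cutoff=0.0)
            values = [v for _, v in curve.points]
            assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_invariant_to_row_order(self, rng):
        hm = random_matrix(rng, 16, 20)
        perm = rng.permutation(16)
        hm2 = make_matrix(hm.alleles[perm], positions=hm.positions)
        c1 = ehh(hm, 5, 1, "downstream", ehh_cutoff=0.0)
        c2 = ehh(hm2, 5, 1, "downstream", ehh_cutoff=0.0)
        assert c1.points == c2.points


class TestIHH:
    def test_closed_form_trapezoid(self):
        up = EHHCurve(0, 1, "upstream", [(0, 1.0), (100, 0.5), (200, 0.0)])
        down = EHHCurve(0, 1, "downstream", [(0, 1.0)])
        # 100*(1+0.5)/2 + 100*(0.5+0)/2 = 100
        assert ihh(up, down) == pytest.approx(100.0, abs=1e-12)

    def test_doubling_distances_doubles_integral(self):
        pts = [(0, 1.0), (50, 0.8), (120, 0.3), (150, 0.02)]
        doubled = [(2 * d, v) for d, v in pts]
        up1 = EHHCurve(0, 1, "upstream", pts)
        up2 = EHHCurve(0, 1, "upstream", doubled)
        flat = EHHCurve(0, 1, "downstream", [(0, 1.0)])
        assert ihh(up2, flat) == pytest.approx(2 * ihh(up1, flat), rel=1e-12)

    def test_flat_segment_lower_bound(self):
        up = EHHCurve(0, 1, "upstream", [(0, 1.0), (300, 1.0), (400, 0.01)])
        down = EHHCurve(0, 1, "downstream", [(0, 1.0), (300, 1.0), (350, 0.01)])
        assert ihh(up, down) >= 600.0

    def test_truncated_curve_rejected(self):
        up = EHHCurve(0, 1, "upstream", [(0, 1.0), (100, 0.5)], truncated="gap")
        down = EHHCurve(0, 1, "downstream", [(0, 1.0)])
        with pytest.raises(ValueError, match="truncated"):
            ihh(up, down)


class TestUnstandardizedIHS:
    def test_mirror_configuration_gives_zero(self):
        # ancestral carriers (rows 0-2) and derived carriers (rows 3-5)
        # carry identical flanking haplotype structure around the core
        flank_inner = [0, 1, 1]
        flank_outer = [0, 1, 0]  # splits the surviving pair -> EHH hits 0
        alleles = np.array(
            [
                [o, i, c, i, o]
                for c_group in (0, 1)
                for o, i, c in zip(flank_outer, flank_inner, [c_group] * 3)
            ],
            dtype=np.int8,
        )
        hm = make_matrix(alleles)
        score = unstandardized_ihs(hm, 2, ScanOptions(min_carriers=2))
        assert score.valid
        assert score.uihs == 0.0

    def test_label_swap_negates_exactly(self, rng):
        opts = ScanOptions(min_carriers=2)
        checked = 0
        for _ in range(10):
            hm = random_matrix(rng, 20, 30)
            flipped = make_matrix(
                np.where(hm.alleles == MISSING, MISSING, 1 - hm.alleles),
                positions=hm.positions,
            )
            for core in range(30):
                s1 = unstandardized_ihs(hm, core, opts)
                s2 = unstandardized_ihs(flipped, core, opts)
                assert s1.valid == s2.valid
                if s1.valid:
                    assert s2.uihs == -s1.uihs  # exact, not approximate
                    checked += 1
        assert checked > 50

    def test_sweep_site_has_negative_uihs(self):
        from sweepscan.synthetic_data import SimParams, simulate_population
        from sweepscan.vcf_qc import apply_qc

        p = SimParams(
            seed=42, n_diploids=100, n_generations=300, seq_length=400_000,
            mu=1e-6, rho=1e-6, s=1.0, sweep_pos=200_000, sweep_intro_gen=285,
            sweep_freq_range=(0.5, 0.9), sample_n=40,
        )
        hm, truth = simulate_population(p)
        clean, _ = apply_qc(hm)
        idx = int(np.argmin(np.abs(clean.positions - truth.sweep_pos)))
        score = unstandardized_ihs(clean, idx, ScanOptions(min_carriers=2))
        assert score.valid and score.uihs < 0

    def test_too_few_carriers_flagged(self):
        col = np.zeros(20, dtype=np.int8)
        col[:2] = 1
        alleles = np.column_stack([col] + [np.arange(20) % 2] * 4).astype(np.int8)
        hm = make_matrix(alleles)
        score = unstandardized_ihs(hm, 0, ScanOptions(min_carriers=5))
        assert not score.valid and score.reason == "too_few_carriers"


def _score(freq: float, uihs: float, pos: int = 1_000) -> IHSScore:
    return IHSScore(
        chrom="chr1", position=pos, derived_freq=freq, uihs=uihs, valid=True
    )


class TestStandardize:
    def test_two_scores_hand_arithmetic(self):
        scores = [_score(0.5, 1.0, 100), _score(0.5, 3.0, 200)]
        out, bins = standardize(scores, n_bins=1)
        # sample sd (n-1) of {1, 3} is sqrt(2); (1-2)/sqrt(2) = -1/sqrt(2)
        assert out[0].ihs_std == pytest.approx(-1 / math.sqrt(2), abs=1e-12)
        assert out[1].ihs_std == pytest.approx(+1 / math.sqrt(2), abs=1e-12)

    def test_bin_moments_are_zero_one(self, rng):
        scores = [
            _score(float(rng.uniform(0.02, 0.98)), float(rng.normal()), i)
            for i in range(500)
        ]
        out, bins = standardize(scores, n_bins=20)
        groups: dict[int, list[float]] = {}
        for s in out:
            if s.valid:
                g = int(bins.merged_group[s.bin_index])
                groups.setdefault(g, []).append(s.ihs_std)
        assert groups
        for vals in groups.values():
            arr = np.asarray(vals)
            assert abs(arr.mean()) < 1e-9
            assert abs(arr.std(ddof=1) - 1) < 1e-9

    def test_sparse_bins_are_merged(self):
        scores = [_score(0.1, 1.0), _score(0.1, 2.0), _score(0.9, 5.0)]
        out, bins = standardize(scores, n_bins=100)
        # the lone high-frequency score must share a merged group
        assert int(bins.merged_group.max()) + 1 < 100
        assert all(s.valid for s in out)

    def test_all_invalid_raises(self):
        bad = IHSScore(chrom="chr1", position=1, derived_freq=0.5, valid=False)
        with pytest.raises(ValueError, match="no valid scores"):
            standardize([bad])

    def test_neutral_simulation_tail_fraction(self):
        from sweepscan.synthetic_data import SimParams, simulate_genome
        from sweepscan.vcf_qc import apply_qc

        base = SimParams(seed=1234)
        mats, _ = simulate_genome(base, 3)
        scores = []
        for hm in mats:
            clean, _ = apply_qc(hm)
            scores.extend(scan_chromosome(clean))
        out, _ = standardize(scores)
        std = np.array([s.ihs_std for s in out if s.valid])
        assert std.size >= 1_500
        tail = float((np.abs(std) > 2).mean())
        assert 0.01 <= tail <= 0.15
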