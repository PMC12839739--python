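"""EHH/iHH/iHS/nSL against independent naive oracles and symmetry laws."""

import itertools
import math

import numpy as np
import pytest

from dcmscan import HaplotypeMatrix, ehh, ihh, ihs_scan, nsl_scan, standardize_by_freq_bins
from dcmscan.haplo_stats import SKIP_MAF, SKIP_TRUNC, CoreSiteScore

from conftest import random_matrix


# ---------------------------------------------------------------- oracles

def ehh_oracle(matrix, core, allele, direction, distance):
    """EHH by explicit enumeration of carrier pairs and substring equality."""
    carriers = [h for h in range(matrix.n_haplotypes)
                if matrix.alleles[h, core] == allele]
    n_c = len(carriers)
    step = -1 if direction == "left" else 1
    lo, hi = sorted((core, core + step * distance))
    identical = 0
    for a, b in itertools.combinations(carriers, 2):
        if all(matrix.alleles[a, j] == matrix.alleles[b, j]
               for j in range(lo, hi + 1)):
            identical += 1
    return identical / (n_c * (n_c - 1) / 2)


def ihh_oracle(matrix, core, allele, ehh_cutoff=0.05, max_gap_bp=200_000):
    """Site-by-site EHH walk with a separately written trapezoid rule."""
    area = 0.0
    ok = True
    for direction, step in (("left", -1), ("right", 1)):
        prev_ehh, prev_pos = 1.0, int(matrix.positions[core])
        reached = False
        d = 0
        while True:
            d += 1
            j = core + step * d
            if j < 0 or j >= matrix.n_sites:
                break
            gap = abs(int(matrix.positions[j]) - prev_pos)
            if gap > max_gap_bp:
                break
            e = ehh_oracle(matrix, core, allele, direction, d)
            area += 0.5 * (prev_ehh + e) * gap
            prev_ehh, prev_pos = e, int(matrix.positions[j])
            if e < ehh_cutoff:
                reached = True
                break
        if not reached:
            ok = False
    return area, ok


def sl_oracle_class(matrix, core, allele, cap=100):
    """Mean shared-interval length by an exhaustive per-pair double loop."""
    carriers = [h for h in range(matrix.n_haplotypes)
                if matrix.alleles[h, core] == allele]
    lengths = []
    for a, b in itertools.combinations(carriers, 2):
        left = 0
        j = core - 1
        while j >= 0 and left < cap and matrix.alleles[a, j] == matrix.alleles[b, j]:
            left += 1
            j -= 1
        right = 0
        j = core + 1
        while (j < matrix.n_sites and right < cap
               and matrix.alleles[a, j] == matrix.alleles[b, j]):
            right += 1
            j += 1
        lengths.append(1 + left + right)
    return sum(lengths) / len(lengths)


def make_matrix(rows, positions=None, chrom="1"):
    alleles = np.array(rows, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 1_000
    return HaplotypeMatrix(chrom=chrom, positions=np.asarray(positions),
                           alleles=alleles,
                           sample_ids=[f"S{i}" for i in range(alleles.shape[0] // 2)])


# ---------------------------------------------------------------- EHH

class TestEhh:
    def test_distance_zero_is_one(self, rng):
        m = random_matrix(rng, 8, 10)
        assert ehh(m, 4, 1, "left", 0) == 1.0
        assert ehh(m, 4, 0, "right", 0) == 1.0

    def test_identical_carriers_stay_at_one(self):
        rows = [[1, 1, 1, 1, 1]] * 3 + [[0, 0, 0, 0, 0]] * 3
        m = make_matrix(rows)
        for d in range(3):
            assert ehh(m, 2, 1, "right", d) == 1.0
            assert ehh(m, 2, 1, "left", d) == 1.0

    def test_matches_pair_oracle(self, rng):
        m = random_matrix(rng, 8, 12)
        for core in (5, 6):
            for allele in (0, 1):
                for direction in ("left", "right"):
                    got = ehh(m, core, allele, direction, 5)
                    want = ehh_oracle(m, core, allele, direction, 5)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_non_increasing_in_distance(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 10, 15)
            core = 7
            for allele in (0, 1):
                for direction in ("left", "right"):
                    max_d = core if direction == "left" else m.n_sites - 1 - core
                    values = [ehh(m, core, allele, direction, d)
                              for d in range(max_d + 1)]
                    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------- iHH

class TestIhh:
    def test_two_interval_hand_computation(self):
        # two carriers of the derived allele; they split at both flanking
        # sites, so EHH drops 1 -> 0 over one interval per side
        rows = [
            [0, 1, 0],
            [1, 1, 1],
            [0, 0, 0],
            [1, 0, 1],
        ]
        m = make_matrix(rows, positions=[1_000, 2_000, 3_500])
        area, ok = ihh(m, 1, 1)
        assert ok
        assert area == pytest.approx(0.5 * 1_000 + 0.5 * 1_500)

    def test_constant_ehh_to_edge_is_truncated(self):
        rows = [[1] * 5, [1] * 5, [0] * 5, [0] * 5]
        m = make_matrix(rows)
        _area, ok = ihh(m, 2, 1)
        assert not ok

    def test_matches_naive_oracle(self, rng):
        m = random_matrix(rng, 16, 30)
        for core in range(5, 25, 3):
            for allele in (0, 1):
                got_area, got_ok = ihh(m, core, allele)
                want_area, want_ok = ihh_oracle(m, core, allele)
                assert got_ok == want_ok
                if got_ok:
                    assert got_area == pytest.approx(want_area, abs=1e-9)


# ---------------------------------------------------------------- iHS scan

class TestIhsScan:
    def test_mirror_symmetry_gives_zero(self):
        # derived and ancestral classes carry identical flank patterns
        flank = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        rows = np.hstack([flank[:, :1], flank, np.ones((4, 1), np.uint8),
                          flank, flank[:, :1]])
        rows = np.vstack([rows, rows])
        rows[4:, 3] = 0  # ancestral class at the core, same flanks
        m = make_matrix(rows.tolist())
        scores = ihs_scan(m, min_maf=0.05)
        core = 3
        assert scores[core].ihs_raw == pytest.approx(0.0, abs=1e-12)

    def test_low_maf_skipped(self, rng):
        m = random_matrix(rng, 30, 9)
        alleles = m.alleles.copy()
        alleles[:, 4] = 0
        alleles[0, 4] = 1  # freq 1/30 < 0.05
        m2 = HaplotypeMatrix(chrom="1", positions=m.positions, alleles=alleles,
                             sample_ids=m.sample_ids)
        scores = ihs_scan(m2)
        assert scores[4].skipped_reason == SKIP_MAF
        assert math.isnan(scores[4].ihs_raw)

    def test_scan_matches_naive_oracle(self, rng):
        m = random_matrix(rng, 20, 100)
        scores = ihs_scan(m)
        checked = 0
        for k, s in enumerate(scores):
            want_d = ihh_oracle(m, k, 1) if s.skipped_reason != SKIP_MAF and 0 < k < 99 else None
            if s.skipped_reason == "none":
                d_area, d_ok = ihh_oracle(m, k, 1)
                a_area, a_ok = ihh_oracle(m, k, 0)
                assert d_ok and a_ok
                assert s.ihs_raw == pytest.approx(math.log(a_area / d_area), abs=1e-9)
                checked += 1
        assert checked > 20  # the fixture must actually exercise the scan

    def test_label_swap_negates_raw(self, rng):
        m = random_matrix(rng, 16, 40)
        scores = ihs_scan(m)
        k = next(i for i, s in enumerate(scores) if s.skipped_reason == "none")
        flipped = m.alleles.copy()
        flipped[:, k] = 1 - flipped[:, k]
        m2 = HaplotypeMatrix(chrom="1", positions=m.positions, alleles=flipped,
                             sample_ids=m.sample_ids)
        scores2 = ihs_scan(m2)
        assert scores2[k].ihs_raw == pytest.approx(-scores[k].ihs_raw, abs=1e-12)

    def test_invariant_to_haplotype_order(self, rng):
        m = random_matrix(rng, 12, 30)
        perm = rng.permutation(12)
        m2 = HaplotypeMatrix(chrom="1", positions=m.positions,
                             alleles=m.alleles[perm], sample_ids=m.sample_ids)
        raw1 = [s.ihs_raw for s in ihs_scan(m)]
        raw2 = [s.ihs_raw for s in ihs_scan(m2)]
        np.testing.assert_allclose(raw1, raw2, atol=1e-12)


# ---------------------------------------------------------------- nSL scan

class TestNslScan:
    def test_mirror_symmetry_gives_zero(self):
        flank = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        rows = np.hstack([flank, np.ones((4, 1), np.uint8), flank])
        rows = np.vstack([rows, rows])
        rows[4:, 2] = 0
        m = make_matrix(rows.tolist())
        scores = nsl_scan(m)
        assert scores[2].nsl_raw == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_spans_whole_matrix(self):
        # one haplotype pair identical over all 10 sites: SL_ab = 10 anywhere
        base = [1, 0, 1, 1, 0, 1, 0, 0, 1, 0]
        other = [[0, 1, 0, 0, 1, 0, 1, 1, 0, 1],
                 [0, 0, 0, 1, 1, 1, 0, 1, 0, 0]]
        m = make_matrix([base, base] + other)
        for core in range(10):
            assert sl_oracle_class(m, core, m.alleles[0, core]) >= 1.0
        # the identical pair alone forms the carrier class where it is
        # the only pair: pick a core where only those two carry the allele
        scores = nsl_scan(m, min_maf=0.0)
        core = 0  # alleles at site 0: base=1,1; others=0,0
        assert scores[core].sl_derived == pytest.approx(10.0)

    def test_matches_exhaustive_double_loop(self, rng):
        m = random_matrix(rng, 12, 60)
        scores = nsl_scan(m)
        for k, s in enumerate(scores):
            if s.skipped_reason != "none":
                continue
            assert s.sl_derived == pytest.approx(
                sl_oracle_class(m, k, 1), abs=1e-9)
            assert s.sl_ancestral == pytest.approx(
                sl_oracle_class(m, k, 0), abs=1e-9)
            assert s.nsl_raw == pytest.approx(
                math.log(sl_oracle_class(m, k, 0) / sl_oracle_class(m, k, 1)),
                abs=1e-9)

    def test_extension_cap_binds(self):
        rows = [[1] * 9, [1] * 9, [0] * 9, [0] * 9]
        m = make_matrix(rows)
        scores = nsl_scan(m, min_maf=0.0, max_extend_sites=2)
        # middle core: both sides capped at 2 -> SL = 1 + 2 + 2
        assert scores[4].sl_derived == pytest.approx(5.0)

    def test_label_swap_negates_raw(self, rng):
        m = random_matrix(rng, 12, 30)
        scores = nsl_scan(m)
        k = next(i for i, s in enumerate(scores) if s.skipped_reason == "none")
        flipped = m.alleles.copy()
        flipped[:, k] = 1 - flipped[:, k]
        m2 = HaplotypeMatrix(chrom="1", positions=m.positions, alleles=flipped,
                             sample_ids=m.sample_ids)
        assert nsl_scan(m2)[k].nsl_raw == pytest.approx(-scores[k].nsl_raw, abs=1e-12)


def test_sweep_elevates_ihs_near_site(sweep_scans):
    """Mean |iHS_std| at the 10 scored SNPs nearest the sweep exceeds the
    chromosome-wide mean in a majority of replicates (raw matrices)."""
    wins = 0
    evaluated = 0
    for res in sweep_scans:
        m = res["sweep_matrix"]
        truth = res["truth"]
        scores = standardize_by_freq_bins(ihs_scan(m), "ihs")
        z = np.array([s.ihs_std for s in scores])
        pos = np.array([s.pos for s in scores])
        ok = np.isfinite(z)
        if ok.sum() < 30:
            continue
        order = np.argsort(np.abs(pos - truth.sweep_pos))
        near = [i for i in order if ok[i]][:10]
        evaluated += 1
        if np.abs(z[near]).mean() > np.abs(z[ok]).mean():
            wins += 1
    assert evaluated >= 10
    assert wins > evaluated / 2


# ---------------------------------------------------------------- standardization

def make_scores(raws, freqs, chrom="1"):
    return [
        CoreSiteScore(chrom=chrom, pos=1_000 * (i + 1), derived_freq=f,
                      ihs_raw=r, nsl_raw=r)
        for i, (r, f) in enumerate(zip(raws, freqs))
    ]


class TestStandardize:
    def test_single_bin_population_sd(self):
        scores = make_scores([-1.0, 0.0, 1.0], [0.5, 0.5, 0.5])
        standardize_by_freq_bins(scores, "ihs", min_per_bin=1)
        got = [s.ihs_std for s in scores]
        sd = math.sqrt(2.0 / 3.0)  # population sd of {-1, 0, 1}
        assert got == pytest.approx([-1 / sd, 0.0, 1 / sd], abs=1e-9)
        assert got[0] == pytest.approx(-1.2247, abs=1e-4)

    def test_zero_variance_bin_left_missing(self):
        scores = make_scores([2.0, 2.0, 2.0], [0.5, 0.5, 0.5])
        standardize_by_freq_bins(scores, "ihs", min_per_bin=1)
        assert all(math.isnan(s.ihs_std) for s in scores)

    def test_two_bins_recover_z_scores(self, rng):
        low = rng.normal(3.0, 2.0, size=40)
        high = rng.normal(-1.0, 0.5, size=40)
        raws = np.concatenate([low, high])
        freqs = np.array([0.2] * 40 + [0.8] * 40)
        scores = make_scores(raws.tolist(), freqs.tolist())
        standardize_by_freq_bins(scores, "ihs", n_bins=2, min_per_bin=10)
        z_low = (low - low.mean()) / low.std()
        z_high = (high - high.mean()) / high.std()
        got = np.array([s.ihs_std for s in scores])
        np.testing.assert_allclose(got[:40], z_low, atol=1e-9)
        np.testing.assert_allclose(got[40:], z_high, atol=1e-9)

    def test_bins_have_zero_mean_unit_sd(self, rng):
        raws = rng.normal(size=300)
        freqs = rng.uniform(0.05, 0.95, size=300)
        scores = make_scores(raws.tolist(), freqs.tolist())
        standardize_by_freq_bins(scores, "nsl", n_bins=10, min_per_bin=20)
        by_bin: dict[int, list[float]] = {}
        # reconstruct effective groups from the standardized output: any
        # grouping must satisfy mean 0 / sd 1 overall per frequency bin set;
        # here we check the pooled first and second moments per raw bin group
        vals = np.array([s.nsl_std for s in scores])
        assert np.isfinite(vals).all()
        # the union of zero-mean groups has zero mean
        assert abs(vals.mean()) < 1e-9
        # with a single bin the group is recoverable: mean 0, population sd 1
        single = make_scores(raws.tolist(), freqs.tolist())
        standardize_by_freq_bins(single, "nsl", n_bins=1, min_per_bin=1)
        sv = np.array([s.nsl_std for s in single])
        assert abs(sv.mean()) < 1e-9
        assert abs(sv.std() - 1.0) < 1e-9
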