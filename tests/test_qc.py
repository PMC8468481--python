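"""QC cascade: IO round-trips, exact tests, filters, and the full run."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genemediate import qc, simulate
from genemediate.containers import GenotypeMatrix
from genemediate.plink import read_plink, write_plink
from genemediate.qc import (
    QCConfig,
    heterozygosity_filter,
    hwe_exact_test,
    ibd_filter,
    iterative_missingness_filter,
    ld_prune,
    ld_r2,
    maf,
    maf_filter,
    run_qc,
)


def _matrix(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else [1] * m,
            "pos": pos if pos is not None else list(range(100, 100 + m)),
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"f{i}" for i in range(n)], "iid": [f"i{i}" for i in range(n)], "sex": 1}
    )
    return GenotypeMatrix(dosage, snps, samples)


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1
1\t300\trs3\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
"""


class TestIO:
    def test_vcf_dosages_match_hand_count(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        g = qc.read_genotypes(str(path), format="vcf")
        # rs3 is multi-allelic and skipped; rs2 ALT freq 5/6 -> flipped to REF
        assert g.n_snps == 2
        np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(g.dosage[:, 1], [0, 0, 1])
        assert g.snps.loc[1, "a1"] == "C"  # minor allele after relabeling

    def test_plink_round_trip_preserves_everything(self, tmp_path, small_cohort):
        _, g, _ = small_cohort
        g = g.copy()
        g.dosage[3, 5] = np.nan  # exercise the missing code
        prefix = str(tmp_path / "rt")
        write_plink(g, prefix)
        back = read_plink(prefix)
        np.testing.assert_array_equal(np.isnan(back.dosage), np.isnan(g.dosage))
        np.testing.assert_array_equal(
            np.nan_to_num(back.dosage), np.nan_to_num(g.dosage)
        )
        assert back.snps["snp"].tolist() == g.snps["snp"].tolist()
        assert back.samples["iid"].tolist() == g.samples["iid"].tolist()

    def test_vcf_and_plink_agree(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        g_vcf = qc.read_genotypes(str(path), format="vcf")
        prefix = str(tmp_path / "conv")
        write_plink(g_vcf, prefix)
        g_plink = qc.read_genotypes(prefix, format="plink")
        np.testing.assert_array_equal(g_vcf.dosage, g_plink.dosage)

    def test_empty_variant_set(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
        )
        g = qc.read_genotypes(str(path), format="vcf")
        assert g.n_snps == 0 and g.n_samples == 1

    def test_bad_magic_raises(self, tmp_path):
        prefix = tmp_path / "bad"
        (prefix.with_suffix(".bed")).write_bytes(b"xxx")
        (prefix.with_suffix(".bim")).write_text("1\ts1\t0\t100\tA\tG\n")
        (prefix.with_suffix(".fam")).write_text("f1\ti1\t0\t0\t1\t-9\n")
        with pytest.raises(ValueError, match="magic"):
            read_plink(str(prefix))


class TestMaf:
    def test_printed_genotype_groups(self):
        dosage = np.array([2.0] * 5 + [1.0] * 52 + [0.0] * 577)
        assert round(float(maf(dosage)[0]), 4) == 0.0489

    def test_monomorphic_is_zero(self):
        assert maf(np.zeros(10))[0] == 0.0

    def test_all_heterozygous_is_half(self):
        assert maf(np.ones(10))[0] == 0.5

    def test_folding_above_half(self):
        assert maf(np.full(10, 2.0))[0] == 0.0


def _hwe_oracle(hom1, het, hom2):
    """Exhaustive conditional enumeration with exact rational arithmetic."""
    from math import comb

    n = hom1 + het + hom2
    na = 2 * hom1 + het  # minor allele count
    na = min(na, 2 * n - na)
    probs = {}
    for h in range(na % 2, na + 1, 2):
        ha = (na - h) // 2
        hb = n - h - ha
        if hb < 0:
            continue
        # P(h | n, na) = n! 2^h na! nb! / (ha! h! hb! (2n)!)
        from math import factorial

        num = factorial(n) * 2**h * factorial(na) * factorial(2 * n - na)
        den = factorial(ha) * factorial(h) * factorial(hb) * factorial(2 * n)
        probs[h] = num / den
    obs = probs[het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12)), probs


class TestHWE:
    def test_monomorphic_probability_one(self):
        assert hwe_exact_test(0, 0, 25) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [(3, 4, 3), (1, 10, 30), (0, 5, 45), (5, 0, 5)])
    def test_matches_exhaustive_enumeration(self, counts):
        expected, _ = _hwe_oracle(*counts)
        assert hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-10)

    @given(
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, hom1, het, hom2):
        if hom1 + het + hom2 == 0:
            return
        p = hwe_exact_test(hom1, het, hom2)
        assert 0 < p <= 1 + 1e-12
        assert p == pytest.approx(hwe_exact_test(hom2, het, hom1))

    def test_conditional_distribution_sums_to_one(self):
        _, probs = _hwe_oracle(6, 9, 12)
        assert sum(probs.values()) == pytest.approx(1.0)


class TestMissingness:
    def test_no_missing_is_identity(self):
        g = _matrix(np.ones((5, 4)))
        out, rs, rsam = iterative_missingness_filter(g)
        assert rs == [] and rsam == []
        assert out.dosage.shape == (5, 4)

    def test_high_missing_snp_removed_at_first_pass(self):
        d = np.ones((20, 3))
        d[:3, 1] = np.nan  # 15% missing
        out, rs, _ = iterative_missingness_filter(_matrix(d))
        assert rs == ["s1"]

    def test_snp_first_order_spares_borderline_sample(self):
        # sample i0 is missing only on the bad SNP: filtering variants first
        # rescues it, while a samples-first oracle would drop it
        d = np.zeros((6, 6))
        d[:, 5] = [np.nan, np.nan, np.nan, 0, 0, 0]  # SNP s5: 50% missing
        d[0, 5] = np.nan  # sample i0 misses only s5: rate 1/6 > 0.1
        g = _matrix(d)
        out, rs, rsam = iterative_missingness_filter(g, (0.1,))
        assert rs == ["s5"] and rsam == []
        # reversed-order oracle: samples filtered before variants
        sample_miss = np.isnan(d).mean(axis=1)
        dropped_first = {f"i{i}" for i in np.flatnonzero(sample_miss > 0.1)}
        assert "i0" in dropped_first

    def test_everything_removed_raises(self):
        d = np.full((3, 3), np.nan)
        d[0, 0] = 1.0
        with pytest.raises(qc.EmptyResultError):
            iterative_missingness_filter(_matrix(d), (0.01,))


class TestLD:
    def test_identical_and_flipped(self):
        x = np.array([0.0, 1, 2, 1, 0])
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        x = np.array([0.0, 1, 2, 1])
        y = np.array([0.0, 0, 2, 2])
        # deviations (-1,0,1,0) and (-1,-1,1,1): r = 0.5/sqrt(0.5*1) -> r2 = 0.5
        assert ld_r2(x, y) == pytest.approx(0.5)

    def test_zero_variance_flagged(self):
        assert np.isnan(ld_r2(np.array([1.0, 1, 1]), np.array([0.0, 1, 2])))

    def test_uncorrelated_all_retained(self, rng):
        d = rng.integers(0, 3, size=(400, 10)).astype(float)
        kept = ld_prune(_matrix(d), window=5, step=2, r2_max=0.2)
        assert len(kept) == 10

    def test_duplicate_pair_keeps_one(self, rng):
        col = rng.integers(0, 3, size=200).astype(float)
        d = np.column_stack([col, col, rng.integers(0, 3, 200)])
        kept = ld_prune(_matrix(d), window=5, step=2, r2_max=0.2)
        assert list(kept) == [0, 2]

    def test_matches_bruteforce_fixed_point_oracle(self, rng):
        # 20 SNPs with LD confined to within-window distances
        base = rng.integers(0, 3, size=(300, 20)).astype(float)
        for j in (1, 4, 9, 13):  # make some SNPs near-copies of a neighbor
            mask = rng.random(300) < 0.9
            base[mask, j] = base[mask, j - 1]
        g = _matrix(base)
        kept = ld_prune(g, window=5, step=2, r2_max=0.2)

        window = 5
        removed = set()
        while True:
            pair = None
            for i in range(20):
                if i in removed:
                    continue
                for j in range(i + 1, min(i + window, 20)):
                    if j in removed:
                        continue
                    if ld_r2(base[:, i], base[:, j]) > 0.2:
                        pair = (i, j)
                        break
                if pair:
                    break
            if pair is None:
                break
            removed.add(pair[1])  # no missingness: later member removed
        oracle = [i for i in range(20) if i not in removed]
        assert list(kept) == oracle


class TestHeterozygosity:
    def test_hwe_simulated_mean_near_zero(self, rng):
        p = rng.uniform(0.1, 0.5, size=500)
        d = (rng.random((300, 500)) < p).astype(float) + (
            rng.random((300, 500)) < p
        ).astype(float)
        f = qc.heterozygosity_f(_matrix(d))
        assert abs(f.mean()) < 3 / np.sqrt(300)

    def test_fully_homozygous_sample_removed(self, rng):
        p = rng.uniform(0.2, 0.5, size=400)
        d = (rng.random((100, 400)) < p).astype(float) + (
            rng.random((100, 400)) < p
        ).astype(float)
        d[0] = np.round(d[0] / 2) * 2  # force sample 0 fully homozygous
        keep, f = heterozygosity_filter(_matrix(d), 3.0)
        assert 0 not in keep
        assert f[0] > 0.5

    def test_infinite_bound_is_identity(self, rng):
        d = rng.integers(0, 3, size=(50, 100)).astype(float)
        keep, _ = heterozygosity_filter(_matrix(d), np.inf)
        assert len(keep) == 50


class TestIBD:
    def _unrelated(self, rng, n=60, m=1500):
        p = rng.uniform(0.1, 0.5, size=m)
        return ((rng.random((n, m)) < p).astype(float)
                + (rng.random((n, m)) < p).astype(float))

    def test_duplicate_sample_detected_and_removed(self, rng):
        d = self._unrelated(rng)
        d[1] = d[0]
        g = _matrix(d)
        pihat = qc.ibd_pihat(g)
        assert pihat[0, 1] == pytest.approx(1.0, abs=0.05)
        keep, _ = ibd_filter(g, 0.1875)
        assert len(keep) == 59 and not (0 in keep and 1 in keep)

    def test_unrelated_pihat_near_zero(self, rng):
        d = self._unrelated(rng)
        pihat = qc.ibd_pihat(_matrix(d))
        iu = np.triu_indices(60, 1)
        assert pihat[iu].mean() < 0.05

    def test_parent_offspring_pair_broken(self, rng):
        m = 1500
        p = rng.uniform(0.1, 0.5, size=m)
        h = (rng.random((4, m)) < p).astype(float)  # 4 haplotypes
        parent = h[0] + h[1]
        child = h[0] + (rng.random(m) < p).astype(float)  # shares haplotype 0
        others = self._unrelated(rng, n=40, m=m)
        d = np.vstack([parent, child, others])
        g = _matrix(d)
        pihat = qc.ibd_pihat(g)
        assert pihat[0, 1] == pytest.approx(0.5, abs=0.1)
        keep, _ = ibd_filter(g, 0.1875)
        assert not (0 in keep and 1 in keep)

    def test_pihat_bounded(self, rng):
        d = self._unrelated(rng, n=30, m=800)
        pihat = qc.ibd_pihat(_matrix(d))
        assert pihat.min() >= 0.0 and pihat.max() <= 1.0


class TestRunQC:
    def test_clean_data_survives(self, small_cohort):
        _, g, _ = small_cohort
        out, report = run_qc(g, QCConfig(), mode="all")
        assert report.removed(kind="snp") == []
        # the 3-SD heterozygosity cut has a ~0.3% expected false-positive rate
        assert len(report.removed(kind="sample")) <= max(2, int(0.01 * g.n_samples))

    def test_injected_violations_removed_exactly(self):
        spec = simulate.SimulationSpec(
            n_samples=400, n_gene_snps=10, n_background_snps=150,
            n_chromosomes=4, n_related_pairs=0, seed=41,
        )
        g = simulate.gen_genotypes(spec)
        bad, manifest = simulate.inject_qc_violations(
            g, n_low_maf=5, n_hwe_violating=3, n_high_missing_snps=4,
            n_high_missing_samples=3, seed=8,
        )
        out, report = run_qc(bad, QCConfig(), mode="all")
        assert sorted(report.removed("maf")) == manifest["low_maf"]
        assert sorted(report.removed("missingness", "snp")) == manifest["high_missing_snps"]
        assert sorted(report.removed("missingness", "sample")) == manifest["high_missing_samples"]
        assert sorted(report.removed("hwe")) == manifest["hwe"]

    def test_mode_unrelated_breaks_related_pair(self):
        spec = simulate.SimulationSpec(
            n_samples=200, n_gene_snps=10, n_background_snps=1500,
            n_chromosomes=6, n_related_pairs=1, seed=43,
        )
        g = simulate.gen_genotypes(spec)
        out_all, _ = run_qc(g, QCConfig(), mode="all")
        out_unrel, _ = run_qc(g, QCConfig(), mode="unrelated")
        assert out_all.n_samples - out_unrel.n_samples == 1

    def test_idempotent_on_own_output(self, small_cohort):
        _, g, _ = small_cohort
        once, _ = run_qc(g, QCConfig(), mode="all")
        twice, report2 = run_qc(once, QCConfig(), mode="all")
        assert report2.removed(kind="snp") == []
        assert twice.n_samples >= int(0.995 * once.n_samples)

    def test_snp_filters_do_not_alter_genotypes(self, small_cohort):
        _, g, _ = small_cohort
        out, _ = run_qc(g, QCConfig(), mode="all")
        kept_snps = [g.snp_index(s) for s in out.snp_ids]
        kept_samples = [int(np.flatnonzero(g.sample_ids == i)[0]) for i in out.sample_ids]
        np.testing.assert_array_equal(
            np.nan_to_num(out.dosage, nan=-1),
            np.nan_to_num(g.dosage[np.ix_(kept_samples, kept_snps)], nan=-1),
        )


def test_bad_schedule_rejected():
    with pytest.raises(ValueError, match="decreasing"):
        QCConfig(missing_schedule=(0.01, 0.05))
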