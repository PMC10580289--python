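import numpy as np
import pandas as pd
import pytest

from _oracles import brute_hwe_exact_p, naive_call_roh
from autozyg import roh as rh
from autozyg.exceptions import ConfigError, PipelineError, StructuralError
from autozyg.genome import GeneticMap
from autozyg.roh import ROHCallParams, call_roh, compute_froh, hwe_exact_p, site_qc


def _site_table(pos, chrom="1"):
    pos = np.asarray(pos)
    return pd.DataFrame({"chrom": chrom, "pos_bp": pos, "pos_cm": pos / 1e6})


class TestSiteQC:
    def test_perfect_hwe_site_retained(self):
        G = np.repeat([0, 1, 2], [25, 50, 25]).astype(np.int8).reshape(-1, 1)
        sites = _site_table([100])
        assert hwe_exact_p(50, 25, 25) == pytest.approx(1.0, abs=0.05)
        Gq, sq, report = site_qc(G, sites, maf_min=0.05, hwe_p_min=1e-6)
        assert len(sq) == 1 and report.empty

    def test_monomorphic_removed_and_reported(self):
        G = np.zeros((10, 2), dtype=np.int8)
        G[:, 1] = [0, 1, 1, 2, 0, 1, 2, 0, 1, 2]
        sites = _site_table([100, 200])
        Gq, sq, report = site_qc(G, sites, maf_min=0.05)
        assert sq["pos_bp"].tolist() == [200]
        assert report.iloc[0]["reason"] == "maf"

    def test_extreme_het_deficit_fails_hwe(self):
        col = np.repeat([0, 2], [50, 50]).astype(np.int8)
        G = col.reshape(-1, 1)
        sites = _site_table([100])
        with pytest.raises(PipelineError):  # the only site is removed
            site_qc(G, sites, maf_min=0.05, hwe_p_min=1e-6)

    def test_hwe_subset_restricts_test(self):
        # site 0: balanced over all samples but het-free in the subgroup;
        # site 1: in equilibrium everywhere
        site0 = np.concatenate([np.repeat([0, 2], [25, 25]), np.repeat(1, 50)])
        site1 = np.tile(np.repeat([0, 1, 2], [25, 50, 25]), 1)
        G = np.column_stack([site0, site1]).astype(np.int8)
        sites = _site_table([100, 200])
        mask = np.zeros(100, dtype=bool)
        mask[:50] = True
        _, sq, report = site_qc(
            G, sites, maf_min=0.0, hwe_p_min=1e-6, hwe_subset=mask
        )
        assert report["pos_bp"].tolist() == [100]
        assert report["reason"].tolist() == ["hwe"]
        assert sq["pos_bp"].tolist() == [200]
        # without the subgroup restriction the site passes
        _, sq2, _ = site_qc(G, sites, maf_min=0.0, hwe_p_min=1e-6)
        assert len(sq2) == 2

    @pytest.mark.parametrize(
        "counts", [(50, 25, 25), (0, 50, 50), (10, 5, 85), (3, 1, 16), (7, 0, 3), (1, 0, 0)]
    )
    def test_exact_hwe_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(brute_hwe_exact_p(*counts), abs=1e-12)


class TestCallROHTrivial:
    def test_clean_60_snp_run_over_2mb(self):
        pos = np.linspace(1, 2_000_000, 60).astype(np.int64)
        segs = call_roh(np.zeros((1, 60), np.int8), _site_table(pos))
        assert len(segs) == 1
        row = segs.iloc[0]
        assert (row["start_bp"], row["end_bp"], row["n_snps"]) == (1, 2_000_000, 60)

    def test_same_run_over_1mb_fails_min_kb(self):
        pos = np.linspace(1, 1_000_000, 60).astype(np.int64)
        assert call_roh(np.zeros((1, 60), np.int8), _site_table(pos)).empty

    def test_sparse_run_fails_density(self):
        pos = np.linspace(1, 6_000_000, 60).astype(np.int64)  # 100 kb/SNP
        assert call_roh(np.zeros((1, 60), np.int8), _site_table(pos)).empty

    def test_large_gap_splits_run(self):
        pos = np.concatenate(
            [np.linspace(1, 2_000_000, 60), np.linspace(3_500_000, 5_500_000, 60)]
        ).astype(np.int64)
        segs = call_roh(np.zeros((1, 120), np.int8), _site_table(pos))
        assert len(segs) == 2
        assert segs["n_snps"].tolist() == [60, 60]

    def test_unsorted_input_rejected(self):
        pos = np.array([100, 50, 200])
        with pytest.raises(StructuralError, match="sorted"):
            call_roh(np.zeros((1, 3), np.int8), _site_table(pos))

    def test_map_must_cover_sites(self):
        pos = np.linspace(1, 2_000_000, 60).astype(np.int64)
        gmap = GeneticMap.uniform(1, 1_000_000)
        with pytest.raises(ValueError, match="outside"):
            call_roh(np.zeros((1, 60), np.int8), _site_table(pos), gmap)


class TestCallROHOracle:
    """The vectorized caller must agree exactly with a literal quadratic
    re-implementation of the window rules."""

    PARAMS = ROHCallParams(
        window_snp=10,
        min_snp=10,
        min_kb=100.0,
        max_gap_kb=200.0,
        density_kb_per_snp=50.0,
        window_missing=2,
        window_het=1,
    )

    def test_het_interrupted_run_matches_oracle(self):
        rng = np.random.default_rng(0)
        g = np.zeros(120, dtype=np.int8)
        g[[30, 60]] = 1  # two heterozygotes 30 SNPs apart
        pos = np.sort(rng.choice(np.arange(1, 3_000_000, 20_000), 120, replace=False))
        got = call_roh(g, _site_table(pos), params=self.PARAMS)
        exp = naive_call_roh(g, pos, self.PARAMS)
        assert [
            (r.start_bp, r.end_bp, r.n_snps) for r in got.itertuples()
        ] == exp

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            s = int(rng.integers(5, 200))
            g = rng.choice(
                np.array([0, 1, 2, -1], np.int8), size=s, p=[0.55, 0.2, 0.2, 0.05]
            )
            pos = np.sort(
                rng.choice(np.arange(1, 5_000_001, 1000), size=s, replace=False)
            )
            got = call_roh(g, _site_table(pos), params=self.PARAMS)
            exp = naive_call_roh(g, pos, self.PARAMS)
            assert [
                (r.start_bp, r.end_bp, r.n_snps) for r in got.itertuples()
            ] == exp

    def test_adding_het_never_lengthens_segments(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            s = 150
            g = rng.choice(np.array([0, 2], np.int8), size=s)
            pos = np.arange(1, s * 20_000, 20_000)[:s]
            before = call_roh(g, _site_table(pos), params=self.PARAMS)
            if before.empty:
                continue
            row = before.iloc[0]
            inside = np.flatnonzero(
                (pos >= row["start_bp"]) & (pos <= row["end_bp"])
            )
            g2 = g.copy()
            g2[inside[len(inside) // 2]] = 1
            after = call_roh(g2, _site_table(pos), params=self.PARAMS)
            max_after = after["length_bp"].max() if len(after) else 0
            assert max_after <= before["length_bp"].max()
            total_after = after["length_bp"].sum() if len(after) else 0
            assert total_after <= before["length_bp"].sum()


class TestFroh:
    def test_no_segments_is_zero(self):
        assert compute_froh([]) == 0.0

    def test_forced_arithmetic(self):
        seg = rh.ROHSegment("s", "1", 1, 168_750_000, 99)
        assert compute_froh([seg]) == pytest.approx(0.0625)

    def test_cap_and_warning(self):
        segs = [
            rh.ROHSegment("s", "1", 1, 1_600_000_000, 9),
            rh.ROHSegment("s", "2", 1, 1_200_000_000, 9),
        ]
        with pytest.warns(UserWarning, match="capping"):
            assert compute_froh(segs) == 1.0

    def test_overlap_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s", "s"],
                "chrom": ["1", "1"],
                "start_bp": [1, 500],
                "end_bp": [1000, 1500],
                "length_bp": [1000, 1001],
            }
        )
        with pytest.raises(ConfigError, match="overlap"):
            compute_froh(df)

    def test_froh_tracks_true_autozygosity(self, panel, fc_offspring):
        """Marker-based F_ROH correlates strongly with the realized
        identity-by-descent fraction for first-cousin offspring."""
        genos, truth = fc_offspring
        segs = call_roh(
            genos, panel.sites, panel.gmap, sample_ids=truth["sample_id"].tolist()
        )
        froh = rh.froh_per_sample(
            segs, truth["sample_id"].tolist(), panel.gmap.total_bp
        )
        r = np.corrcoef(froh.to_numpy(), truth["realized_autozygous_fraction"])[0, 1]
        assert r > 0.95
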