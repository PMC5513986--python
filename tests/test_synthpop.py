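"""Generator contracts: determinism, file consistency, and signal structure."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from domesticscan import popstats, seqio, synthpop
from domesticscan.synthpop import SimulationConfig, simulate_gene, generate_dataset


def small_config(**kw):
    base = dict(n_wild=6, n_landrace=7, cds_length=300, rng_seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_wild": 1}, {"n_landrace": 0}, {"cds_length": 100},
        {"theta": -1.0}, {"bottleneck_factor": 0.0},
        {"bottleneck_factor": 1.5}, {"selection_rod": 0.5},
        {"frac_selected": 1.2},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(synthpop.ConfigurationError):
            small_config(**kw)


class TestSimulateGene:
    def test_theta_zero_no_polymorphism(self):
        cfg = small_config(theta=0.0)
        m = simulate_gene(cfg, False, np.random.default_rng(0))
        assert m.n_sites == 0
        assert m.n_samples == 13

    def test_sites_biallelic_and_sorted(self):
        cfg = small_config(theta=0.02)
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = simulate_gene(cfg, True, rng)
            assert np.all(np.diff(m.positions) > 0)
            assert set(np.unique(m.alleles)) <= {0, 1}
            for j in range(m.n_sites):  # both alleles present
                col = m.alleles[:, j]
                assert 0 < col.sum() < len(col)
            for r, a in zip(m.ref_alleles, m.alt_alleles):
                assert r != a

    def test_selected_rod_exceeds_neutral_rod(self):
        # median realized RoD of selected genes above matched neutral genes
        cfg = SimulationConfig(selection_rod=20.0, bottleneck_factor=0.5,
                               cds_length=600, rng_seed=0)
        rng = np.random.default_rng(12)
        wild = cfg.sample_ids[:cfg.n_wild]
        land = cfg.sample_ids[cfg.n_wild:]

        def rods(selected, n=200):
            out = []
            for _ in range(n):
                m = simulate_gene(cfg, selected, rng)
                pw = popstats.theta_pi(m, wild)
                pl = popstats.theta_pi(m, land)
                if not (math.isnan(pw) or math.isnan(pl)):
                    r = popstats.rod(pw, pl)
                    if math.isfinite(r):
                        out.append(r)
            return np.array(out)

        assert np.median(rods(True)) > np.median(rods(False))

    def test_landrace_diversity_monotone_in_bottleneck_and_rod(self):
        # stochastic monotonicity: mean landrace pi decreases as the
        # bottleneck deepens and as selection_rod grows (rank correlation)
        rng = np.random.default_rng(42)

        def mean_pi_l(b, rod, selected, n=60):
            cfg = SimulationConfig(bottleneck_factor=b, selection_rod=rod,
                                   cds_length=600, rng_seed=0)
            land = cfg.sample_ids[cfg.n_wild:]
            vals = [popstats.theta_pi(simulate_gene(cfg, selected, rng), land)
                    for _ in range(n)]
            return np.nanmean(vals)

        bvals = [0.1, 0.3, 0.6, 1.0]
        pis = [mean_pi_l(b, 1.0, False) for b in bvals]
        rho_b = sps.spearmanr(bvals, pis).statistic
        assert rho_b > 0.9  # diversity rises with landrace size

        rods = [1.0, 3.0, 10.0, 30.0]
        pis_r = [mean_pi_l(0.5, r, True) for r in rods]
        rho_r = sps.spearmanr(rods, pis_r).statistic
        assert rho_r < -0.9  # diversity falls with selection strength


class TestGenerateDataset:
    def test_same_seed_identical_checksums(self, tmp_path):
        cfg = small_config(n_candidate_genes=4, n_neutral_genes=4)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for name in ["reference.fasta", "variants.vcf", "groups.tsv",
                     "annotation.tsv", "expression.tsv", "tissues.tsv",
                     "truth.tsv"]:
            assert (synthpop.file_checksum(tmp_path / "a" / name)
                    == synthpop.file_checksum(tmp_path / "b" / name)), name

    def test_frac_selected_zero_truth_has_none(self, tmp_path):
        cfg = small_config(n_candidate_genes=5, n_neutral_genes=3,
                           frac_selected=0.0)
        truth = generate_dataset(cfg, tmp_path)
        assert not any(rec["is_selected"] for rec in truth.values())

    def test_vcf_samples_and_positions_consistent(self, small_panel):
        d = small_panel["dir"]
        cfg = small_panel["config"]
        ann = pd.read_csv(d / "annotation.tsv", sep="\t")
        lengths = dict(zip(ann["gene_id"], ann["cds_length"]))
        from cyvcf2 import VCF
        vcf = VCF(str(d / "variants.vcf"))
        assert len(vcf.samples) == cfg.n_wild + cfg.n_landrace
        for rec in vcf:
            assert 1 <= rec.POS <= lengths[rec.CHROM]

    def test_truth_covers_every_gene_once(self, small_panel):
        truth = small_panel["truth"]
        ann = pd.read_csv(small_panel["dir"] / "annotation.tsv", sep="\t")
        assert set(truth) == set(ann["gene_id"])

    def test_expression_has_required_tissue_design(self, small_panel):
        tissues = pd.read_csv(small_panel["dir"] / "tissues.tsv", sep="\t",
                              header=None, names=["sample", "klass"])
        assert (tissues["klass"] == "seed").sum() >= 2
        assert (tissues["klass"] == "non_seed").sum() >= 5

    def test_roundtrip_alleles_exact(self, tmp_path):
        # reading the files back reproduces the simulator's matrices
        cfg = small_config(n_candidate_genes=3, n_neutral_genes=2,
                           theta=0.01, rng_seed=9)
        generate_dataset(cfg, tmp_path)
        ds = seqio.read_inputs(tmp_path / "reference.fasta",
                               tmp_path / "variants.vcf",
                               tmp_path / "groups.tsv",
                               tmp_path / "annotation.tsv")
        # regenerate in memory with the same seed: must agree site-for-site
        rng = np.random.default_rng(cfg.rng_seed)
        n_sel = int(round(cfg.frac_selected * cfg.n_candidate_genes))
        order = [(f"cand{i:04d}", i < n_sel) for i in range(3)] + \
                [(f"neut{i:04d}", False) for i in range(2)]
        for gid, selected in order:
            ref = synthpop.random_cds(cfg.cds_length, rng)
            m = simulate_gene(cfg, selected, rng, gene_id=gid, reference_cds=ref)
            got = ds.matrices[gid]
            assert np.array_equal(got.positions, m.positions), gid
            assert np.array_equal(got.alleles, m.alleles), gid
            assert got.ref_alleles == m.ref_alleles
            assert got.alt_alleles == m.alt_alleles
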