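"""Tests of the synthetic-data generator: determinism, planted structure, moments."""

import numpy as np
import pandas as pd
import pytest

from cytocross import synthetic
from cytocross.sites import count_fragments
from cytocross.stats import welch_t
from cytocross.synthetic import (
    NFKB_PWM,
    STAT3_PWM,
    SyntheticConfig,
    demo_config,
    make_dataset,
    make_truth,
    simulate_chip_reads,
    simulate_expression,
    simulate_genome_sites,
)
from cytocross.context import scan_pwm


class TestTruth:
    def test_proportions_give_exact_counts(self):
        cfg = SyntheticConfig(n_genes=1000, proportions={"synergistic": 0.05})
        truth = make_truth(cfg, seed=3)
        assert (truth.genes["label"] == "synergistic").sum() == 50
        assert (truth.genes["label"] == "unchanged").sum() == 950

    def test_same_seed_identical_tables(self):
        cfg = demo_config()
        assert make_truth(cfg, 5).to_json() == make_truth(cfg, 5).to_json()

    def test_synergy_dual_multiplier_formula(self):
        cfg = SyntheticConfig(
            n_genes=10,
            proportions={"synergistic": 1.0},
            single_multipliers={"synergistic": (2.0, 3.0), "unchanged": (1.0, 1.0)},
            synergy_ratio=1.5,
        )
        truth = make_truth(cfg, 0)
        assert np.allclose(truth.genes["m_dual"], 6.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_truth(SyntheticConfig(proportions={"synergistic": -0.1}), 0)
        with pytest.raises(ValueError):
            make_truth(SyntheticConfig(proportions={"synergistic": 0.9, "additive_dual": 0.9}), 0)
        with pytest.raises(ValueError):
            make_truth(SyntheticConfig(dispersion=-1.0), 0)

    def test_assisted_lambda_ratio_planted(self, demo_truth):
        a = demo_truth.sites[demo_truth.sites["label"] == "assisted"]
        ratio = a["lambda_STAT3_DUAL"] / a["lambda_STAT3_IL6"]
        assert np.allclose(ratio, demo_truth.meta["config"]["assisted_ratio"])


class TestExpression:
    def test_condition_mean_tracks_multiplier_poisson(self):
        cfg = SyntheticConfig(
            n_genes=600,
            proportions={"antagonized_by_il6": 0.9},
            single_multipliers={"antagonized_by_il6": (2.0, 1.0), "unchanged": (1.0, 1.0)},
            dispersion=0.0,
            depth_factor_range=(1.0, 1.0),
        )
        truth = make_truth(cfg, 1)
        m = simulate_expression(truth, 1)
        planted = truth.genes["label"] == "antagonized_by_il6"
        il1_cols = [s for s in m.counts.columns if s.startswith("IL1")]
        ratio = (
            m.counts.loc[planted, il1_cols].mean(axis=1)
            / truth.genes.loc[planted, "baseline"]
        )
        n = planted.sum() * len(il1_cols)
        se = np.sqrt(2.0 / (truth.genes.loc[planted, "baseline"].mean() * n)) * 2
        assert abs(ratio.mean() - 2.0) < 3 * max(se, 0.01)

    def test_unchanged_gene_condition_means_equal(self):
        cfg = SyntheticConfig(n_genes=400, proportions={}, dispersion=0.05,
                              depth_factor_range=(1.0, 1.0), n_reps=10)
        truth = make_truth(cfg, 2)
        m = simulate_expression(truth, 2)
        cond_means = {
            c: m.counts[[s for s in m.counts.columns if s.startswith(c + "_")]]
            .mean(axis=1)
            for c in ("NT", "IL1", "IL6", "DUAL")
        }
        base = truth.genes["baseline"]
        for c, v in cond_means.items():
            assert abs((v / base).mean() - 1.0) < 0.02

    def test_nb_variance_mean_relation(self):
        alpha = 0.2
        cfg = SyntheticConfig(
            n_genes=400,
            proportions={},
            dispersion=alpha,
            n_reps=50,
            depth_factor_range=(1.0, 1.0),
            unchanged_baseline_range=(200.0, 200.0),
        )
        truth = make_truth(cfg, 3)
        m = simulate_expression(truth, 3)
        nt = m.counts[[s for s in m.counts.columns if s.startswith("NT_")]]
        ratio = (nt.var(axis=1) / nt.mean(axis=1)).mean()
        assert ratio == pytest.approx(1 + alpha * 200.0, rel=0.1)

    def test_counts_are_finite_nonnegative_ints(self, demo_dataset):
        arr = demo_dataset.counts.counts.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer) and (arr >= 0).all()


class TestGenomeSites:
    def test_sites_within_bounds_and_disjoint(self, demo_dataset):
        st = demo_dataset.truth.sites
        clen = demo_dataset.truth.meta["chrom_lengths"]["chr1"]
        assert (st["start"] >= 0).all() and (st["end"] <= clen).all()
        s = st.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_planted_nfkb_motif_recovered_at_offset(self, demo_dataset):
        st = demo_dataset.truth.sites
        seq = demo_dataset.genome["chr1"]
        planted = st[st["nfkb_offset"].notna()].head(10)
        for _, row in planted.iterrows():
            start = int(row["center"] + row["nfkb_offset"])
            window = seq[start : start + len(NFKB_PWM)]
            hits = scan_pwm(window, NFKB_PWM, NFKB_PWM.max_score - 1e-6)
            assert (hits["position"] == 0).any()

    def test_motif_probabilities_extreme_partition(self):
        cfg = demo_config()
        cfg.p_motif_assisted = 1.0
        cfg.p_motif_unassisted = 0.0
        truth = make_truth(cfg, 9)
        simulate_genome_sites(truth, 9)
        st = truth.sites
        assert st.loc[st["label"] == "assisted", "nfkb_offset"].notna().all()
        assert st.loc[st["label"] != "assisted", "nfkb_offset"].isna().all()

    def test_stat3_motif_penalized_at_assisted(self, demo_dataset):
        st = demo_dataset.truth.sites
        cons = STAT3_PWM.consensus()
        assisted = st[st["label"] == "assisted"]["stat3_motif"]
        unassisted = st[st["label"] == "unassisted"]["stat3_motif"]
        assert (unassisted == cons).all()
        assert (assisted != cons).all()

    def test_each_synergistic_gene_has_close_assisted_site(self, demo_dataset):
        truth = demo_dataset.truth
        syn = truth.genes[truth.genes["label"] == "synergistic"]
        centers = truth.sites.loc[truth.sites["label"] == "assisted", "center"].to_numpy()
        lo, hi = truth.meta["config"]["tss_offset_range"]
        for tss in syn["tss"]:
            assert np.abs(centers - tss).min() <= hi


class TestChipReads:
    def test_zero_lambda_zero_background_empty(self):
        cfg = demo_config()
        cfg.background_rate_per_bp = 0.0
        cfg.chrm_reads = 0
        truth = make_truth(cfg, 4)
        simulate_genome_sites(truth, 4)
        for col in truth.sites.columns:
            if col.startswith("lambda_"):
                truth.sites[col] = 0.0
        rs = simulate_chip_reads(truth, "STAT3", "DUAL", 4)
        assert len(rs.reads) == 0

    def test_poisson_fragment_ratio_matches_planted(self):
        cfg = SyntheticConfig(
            n_sites=300,
            n_assisted=250,
            n_background_sites=0,
            background_rate_per_bp=0.0,
            chrm_reads=0,
        )
        truth = make_truth(cfg, 5)
        simulate_genome_sites(truth, 5)
        rs6 = simulate_chip_reads(truth, "STAT3", "IL6", 5)
        rsd = simulate_chip_reads(truth, "STAT3", "DUAL", 5)
        peaks = truth.sites[truth.sites["label"] == "assisted"][["chrom", "start", "end"]]
        peaks = peaks.assign(name=peaks.index).reset_index(drop=True)
        cl = {k: int(v) for k, v in truth.meta["chrom_lengths"].items()}
        cm = count_fragments([rs6, rsd], peaks, 150, chrom_lengths=cl)
        ratio = cm.counts[rsd.sample_id].mean() / cm.counts[rs6.sample_id].mean()
        assert ratio == pytest.approx(cfg.assisted_ratio, rel=0.10)

    def test_dn_ablated_sites_match_background(self, demo_dataset):
        truth = demo_dataset.truth
        cl = {k: int(v) for k, v in truth.meta["chrom_lengths"].items()}
        rs = demo_dataset.readsets[("STAT3", "DN_DUAL")][0]
        ablated = truth.sites[truth.sites["dn_ablated"]]
        peaks = ablated[["chrom", "start", "end"]].assign(name=ablated.index)
        cm = count_fragments([rs], peaks, 150, chrom_lengths=cl)
        width = int((ablated["end"] - ablated["start"]).iloc[0])
        rng = np.random.default_rng(0)
        occupied = truth.sites[["start", "end"]].to_numpy()
        bg_counts = []
        starts = rng.integers(0, cl["chr1"] - width, size=400)
        keep = ~np.array(
            [((s < occupied[:, 1]) & (s + width > occupied[:, 0])).any() for s in starts]
        )
        bg = pd.DataFrame(
            {"chrom": "chr1", "start": starts[keep], "end": starts[keep] + width}
        )
        bg["name"] = [f"bg{i}" for i in range(len(bg))]
        cm_bg = count_fragments([rs], bg.reset_index(drop=True), 150, chrom_lengths=cl)
        t, p = welch_t(cm.counts.iloc[:, 0], cm_bg.counts.iloc[:, 0])
        assert p > 0.01

    def test_unknown_assay_or_condition_rejected(self, demo_truth):
        with pytest.raises(ValueError):
            simulate_chip_reads(demo_truth, "H3K9me3", "NT", 0)
        with pytest.raises(ValueError):
            simulate_chip_reads(demo_truth, "STAT3", "TRIPLE", 0)


class TestDatasetDeterminism:
    def test_identical_seed_byte_identical_outputs(self):
        cfg = demo_config()
        d1 = make_dataset(cfg, seed=11, assays=("STAT3",))
        d2 = make_dataset(demo_config(), seed=11, assays=("STAT3",))
        assert d1.truth.to_json() == d2.truth.to_json()
        assert d1.counts.counts.to_csv() == d2.counts.counts.to_csv()
        k = ("STAT3", "DUAL")
        assert d1.readsets[k][0].reads.to_csv() == d2.readsets[k][0].reads.to_csv()
        assert d1.genome["chr1"] == d2.genome["chr1"]

    def test_different_seeds_differ(self):
        cfg = demo_config()
        d1 = make_dataset(cfg, seed=11, assays=())
        d2 = make_dataset(demo_config(), seed=12, assays=())
        assert d1.counts.counts.to_csv() != d2.counts.counts.to_csv()
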