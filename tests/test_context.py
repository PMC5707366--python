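"""Tests for nearest-TSS logic, matching, PWM scanning and proximity profiles."""

import numpy as np
import pandas as pd
import pytest

from cytocross import synthetic as synthetic_mod

from cytocross.context import (
    PWM,
    best_motif_score,
    match_additive_set,
    motif_proximity_profile,
    nearest_gene_class_counts,
    nearest_site_histogram,
    nearest_tss,
    nearest_tss_all,
    scan_pwm,
)


def _ann(tss_list, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(len(tss_list))],
            "chrom": chrom,
            "tss": tss_list,
            "strand": "+",
        }
    )


def _sites(centers, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "center": centers,
            "start": [c - 10 for c in centers],
            "end": [c + 10 for c in centers],
            "name": [f"s{i}" for i in range(len(centers))],
        }
    )


class TestNearestTSS:
    def test_simple_distance(self):
        gene, dist = nearest_tss(3500, "chr1", _ann([1000]))
        assert (gene, dist) == ("g000", 2500)

    def test_exact_hit_distance_zero(self):
        gene, dist = nearest_tss(1000, "chr1", _ann([1000, 5000]))
        assert (gene, dist) == ("g000", 0)

    def test_tie_broken_lexicographically(self):
        ann = _ann([900, 1100])  # both 100 away from 1000
        gene, dist = nearest_tss(1000, "chr1", ann)
        assert gene == "g000" and dist == 100

    def test_missing_chromosome_warns_unassigned(self):
        with pytest.warns(UserWarning):
            gene, dist = nearest_tss(5, "chrX", _ann([100]))
        assert gene is None

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        ann = _ann(sorted(int(x) for x in rng.integers(0, 1_000_000, 300)))
        sites = _sites([int(x) for x in rng.integers(0, 1_000_000, 500)])
        got = nearest_tss_all(sites, ann)
        for (_, s), (_, g) in zip(sites.iterrows(), got.iterrows()):
            d = (ann["tss"] - s["center"]).abs()
            dmin = d.min()
            best = sorted(ann.loc[d == dmin, "gene_id"])[0]
            assert g["gene_id"] == best and g["distance"] == dmin


class TestHistogram:
    def test_halfopen_binning(self):
        hist = nearest_site_histogram(_ann([0]), _sites([2500]), binsize=2500, maxdist=10_000)
        assert hist.loc[hist["bin_left"] == 2500, "n_genes"].iloc[0] == 1
        assert hist["n_genes"].sum() == 1

    def test_only_nearest_site_counts(self):
        hist = nearest_site_histogram(
            _ann([1000]), _sites([1100, 1500, 9000]), binsize=500, maxdist=20_000
        )
        assert hist["n_genes"].sum() == 1
        assert hist.loc[hist["bin_left"] == 0, "n_genes"].iloc[0] == 1

    def test_conservation_and_maxdist_exclusion(self):
        rng = np.random.default_rng(10)
        ann = _ann([int(x) for x in rng.integers(0, 200_000, 150)])
        sites = _sites([int(x) for x in rng.integers(0, 200_000, 30)])
        maxdist = 5000
        hist = nearest_site_histogram(ann, sites, 2500, maxdist)
        centers = np.sort(sites["center"].to_numpy())
        within = sum(
            1 for t in ann["tss"] if np.abs(centers - t).min() <= maxdist
        )
        assert hist["n_genes"].sum() == within


class TestMatchAdditive:
    @staticmethod
    def _records(n_syn=40, n_add=120, seed=0):
        rng = np.random.default_rng(seed)
        syn = pd.DataFrame(
            {"label": "synergistic", "fc_dual": rng.uniform(2, 10, n_syn)},
            index=[f"syn{i}" for i in range(n_syn)],
        )
        add = pd.DataFrame(
            {"label": "additive_dual", "fc_dual": rng.uniform(2, 10, n_add)},
            index=[f"add{i}" for i in range(n_add)],
        )
        return pd.concat([syn, add])

    def test_size_and_determinism(self):
        rec = self._records()
        c1 = match_additive_set(rec, seed=5)
        c2 = match_additive_set(rec, seed=5)
        assert len(c1) == 40 and c1 == c2
        assert set(c1).issubset(set(rec.index[rec["label"] == "additive_dual"]))

    def test_quintile_counts_match_target(self):
        rec = self._records(n_syn=50, n_add=500, seed=1)
        control = match_additive_set(rec, seed=2)
        syn_fc = rec.loc[rec["label"] == "synergistic", "fc_dual"].to_numpy()
        ctl_fc = rec.loc[control, "fc_dual"].to_numpy()
        edges = np.quantile(syn_fc, np.linspace(0, 1, 6))
        edges[0], edges[-1] = -np.inf, np.inf
        syn_bins = np.clip(np.searchsorted(edges, syn_fc, "right") - 1, 0, 4)
        ctl_bins = np.clip(np.searchsorted(edges, ctl_fc, "right") - 1, 0, 4)
        assert np.array_equal(np.bincount(syn_bins, minlength=5),
                              np.bincount(ctl_bins, minlength=5))

    def test_small_pool_rejected(self):
        rec = self._records(n_syn=30, n_add=10)
        with pytest.raises(ValueError):
            match_additive_set(rec, seed=0)


class TestClassCounts:
    def test_all_sites_adjacent_to_class_a(self):
        ann = _ann([100, 50_000])
        n_a, n_b = nearest_gene_class_counts(
            _sites([120, 150]), {"g000"}, {"g001"}, ann
        )
        assert (n_a, n_b) == (2, 0)

    def test_empty_sites(self):
        assert nearest_gene_class_counts(
            _sites([]), {"a"}, {"b"}, _ann([1])
        ) == (0, 0)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            nearest_gene_class_counts(_sites([1]), {"x"}, {"x"}, _ann([1]))


class TestPWM:
    def test_perfect_match_score_without_pseudocount(self):
        pwm = PWM("m", np.eye(4), pseudocount=0.0)  # consensus ACGT
        hits = scan_pwm("ACGT", pwm, threshold_bits=7.9)
        fwd = hits[hits["strand"] == "+"]
        # 4 positions x log2(1/0.25) = 8 bits
        assert fwd["score"].iloc[0] == pytest.approx(8.0)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 500))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pwm = PWM("m", np.array([[0.7, 0.1, 0.1, 0.1]] * 3 + [[0.1, 0.6, 0.2, 0.1]] * 3))
        s1 = scan_pwm(seq, pwm, -np.inf)["score"].max()
        s2 = scan_pwm(rc, pwm, -np.inf)["score"].max()
        assert s1 == pytest.approx(s2)

    def test_matches_naive_per_offset_scoring(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGTN"), 2000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        pwm = PWM("m", np.array([[0.4, 0.3, 0.2, 0.1]] * 6))
        hits = scan_pwm(seq, pwm, threshold_bits=-np.inf)
        lo = pwm.log_odds
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
        for strand in "+-":
            sub = hits[hits["strand"] == strand].set_index("position")["score"]
            for off in range(len(seq) - 5):
                window = seq[off : off + 6]
                if strand == "-":
                    window = "".join(comp[b] for b in window[::-1])
                expected = sum(lo[j, idx[b]] for j, b in enumerate(window))
                assert sub.loc[off] == pytest.approx(expected)

    def test_sequence_shorter_than_motif_empty(self):
        pwm = PWM("m", np.full((6, 4), 0.25))
        assert scan_pwm("ACG", pwm, 0.0).empty

    def test_too_short_motif_rejected(self):
        with pytest.raises(ValueError):
            PWM("m", np.full((3, 4), 0.25))


class TestBestScore:
    def test_planted_consensus_reaches_maximum(self):
        pwm = PWM("m", np.eye(4), pseudocount=0.0)
        seq = "T" * 100 + "ACGT" + "T" * 100
        assert best_motif_score(102, 50, pwm, seq) == pytest.approx(pwm.max_score)

    def test_all_n_window_scores_zero(self):
        pwm = PWM("m", np.full((5, 4), 0.25))
        assert best_motif_score(50, 20, pwm, "N" * 100) == pytest.approx(0.0)


class TestProximityProfile:
    def test_hits_at_centers_concentrate_in_bin_zero(self):
        sites = _sites([1000, 2000, 3000])
        hits = pd.DataFrame({"chrom": "chr1", "position": [1000, 2000, 3000]})
        prof = motif_proximity_profile(sites, hits, binsize=50, halfwindow=500)
        assert prof.loc[prof["bin_left"] == 0, "percent"].iloc[0] == 100.0
        assert prof.loc[prof["bin_left"] != 0, "percent"].sum() == 0.0

    def test_no_hits_all_zero(self):
        prof = motif_proximity_profile(
            _sites([100]), pd.DataFrame({"chrom": [], "position": []}), 50, 500
        )
        assert (prof["percent"] == 0).all()

    def test_site_counted_once_per_bin(self):
        sites = _sites([1000])
        hits = pd.DataFrame({"chrom": "chr1", "position": [1005, 1010, 1049]})
        prof = motif_proximity_profile(sites, hits, binsize=50, halfwindow=500)
        assert prof.loc[prof["bin_left"] == 0, "percent"].iloc[0] == 100.0
        assert prof["percent"].sum() == 100.0


class TestPlantedProximityBias:
    def test_assisted_sites_sit_near_synergistic_genes(self):
        cfg = synthetic_mod.SyntheticConfig()
        truth = synthetic_mod.make_truth(cfg, 31)
        synthetic_mod.simulate_genome_sites(truth, 31)
        ann = truth.genes.reset_index()[["gene_id", "chrom", "tss", "strand"]]
        syn = set(truth.genes.index[truth.genes["label"] == "synergistic"])
        add = set(truth.genes.index[truth.genes["label"] == "additive_dual"])
        assisted = truth.sites[truth.sites["label"] == "assisted"]
        n_syn, n_add = nearest_gene_class_counts(assisted, syn, add, ann)
        # planted TSS proximity: most assisted sites capture their paired
        # synergistic gene, while additive genes are only chance neighbors
        assert n_syn >= 30
        assert n_add <= 10
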