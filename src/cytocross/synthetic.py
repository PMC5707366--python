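"""Synthetic dataset generator with known ground truth.

Emulates the data structure of a two-cytokine stimulation study in
primary hepatocytes: four treatment conditions (NT, IL1, IL6, DUAL) of
negative-binomially distributed gene counts with planted crosstalk
classes, and per-condition ChIP read sets (STAT3, H3K27ac, RNAPII) over
planted binding sites that are either "assisted" (maximal TF binding
only under the dual treatment), "unassisted" (maximal binding under IL-6
alone) or background.  An extra STAT3 condition DN_DUAL models the dual
treatment under dominant-negative NF-kB, where a planted fraction of
assisted sites loses binding entirely.

Everything is driven by a :class:`TruthTable` so that downstream
classifiers can be scored against the planted labels, and every draw is
keyed on (seed, component) so identical seeds give byte-identical
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .context import PWM
from .stats import CountMatrix
from .tagdensity import ReadSet

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "SyntheticDataset",
    "NFKB_PWM",
    "STAT3_PWM",
    "demo_config",
    "make_truth",
    "simulate_expression",
    "simulate_genome_sites",
    "simulate_chip_reads",
    "make_dataset",
]

CONDITIONS = ("NT", "IL1", "IL6", "DUAL")
ASSAYS = ("STAT3", "H3K27ac", "RNAPII")
GENE_CLASSES = (
    "synergistic",
    "antagonized_by_il6",
    "antagonized_by_il1",
    "additive_dual",
    "il1_only",
    "il6_only",
    "unchanged",
)
SITE_CLASSES = ("assisted", "unassisted", "background")


def _strong_pwm(consensus: str, p: float = 0.85) -> np.ndarray:
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = p
    return m


# Toy motif models with the flavor of the real response elements:
# an NF-kB-like GGGANTTTCC decamer and a STAT3-like TTCCNGGAA element.
NFKB_PWM = PWM("NFKB_synthetic", _strong_pwm("GGGAATTTCC"))
STAT3_PWM = PWM("STAT3_synthetic", _strong_pwm("TTCCAGGAA"))


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults are the reference study conditions."""

    # expression
    n_genes: int = 1000
    proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "synergistic": 0.05,
            "antagonized_by_il6": 0.05,
            "antagonized_by_il1": 0.05,
            "additive_dual": 0.05,
            "il1_only": 0.015,
            "il6_only": 0.015,
        }
    )
    # (m_il1, m_il6) per class; dual multipliers are derived below
    single_multipliers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "synergistic": (3.0, 4.0),
            "antagonized_by_il6": (8.0, 1.0),
            "antagonized_by_il1": (1.0, 8.0),
            "additive_dual": (3.0, 4.0),
            "il1_only": (8.0, 1.0),
            "il6_only": (1.0, 8.0),
            "unchanged": (1.0, 1.0),
        }
    )
    synergy_ratio: float = 1.5
    antagonism_dual_fc: float = 1.0
    carryover_dual_fc: float = 1.45
    dispersion: float = 0.05
    n_reps: int = 3
    # cytokine-responsive genes sit in the low-to-mid expression range;
    # constitutive genes span up to library-dominating high expressors
    baseline_range: tuple[float, float] = (100.0, 1000.0)
    unchanged_baseline_range: tuple[float, float] = (100.0, 30000.0)
    gene_length_range: tuple[int, int] = (500, 5000)
    depth_factor_range: tuple[float, float] = (0.5, 2.0)
    # genome / sites
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chrM": 16_000}
    )
    n_sites: int = 500
    n_assisted: int = 100
    n_background_sites: int = 50
    site_width: int = 300
    tss_offset_range: tuple[int, int] = (100, 1200)
    # ChIP signal: expected fragments per site by (assay, class, condition)
    assisted_ratio: float = 4.0
    assisted_il6_lambda: float = 100.0
    unassisted_lambda: float = 400.0
    unassisted_dual_lambda: float = 340.0
    low_lambda: float = 2.0
    k27_high: float = 30.0
    k27_assisted_nt: float = 2.0
    k27_assisted_il6: float = 8.0
    k27_background: float = 3.0
    dn_ablated_fraction: float = 0.9
    chip_reps: Mapping[str, int] = field(
        default_factory=lambda: {"STAT3": 2, "H3K27ac": 3, "RNAPII": 1}
    )
    read_sigma: float = 60.0
    read_length: int = 50
    fragment_length: int = 150
    background_rate_per_bp: float = 0.05
    chrm_reads: int = 2000
    peak_call_lambda: float = 20.0
    # motifs
    p_motif_assisted: float = 0.8
    p_motif_unassisted: float = 0.1
    motif_window: int = 200
    stat3_mutations_at_assisted: int = 2

    def validate(self) -> None:
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        if sum(self.proportions.values()) > 1.0 + 1e-12:
            raise ValueError("class proportions must sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_assisted + self.n_background_sites > self.n_sites:
            raise ValueError("site class counts exceed n_sites")
        if 2 * self.motif_window >= min(l for l in self.chrom_lengths.values()):
            raise ValueError("motif window too large for the chromosomes")


def demo_config() -> SyntheticConfig:
    """Scaled-down preset for quick demos and smoke tests."""
    return SyntheticConfig(
        n_genes=200,
        n_sites=60,
        n_assisted=12,
        n_background_sites=6,
        chrom_lengths={"chr1": 1_500_000, "chrM": 16_000},
        background_rate_per_bp=0.02,
        chrm_reads=200,
    )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


@dataclass
class TruthTable:
    """Planted ground truth: per-gene and per-site generative parameters."""

    genes: pd.DataFrame
    sites: pd.DataFrame
    meta: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes.reset_index().to_dict(orient="list"),
                "sites": self.sites.reset_index().to_dict(orient="list"),
                "meta": self.meta,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        d = json.loads(text)
        genes = pd.DataFrame(d["genes"]).set_index("gene_id")
        sites = pd.DataFrame(d["sites"]).set_index("site_id")
        return cls(genes, sites, d["meta"])


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    annotation: pd.DataFrame
    counts: CountMatrix
    readsets: dict[tuple[str, str], list[ReadSet]]
    peaks: dict[tuple[str, str], pd.DataFrame]
    truth: TruthTable
    config: SyntheticConfig


def _dual_multiplier(cls: str, m1: float, m6: float, cfg: SyntheticConfig) -> float:
    if cls == "synergistic":
        return cfg.synergy_ratio * (m1 + m6 - 1.0)
    if cls in ("antagonized_by_il6", "antagonized_by_il1"):
        return cfg.antagonism_dual_fc
    if cls == "additive_dual":
        return m1 + m6 - 1.0
    if cls in ("il1_only", "il6_only"):
        return cfg.carryover_dual_fc
    return 1.0


def make_truth(config: SyntheticConfig, seed: int) -> TruthTable:
    """Build the planted truth table (deterministic given seed)."""
    config.validate()
    rng = _rng(seed, 0)

    labels: list[str] = []
    for cls in GENE_CLASSES[:-1]:
        labels += [cls] * int(round(config.proportions.get(cls, 0.0) * config.n_genes))
    labels += ["unchanged"] * (config.n_genes - len(labels))
    labels_arr = np.array(labels)
    rng.shuffle(labels_arr)

    lo, hi = config.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    ulo, uhi = config.unchanged_baseline_range
    unchanged_mask = labels_arr == "unchanged"
    baseline[unchanged_mask] = np.exp(
        rng.uniform(np.log(ulo), np.log(uhi), size=int(unchanged_mask.sum()))
    )
    glo, ghi = config.gene_length_range
    lengths = rng.integers(glo, ghi + 1, size=config.n_genes)
    m1 = np.array([config.single_multipliers[c][0] for c in labels_arr])
    m6 = np.array([config.single_multipliers[c][1] for c in labels_arr])
    md = np.array(
        [_dual_multiplier(c, a, b, config) for c, a, b in zip(labels_arr, m1, m6)]
    )
    genes = pd.DataFrame(
        {
            "label": labels_arr,
            "baseline": baseline,
            "length": lengths,
            "m_nt": 1.0,
            "m_il1": m1,
            "m_il6": m6,
            "m_dual": md,
        },
        index=pd.Index([f"gene{i:04d}" for i in range(config.n_genes)], name="gene_id"),
    )

    n_un = config.n_sites - config.n_assisted - config.n_background_sites
    site_labels = np.array(
        ["assisted"] * config.n_assisted
        + ["unassisted"] * n_un
        + ["background"] * config.n_background_sites
    )
    rng.shuffle(site_labels)
    lam = {}
    c = config
    stat3 = {
        "assisted": {
            "NT": c.low_lambda,
            "IL1": c.low_lambda,
            "IL6": c.assisted_il6_lambda,
            "DUAL": c.assisted_il6_lambda * c.assisted_ratio,
        },
        "unassisted": {
            "NT": c.low_lambda,
            "IL1": c.low_lambda,
            "IL6": c.unassisted_lambda,
            "DUAL": c.unassisted_dual_lambda,
        },
        "background": {cond: c.low_lambda for cond in CONDITIONS},
    }
    k27 = {
        "assisted": {
            "NT": c.k27_assisted_nt,
            "IL1": c.k27_high,
            "IL6": c.k27_assisted_il6,
            "DUAL": c.k27_high,
        },
        "unassisted": {cond: c.k27_high for cond in CONDITIONS},
        "background": {cond: c.k27_background for cond in CONDITIONS},
    }
    pol2 = {
        "assisted": {"NT": 3.0, "IL1": 3.0, "IL6": 5.0, "DUAL": 30.0},
        "unassisted": {"NT": 3.0, "IL1": 3.0, "IL6": 25.0, "DUAL": 25.0},
        "background": {cond: 3.0 for cond in CONDITIONS},
    }
    tables = {"STAT3": stat3, "H3K27ac": k27, "RNAPII": pol2}
    for assay, tab in tables.items():
        for cond in CONDITIONS:
            lam[f"lambda_{assay}_{cond}"] = [tab[s][cond] for s in site_labels]

    ablated = np.zeros(config.n_sites, dtype=bool)
    assisted_idx = np.flatnonzero(site_labels == "assisted")
    n_abl = int(round(config.dn_ablated_fraction * assisted_idx.size))
    ablated[rng.choice(assisted_idx, size=n_abl, replace=False)] = True
    # STAT3 under dual treatment + dominant-negative NF-kB
    lam["lambda_STAT3_DN_DUAL"] = [
        0.0
        if abl
        else (
            stat3[s]["DUAL"]
            if s == "assisted"
            else stat3[s]["IL6"] if s == "unassisted" else c.low_lambda
        )
        for s, abl in zip(site_labels, ablated)
    ]

    sites = pd.DataFrame(
        {"label": site_labels, "dn_ablated": ablated, **lam},
        index=pd.Index([f"site{i:04d}" for i in range(config.n_sites)], name="site_id"),
    )
    meta = {
        "seed": int(seed),
        "dispersion": config.dispersion,
        "n_reps": config.n_reps,
        "chip_reps": dict(config.chip_reps),
        "chrom_lengths": dict(config.chrom_lengths),
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    return TruthTable(genes, sites, meta)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_expression(truth: TruthTable, seed: int) -> CountMatrix:
    """NB gene counts for NT/IL1/IL6/DUAL with per-sample depth factors."""
    cfg = truth.meta["config"]
    alpha = truth.meta["dispersion"]
    n_reps = truth.meta["n_reps"]
    rng = _rng(seed, 1)
    lo, hi = cfg["depth_factor_range"]
    samples, conditions = [], {}
    cols = {}
    mult = {
        "NT": truth.genes["m_nt"],
        "IL1": truth.genes["m_il1"],
        "IL6": truth.genes["m_il6"],
        "DUAL": truth.genes["m_dual"],
    }
    for cond in CONDITIONS:
        for r in range(1, n_reps + 1):
            name = f"{cond}_{r}"
            depth = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            mean = truth.genes["baseline"].to_numpy() * mult[cond].to_numpy() * depth
            cols[name] = _nb_draw(rng, mean, alpha)
            samples.append(name)
            conditions[name] = cond
    counts = pd.DataFrame(cols, index=truth.genes.index)
    return CountMatrix(counts, conditions, lengths=truth.genes["length"].astype(float))


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _mutate_consensus(consensus: str, pwm: PWM, k: int, rng: np.random.Generator) -> str:
    """Swap k consensus positions to the least-likely base (score penalty)."""
    out = list(consensus)
    pos = rng.choice(len(consensus), size=k, replace=False)
    for p in pos:
        out[p] = "ACGT"[int(pwm.matrix[p].argmin())]
    return "".join(out)


def simulate_genome_sites(
    truth: TruthTable, seed: int
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random genome, planted site coordinates/motifs and gene TSSs.

    Fills chrom/start/end/center and motif bookkeeping columns of
    ``truth.sites`` in place, and returns (genome, annotation, sites).
    Assisted sites carry an NF-kB motif instance within +-200 bp with
    probability p_a (vs p_u for unassisted); every non-background site
    carries a STAT3 motif at its center, degraded by a planted score
    penalty at assisted sites.  Each synergistic gene's TSS is planted
    near a distinct assisted site so proximity analyses have a defined
    positive class.
    """
    cfg = truth.meta["config"]
    rng = _rng(seed, 2)
    chrom_lengths = {k: int(v) for k, v in truth.meta["chrom_lengths"].items()}
    base_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome_arr = {
        chrom: base_lookup[rng.integers(0, 4, size=length)].copy()
        for chrom, length in chrom_lengths.items()
    }

    main_chrom = max(chrom_lengths, key=lambda k: 0 if k == "chrM" else chrom_lengths[k])
    clen = chrom_lengths[main_chrom]
    n_sites = len(truth.sites)
    width = int(cfg["site_width"])
    margin = 5000
    spacing = (clen - 2 * margin) // n_sites
    jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=n_sites)
    centers = margin + spacing // 2 + spacing * np.arange(n_sites) + jitter
    starts = centers - width // 2
    ends = starts + width
    truth.sites["chrom"] = main_chrom
    truth.sites["start"] = starts
    truth.sites["end"] = ends
    truth.sites["center"] = (starts + ends) // 2

    seq = genome_arr[main_chrom]
    nfkb_cons = NFKB_PWM.consensus()
    stat3_cons = STAT3_PWM.consensus()
    p_by_class = {
        "assisted": cfg["p_motif_assisted"],
        "unassisted": cfg["p_motif_unassisted"],
        "background": cfg["p_motif_unassisted"],
    }
    window = int(cfg["motif_window"])
    nfkb_offsets = np.full(n_sites, np.nan)
    stat3_planted = []
    for i, (label, center) in enumerate(
        zip(truth.sites["label"], truth.sites["center"])
    ):
        has_nfkb = rng.random() < p_by_class[label]
        off = int(rng.integers(-window, window - len(nfkb_cons) + 1))
        if has_nfkb:
            _plant(seq, center + off, nfkb_cons)
            nfkb_offsets[i] = off
        if label == "background":
            stat3_planted.append("")
            continue
        motif = stat3_cons
        if label == "assisted" and cfg["stat3_mutations_at_assisted"] > 0:
            motif = _mutate_consensus(
                stat3_cons, STAT3_PWM, int(cfg["stat3_mutations_at_assisted"]), rng
            )
        _plant(seq, center - len(motif) // 2, motif)
        stat3_planted.append(motif)
    truth.sites["nfkb_offset"] = nfkb_offsets
    truth.sites["stat3_motif"] = stat3_planted

    # TSS placement: each synergistic gene near its own assisted site
    genes = truth.genes
    n_genes = len(genes)
    tss = rng.integers(margin, clen - margin, size=n_genes)
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    syn_idx = np.flatnonzero((genes["label"] == "synergistic").to_numpy())
    assisted_centers = truth.sites.loc[
        truth.sites["label"] == "assisted", "center"
    ].to_numpy()
    chosen = rng.choice(len(assisted_centers), size=min(len(syn_idx), len(assisted_centers)), replace=False)
    olo, ohi = cfg["tss_offset_range"]
    for gi, si in zip(syn_idx, chosen):
        off = int(rng.integers(olo, ohi + 1)) * (1 if rng.random() < 0.5 else -1)
        tss[gi] = int(np.clip(assisted_centers[si] + off, 0, clen - 1))
    genes["chrom"] = main_chrom
    genes["tss"] = tss
    genes["strand"] = strand

    genome = {chrom: arr.tobytes().decode("ascii") for chrom, arr in genome_arr.items()}
    annotation = genes.reset_index()[["gene_id", "chrom", "tss", "strand", "label"]]
    return genome, annotation, truth.sites


def simulate_chip_reads(
    truth: TruthTable,
    assay: str,
    condition: str,
    seed: int,
    rep: int = 1,
) -> ReadSet:
    """One ChIP library: Poisson fragments per site plus uniform background.

    Per site the fragment count is Poisson(lambda) for the planted
    (assay, condition, class) intensity; fragment centers are Normal
    (site center, sigma); the 5' position sits a half-fragment upstream
    on + reads and downstream on - reads.  Uniform background reads cover
    every non-mitochondrial contig, and a fixed mitochondrial read load
    is placed on chrM so depth scaling can be tested.
    """
    col = f"lambda_{assay}_{condition}"
    if col not in truth.sites.columns:
        raise ValueError(f"no planted intensity for assay={assay!r}, condition={condition!r}")
    if "center" not in truth.sites.columns:
        raise ValueError("simulate_genome_sites must run before simulate_chip_reads")
    cfg = truth.meta["config"]
    rng = _rng(seed, 3, _assay_key(assay), _cond_key(condition), rep)
    chrom_lengths = {k: int(v) for k, v in truth.meta["chrom_lengths"].items()}
    sigma = cfg["read_sigma"]
    frag = int(cfg["fragment_length"])
    half = frag // 2

    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    lam = truth.sites[col].to_numpy(dtype=float)
    k = rng.poisson(lam)
    total = int(k.sum())
    site_centers = np.repeat(truth.sites["center"].to_numpy(dtype=np.int64), k)
    site_chroms = np.repeat(truth.sites["chrom"].to_numpy(), k)
    frag_centers = np.rint(site_centers + rng.normal(0.0, sigma, size=total)).astype(np.int64)
    plus = rng.random(total) < 0.5
    pos5 = np.where(plus, frag_centers - half, frag_centers + half - 1)
    chroms.append(site_chroms)
    positions.append(pos5)
    strands.append(np.where(plus, "+", "-"))

    rate = float(cfg["background_rate_per_bp"])
    for chrom, length in chrom_lengths.items():
        if chrom in ("chrM",):
            n_bg = int(cfg["chrm_reads"])
        else:
            n_bg = rng.poisson(rate * length)
        p = rng.integers(0, length, size=n_bg)
        chroms.append(np.full(n_bg, chrom))
        positions.append(p)
        strands.append(np.where(rng.random(n_bg) < 0.5, "+", "-"))

    chrom_all = np.concatenate(chroms)
    pos_all = np.concatenate(positions)
    strand_all = np.concatenate(strands)
    lens = np.array([chrom_lengths[c] for c in chrom_all])
    pos_all = np.clip(pos_all, 0, lens - 1)
    reads = pd.DataFrame(
        {
            "chrom": pd.Categorical(chrom_all, categories=sorted(chrom_lengths)),
            "pos5": pos_all.astype(np.int64),
            "strand": pd.Categorical(strand_all, categories=["+", "-"]),
        }
    )
    reads = reads.sort_values(["chrom", "pos5", "strand"], kind="stable").reset_index(drop=True)
    return ReadSet(f"{assay}_{condition}_{rep}", reads, read_length=int(cfg["read_length"]))


def _assay_key(assay: str) -> int:
    try:
        return list(ASSAYS).index(assay)
    except ValueError as e:
        raise ValueError(f"unknown assay {assay!r}") from e


_COND_KEYS = {c: i for i, c in enumerate(CONDITIONS + ("DN_DUAL",))}


def _cond_key(condition: str) -> int:
    if condition not in _COND_KEYS:
        raise ValueError(f"unknown condition {condition!r}")
    return _COND_KEYS[condition]


def _peak_sets(truth: TruthTable, assay: str) -> dict[str, pd.DataFrame]:
    """Per-condition called peak sets: sites whose planted intensity is high."""
    thr = truth.meta["config"]["peak_call_lambda"]
    out = {}
    for cond in CONDITIONS:
        mask = truth.sites[f"lambda_{assay}_{cond}"] >= thr
        sub = truth.sites.loc[mask, ["chrom", "start", "end"]].copy()
        sub["name"] = sub.index
        out[cond] = sub.reset_index(drop=True)
    return out


def make_dataset(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    assays: tuple[str, ...] = ("STAT3", "H3K27ac"),
    extra_conditions: tuple[str, ...] = ("DN_DUAL",),
) -> SyntheticDataset:
    """Generate a full dataset: truth, genome, expression, reads and peaks."""
    config = config or SyntheticConfig()
    truth = make_truth(config, seed)
    counts = simulate_expression(truth, seed)
    genome, annotation, _ = simulate_genome_sites(truth, seed)
    readsets: dict[tuple[str, str], list[ReadSet]] = {}
    for assay in assays:
        n_reps = config.chip_reps.get(assay, 1)
        conds = list(CONDITIONS)
        if assay == "STAT3":
            conds += [c for c in extra_conditions if f"lambda_STAT3_{c}" in truth.sites]
        for cond in conds:
            readsets[(assay, cond)] = [
                simulate_chip_reads(truth, assay, cond, seed, rep=r)
                for r in range(1, n_reps + 1)
            ]
    peaks = {
        (assay, cond): df for assay in assays for cond, df in _peak_sets(truth, assay).items()
    }
    return SyntheticDataset(genome, annotation, counts, readsets, peaks, truth, config)
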