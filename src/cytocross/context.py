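"""Linking binding sites to genes and sequence motifs.

Covers nearest-TSS assignment and distance histograms, construction of a
fold-change-matched additive control gene set, log-odds PWM scanning of
genomic sequence, per-site best motif scores, and motif-proximity
profiles around site centers.

Conventions: distances are unsigned center-to-TSS distances; PWM scores
are log2 likelihood ratios against a uniform background with a 0.01
per-cell pseudocount, and an N base contributes 0 bits; motif hits are
binned by the offset of the motif start (plus-strand coordinates)
relative to the site center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "nearest_tss",
    "nearest_tss_all",
    "nearest_site_histogram",
    "match_additive_set",
    "nearest_gene_class_counts",
    "scan_pwm",
    "best_motif_score",
    "motif_proximity_profile",
]

_BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position weight matrix with log2-odds scoring.

    ``matrix`` is L x 4 (A, C, G, T) of probabilities; rows are
    re-normalized after adding ``pseudocount`` to every cell.  The score
    of a window is sum over positions of log2(p_base / background); an N
    contributes 0 bits.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    background: float = 0.25

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        m = m + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=1, keepdims=True), **kw)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 log2-odds table; the 5th column (N) is zero."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.motif_id = self.motif_id
        rc.pseudocount = self.pseudocount
        rc.background = self.background
        rc.matrix = self.matrix[::-1, ::-1].copy()
        return rc


def _scores_one_strand(enc: np.ndarray, pwm: PWM) -> np.ndarray:
    L = len(pwm)
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0)
    lo = pwm.log_odds
    s = np.zeros(n)
    for j in range(L):
        s += lo[j, enc[j : j + n]]
    return s


def scan_pwm(seq: str, pwm: PWM, threshold_bits: float) -> pd.DataFrame:
    """Scan both strands; report hits with score >= threshold.

    Hit ``position`` is the offset of the motif start in plus-strand
    coordinates for both strands.  A sequence shorter than the motif
    yields an empty result.
    """
    enc = encode_sequence(seq)
    fwd = _scores_one_strand(enc, pwm)
    rev = _scores_one_strand(enc, pwm.reverse_complement())
    frames = []
    for strand, sc in (("+", fwd), ("-", rev)):
        idx = np.flatnonzero(sc >= threshold_bits)
        frames.append(pd.DataFrame({"position": idx, "strand": strand, "score": sc[idx]}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


def best_motif_score(
    center: int,
    halfwindow: int,
    pwm: PWM,
    chrom_seq: str,
) -> float:
    """Maximum log2-odds score (either strand) in [center-hw, center+hw).

    A window of all N scores 0 bits under the background convention; a
    window shorter than the motif scores -inf.
    """
    lo = max(center - halfwindow, 0)
    hi = min(center + halfwindow, len(chrom_seq))
    window = chrom_seq[lo:hi]
    if len(window) < len(pwm):
        return float("-inf")
    enc = encode_sequence(window)
    fwd = _scores_one_strand(enc, pwm)
    rev = _scores_one_strand(enc, pwm.reverse_complement())
    return float(max(fwd.max(), rev.max()))


def nearest_tss(
    center: int, chrom: str, ann: pd.DataFrame
) -> tuple[str | None, int | None]:
    """Gene minimizing |center - TSS| on ``chrom``; ties by gene id.

    Returns (gene_id, unsigned distance), or (None, None) with a warning
    when the chromosome carries no annotated gene.
    """
    sub = ann[ann["chrom"] == chrom]
    if sub.empty:
        import warnings

        warnings.warn(f"no gene on chromosome {chrom}; site unassigned", stacklevel=2)
        return None, None
    d = (sub["tss"].to_numpy(dtype=np.int64) - center).__abs__()
    dmin = d.min()
    cands = sub.loc[d == dmin, "gene_id"]
    return sorted(cands)[0], int(dmin)


def nearest_tss_all(sites: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Vectorized nearest-TSS assignment for a site table.

    Returns a DataFrame indexed like ``sites`` with columns gene_id and
    distance (NaN-free rows only for chromosomes that carry genes).
    """
    genes, dists = [], []
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in ann.groupby("chrom", sort=False):
        by_chrom[chrom] = sub.sort_values(["tss", "gene_id"], kind="stable")
    for chrom, center in zip(sites["chrom"], sites["center"]):
        sub = by_chrom.get(chrom)
        if sub is None:
            genes.append(None)
            dists.append(np.nan)
            continue
        tss = sub["tss"].to_numpy(dtype=np.int64)
        d = np.abs(tss - int(center))
        dmin = d.min()
        cands = sub.loc[d == dmin, "gene_id"]
        genes.append(sorted(cands)[0])
        dists.append(int(dmin))
    return pd.DataFrame({"gene_id": genes, "distance": dists}, index=sites.index)


def nearest_site_histogram(
    ann: pd.DataFrame,
    sites: pd.DataFrame,
    binsize: int = 2500,
    maxdist: int = 50000,
) -> pd.DataFrame:
    """Distance from each gene's TSS to its nearest site, binned.

    Only the nearest site counts: each gene contributes exactly one count
    to bin floor(d / binsize); genes farther than ``maxdist`` (or on a
    chromosome without sites) are excluded.  Returns bins [left, right)
    with counts.
    """
    if ann.empty or sites.empty:
        raise ValueError("need non-empty genes and sites")
    centers_by_chrom = {
        chrom: np.sort(sub["center"].to_numpy(dtype=np.int64))
        for chrom, sub in sites.groupby("chrom", sort=False)
    }
    nbins = int(np.ceil(maxdist / binsize))
    counts = np.zeros(nbins, dtype=int)
    for chrom, tss in zip(ann["chrom"], ann["tss"]):
        centers = centers_by_chrom.get(chrom)
        if centers is None:
            continue
        i = np.searchsorted(centers, tss)
        cand = centers[max(i - 1, 0) : i + 1]
        d = int(np.abs(cand - tss).min())
        if d > maxdist:
            continue
        b = min(d // binsize, nbins - 1)
        counts[b] += 1
    left = binsize * np.arange(nbins)
    return pd.DataFrame({"bin_left": left, "bin_right": left + binsize, "n_genes": counts})


def match_additive_set(
    records: pd.DataFrame,
    seed: int,
    n_bins: int = 5,
) -> list[str]:
    """Additive control genes matched to the synergistic dual-FC profile.

    ``records`` is the per-gene crosstalk table with columns ``label``
    and ``fc_dual``.  Draws |synergistic| additive_dual genes whose dual
    fold changes match the synergistic set's distribution by rank binning
    (quintiles by default).  Deterministic given ``seed``.  A bin whose
    additive pool runs short is topped up with the unused additive genes
    closest in dual FC.
    """
    syn = records[records["label"] == "synergistic"]
    pool = records[records["label"] == "additive_dual"]
    if len(pool) < len(syn):
        raise ValueError(
            f"additive pool ({len(pool)}) smaller than synergistic set ({len(syn)})"
        )
    rng = np.random.default_rng(seed)
    edges = np.quantile(syn["fc_dual"].to_numpy(), np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    syn_bins = np.clip(np.searchsorted(edges, syn["fc_dual"].to_numpy(), "right") - 1, 0, n_bins - 1)
    pool_bins = np.clip(
        np.searchsorted(edges, pool["fc_dual"].to_numpy(), "right") - 1, 0, n_bins - 1
    )
    pool_ids = pool.index.to_numpy()
    taken: list[str] = []
    available = np.ones(len(pool), dtype=bool)
    shortfall = 0
    for b in range(n_bins):
        want = int((syn_bins == b).sum())
        cand = np.flatnonzero((pool_bins == b) & available)
        if cand.size >= want:
            pick = rng.choice(cand, size=want, replace=False)
        else:
            pick = cand
            shortfall += want - cand.size
        available[pick] = False
        taken.extend(pool_ids[pick])
    if shortfall:
        # fill from remaining pool, nearest in dual FC to the synergistic median
        rest = np.flatnonzero(available)
        target = float(np.median(syn["fc_dual"]))
        order = rest[np.argsort(np.abs(pool["fc_dual"].to_numpy()[rest] - target), kind="stable")]
        taken.extend(pool_ids[order[:shortfall]])
    return sorted(taken)


def nearest_gene_class_counts(
    sites: pd.DataFrame,
    set_a: set[str],
    set_b: set[str],
    ann: pd.DataFrame,
) -> tuple[int, int]:
    """Count sites whose nearest gene (over ALL genes) is in A vs in B.

    A and B must be disjoint; sites whose nearest gene belongs to neither
    count toward neither.
    """
    if set_a & set_b:
        raise ValueError("gene sets must be disjoint")
    if sites.empty:
        return 0, 0
    nearest = nearest_tss_all(sites, ann)["gene_id"]
    n_a = int(nearest.isin(set_a).sum())
    n_b = int(nearest.isin(set_b).sum())
    return n_a, n_b


def motif_proximity_profile(
    sites: pd.DataFrame,
    hits: pd.DataFrame,
    binsize: int = 50,
    halfwindow: int = 500,
) -> pd.DataFrame:
    """Percent of sites with >=1 motif hit per signed-distance bin.

    ``hits`` carries genome-wide motif hits with columns chrom and
    position (motif start, plus-strand coordinates).  For each signed bin
    [k*binsize, (k+1)*binsize) of hit-start offset relative to the site
    center, reports 100 * (#sites with at least one hit in that bin) /
    (#sites).
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    nbins = 2 * (halfwindow // binsize)
    left = -((halfwindow // binsize)) * binsize + binsize * np.arange(nbins)
    has_hit = np.zeros((len(sites), nbins), dtype=bool)
    hits_by_chrom = {
        chrom: np.sort(sub["position"].to_numpy(dtype=np.int64))
        for chrom, sub in hits.groupby("chrom", sort=False)
    }
    for row, (chrom, center) in enumerate(zip(sites["chrom"], sites["center"])):
        pos = hits_by_chrom.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, center + left[0])
        hi = np.searchsorted(pos, center + left[-1] + binsize)
        off = pos[lo:hi] - center
        b = (off - left[0]) // binsize
        has_hit[row, np.unique(b)] = True
    pct = 100.0 * has_hit.sum(axis=0) / len(sites)
    return pd.DataFrame({"bin_left": left, "percent": pct})
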