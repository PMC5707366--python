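"""Binding-site universe construction and assisted/unassisted classification.

A union peak set is built from per-condition peak calls (any overlap of
>= 1 bp merges), each union peak remembering which conditions
contributed.  The "coordinated" universe over which STAT3 assisted
loading is defined consists of peaks called under IL-6 and/or the dual
treatment; a coordinated site is *assisted* when its dual-vs-IL-6
fragment-count contrast reaches fold change >= 1.7 at raw p <= 0.01,
and *unassisted* otherwise.  Differential H3K27ac enhancers use the
stricter fold change >= 2 at adjusted p <= 0.1.  Loss of binding under a
perturbation is called against an empirical background: a site shows no
binding when its depth-scaled count does not exceed the 95th percentile
of random non-peak windows of matched width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import CountMatrix, nb_test
from .tagdensity import ReadSet, extend_reads, scale_factor

__all__ = [
    "SiteThresholds",
    "merge_peak_union",
    "membership_stats",
    "attribution_percent",
    "count_fragments",
    "classify_sites",
    "percent_assisted",
    "differential_enhancers",
    "sample_background_windows",
    "lost_binding_fraction",
]


@dataclass
class SiteThresholds:
    assisted_fc: float = 1.7
    assisted_p: float = 0.01
    enhancer_fc: float = 2.0
    enhancer_q: float = 0.1
    background_quantile: float = 0.95


def _validate_peaks(df: pd.DataFrame, origin: str) -> None:
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError(f"{origin}: peak table needs chrom/start/end")
    if (df["end"].to_numpy() <= df["start"].to_numpy()).any():
        raise ValueError(f"{origin}: malformed interval (start >= end)")


def merge_peak_union(peak_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union peaks across conditions with per-condition membership flags.

    Intervals overlapping by >= 1 bp are merged (touching end-to-start
    intervals are not, coordinates being half-open); the union center is
    the midpoint of the merged span.  Columns: chrom, start, end, center,
    name, in_<condition> flags.
    """
    conds = list(peak_sets)
    rows = []
    for cond, df in peak_sets.items():
        _validate_peaks(df, cond)
        for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
            rows.append((chrom, int(s), int(e), cond))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "center", "name", *[f"in_{c}" for c in conds]])
    allp = pd.DataFrame(rows, columns=["chrom", "start", "end", "cond"])
    out = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur_s = cur_e = None
        members: set[str] = set()
        for s, e, cond in zip(grp["start"], grp["end"], grp["cond"]):
            if cur_s is None:
                cur_s, cur_e, members = s, e, {cond}
            elif s < cur_e:  # >= 1 bp overlap
                cur_e = max(cur_e, e)
                members.add(cond)
            else:
                out.append((chrom, cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, {cond}
        out.append((chrom, cur_s, cur_e, members))
    union = pd.DataFrame(out, columns=["chrom", "start", "end", "members"])
    union["center"] = (union["start"] + union["end"]) // 2
    union["name"] = [f"union{i:05d}" for i in range(len(union))]
    for c in conds:
        union[f"in_{c}"] = [c in m for m in union["members"]]
    return union.drop(columns=["members"])


def attribution_percent(n: int, total: int) -> float:
    """Percent of the union attributed to one condition, one decimal."""
    if total == 0:
        raise ValueError("empty union")
    return round(100.0 * n / total, 1)


def membership_stats(union: pd.DataFrame) -> pd.DataFrame:
    """Per-condition union-peak counts and percentages (one decimal)."""
    total = len(union)
    if total == 0:
        raise ValueError("empty union")
    conds = [c[3:] for c in union.columns if c.startswith("in_")]
    rows = [
        {"condition": c, "n": int(union[f"in_{c}"].sum()),
         "percent": attribution_percent(int(union[f"in_{c}"].sum()), total)}
        for c in conds
    ]
    return pd.DataFrame(rows)


def count_fragments(
    readsets: list[ReadSet],
    peaks: pd.DataFrame,
    extension: int = 150,
    conditions: dict[str, str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> CountMatrix:
    """Per-peak fragment counts for each library.

    A 3'-extended fragment is counted for a peak when the two intervals
    overlap by >= 1 bp.  ``conditions`` maps sample id -> condition; when
    omitted every sample maps to itself.
    """
    _validate_peaks(peaks, "count_fragments")
    names = peaks["name"] if "name" in peaks.columns else pd.Index(
        [f"peak{i:05d}" for i in range(len(peaks))]
    )
    cols = {}
    for rs in readsets:
        counts = np.zeros(len(peaks), dtype=np.int64)
        for chrom, grp in peaks.groupby("chrom", sort=False):
            sub = rs.on_chrom(chrom)
            clen = None if chrom_lengths is None else chrom_lengths.get(chrom)
            fs, fe = extend_reads(sub, extension, clen)
            fs = np.sort(fs)
            fe = np.sort(fe)
            n = fs.size
            ps = grp["start"].to_numpy(dtype=np.int64)
            pe = grp["end"].to_numpy(dtype=np.int64)
            # overlap iff not (frag_end <= peak_start) and not (frag_start >= peak_end)
            ended_before = np.searchsorted(fe, ps, side="right")
            start_after = n - np.searchsorted(fs, pe, side="left")
            counts[peaks.index.get_indexer(grp.index)] = n - ended_before - start_after
        cols[rs.sample_id] = counts
    cond = conditions or {rs.sample_id: rs.sample_id for rs in readsets}
    return CountMatrix(pd.DataFrame(cols, index=pd.Index(names, name="peak")), cond)


def percent_assisted(n_assisted: int, n_unassisted: int) -> int:
    """Assisted share of the coordinated universe, nearest whole percent."""
    total = n_assisted + n_unassisted
    if total == 0:
        raise ValueError("empty universe")
    return int(round(100.0 * n_assisted / total))


def classify_sites(
    peak_counts: CountMatrix,
    union: pd.DataFrame | None = None,
    th: SiteThresholds | None = None,
    universe: str = "il6-or-dual",
    contrast: tuple[str, str] = ("IL6", "DUAL"),
) -> tuple[pd.DataFrame, dict]:
    """Assisted/unassisted classification over the coordinated universe.

    ``peak_counts`` holds per-peak fragment counts for IL-6 and dual
    libraries.  The universe is either peaks called in IL-6 or dual
    (``il6-or-dual``, requires ``union`` membership flags) or every peak
    (``all``).  A universe member is assisted when the NB contrast shows
    FC(DUAL/IL6) >= 1.7 at raw p <= 0.01, unassisted otherwise.

    Returns (classification table, summary dict with n_assisted,
    n_unassisted and percent_assisted to the nearest whole percent).
    """
    th = th or SiteThresholds()
    res = nb_test(peak_counts, contrast)
    if universe == "il6-or-dual":
        if union is None:
            raise ValueError("universe='il6-or-dual' needs the union table")
        flags = union.set_index("name")[[f"in_{contrast[0]}", f"in_{contrast[1]}"]]
        in_universe = (
            flags.reindex(res.index).fillna(False).any(axis=1).to_numpy(dtype=bool)
        )
    elif universe == "all":
        in_universe = np.ones(len(res), dtype=bool)
    else:
        raise ValueError("universe must be 'il6-or-dual' or 'all'")
    if not in_universe.any():
        raise ValueError("empty coordinated-site universe")
    assisted = in_universe & (res["fc"] >= th.assisted_fc) & (res["p"] <= th.assisted_p)
    cls = np.where(assisted, "assisted", np.where(in_universe, "unassisted", ""))
    table = res.assign(universe=in_universe, cls=cls)
    n_a = int(assisted.sum())
    n_u = int(in_universe.sum()) - n_a
    summary = {
        "n_assisted": n_a,
        "n_unassisted": n_u,
        "percent_assisted": percent_assisted(n_a, n_u),
    }
    return table, summary


def differential_enhancers(
    counts: CountMatrix,
    contrast: tuple[str, str],
    th: SiteThresholds | None = None,
) -> tuple[set, set, pd.DataFrame]:
    """Induced / reduced enhancer regions under a contrast.

    Induced iff FC >= 2 and adjusted p <= 0.1 (inclusive); reduced
    symmetric with FC <= 0.5.  With a single replicate on either side
    the NB dispersion is not estimable; a warning is emitted and the
    test proceeds on its Poisson fallback.
    """
    th = th or SiteThresholds()
    na = len(counts.samples_of(contrast[0]))
    nb = len(counts.samples_of(contrast[1]))
    if min(na, nb) < 2:
        warnings.warn(
            "fewer than 2 replicates per side: enhancer calls lose power",
            stacklevel=2,
        )
    res = nb_test(counts, contrast)
    sig = res["q"] <= th.enhancer_q
    induced = set(res.index[(res["fc"] >= th.enhancer_fc) & sig])
    reduced = set(res.index[(res["fc"] <= 1.0 / th.enhancer_fc) & sig])
    return induced, reduced, res


def sample_background_windows(
    chrom_lengths: dict[str, int],
    peaks: pd.DataFrame,
    width: int,
    n: int,
    seed: int,
    exclude_chroms: tuple[str, ...] = ("chrM",),
) -> pd.DataFrame:
    """Random non-peak windows of matched width (background model)."""
    rng = np.random.default_rng(seed)
    chroms = [c for c in chrom_lengths if c not in exclude_chroms]
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    by_chrom = {
        c: sub[["start", "end"]].to_numpy() for c, sub in peaks.groupby("chrom", sort=False)
    }
    out = []
    attempts = 0
    while len(out) < n and attempts < 100 * n:
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=weights)]
        s = int(rng.integers(0, chrom_lengths[c] - width))
        ivs = by_chrom.get(c)
        if ivs is not None and ((s < ivs[:, 1]) & (s + width > ivs[:, 0])).any():
            continue
        out.append((c, s, s + width))
    if not out:
        raise ValueError("could not sample any background window")
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    df["name"] = [f"bg{i:05d}" for i in range(len(df))]
    return df


def lost_binding_fraction(
    site_counts: np.ndarray,
    background_counts: np.ndarray,
    scale: float = 1.0,
    background_scale: float | None = None,
    quantile: float = 0.95,
) -> tuple[int, int, int]:
    """Fraction of sites showing no binding under a perturbation.

    A site shows "no binding" when its depth-scaled fragment count does
    not exceed the given quantile (default 95th percentile) of scaled
    counts in random background windows of matched width.  Returns
    (n_lost, n_total, percent to the nearest whole percent).
    """
    background_counts = np.asarray(background_counts, dtype=float)
    if background_counts.size == 0:
        raise ValueError("no background windows")
    if background_scale is None:
        background_scale = scale
    cutoff = np.quantile(background_counts * background_scale, quantile)
    scaled = np.asarray(site_counts, dtype=float) * scale
    n_total = scaled.size
    n_lost = int((scaled <= cutoff).sum())
    return n_lost, n_total, int(round(100.0 * n_lost / n_total))
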