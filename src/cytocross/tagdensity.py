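"""Tag-density machinery: read extension, depth scaling, coverage profiles.

Sequenced ChIP tags are stored as 5' positions with strand.  Every
operation extends each tag to a fixed fragment length (default 150 bp)
in the 3' direction relative to its strand, piles up per-bp fragment
coverage and multiplies by a depth scale factor of 10 million per total
non-mitochondrial reads.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import MITO_CHROMS

__all__ = [
    "ReadSet",
    "DensityProfile",
    "extend_read",
    "extend_reads",
    "scale_factor",
    "coverage_array",
    "coverage_profile",
    "aggregate_profile",
    "site_density",
    "heatmap_matrix",
]

DEFAULT_FRAGMENT = 150
DEFAULT_READ_LENGTH = 50


@dataclass
class ReadSet:
    """Mapped 5' read placements for one sample (library).

    ``reads`` has columns chrom, pos5, strand.  The non-mitochondrial
    total equals the number of records whose chromosome is not a
    mitochondrial contig (chrM/MT).
    """

    sample_id: str
    reads: pd.DataFrame
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        req = {"chrom", "pos5", "strand"}
        if not req.issubset(self.reads.columns):
            raise ValueError(f"reads need columns {sorted(req)}")
        if (self.reads["pos5"].to_numpy() < 0).any():
            raise ValueError("read positions must be >= 0")
        bad = set(self.reads["strand"].unique()) - {"+", "-"}
        if bad:
            raise ValueError(f"unknown strand value(s): {sorted(bad)}")

    @property
    def n_nonmito(self) -> int:
        return int((~self.reads["chrom"].isin(MITO_CHROMS)).sum())

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.reads[self.reads["chrom"] == chrom]


@dataclass
class DensityProfile:
    """Binned scaled tag density around an anchor.

    ``offsets`` are bin-left offsets in bp relative to the anchor (or to
    the interval start for plain interval profiles); ``values`` are mean
    scaled tags per bp in each bin.
    """

    anchor: str
    binsize: int
    offsets: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.values})


def extend_read(
    pos5: int, strand: str, length: int = DEFAULT_FRAGMENT, chrom_len: int | None = None
) -> tuple[int, int]:
    """3'-extend a tag to ``length`` bp; returns the fragment [start, end).

    Plus strand: [pos5, pos5+L).  Minus strand: [pos5-L+1, pos5+1).
    Clipped at chromosome bounds when ``chrom_len`` is given.
    """
    if strand == "+":
        start, end = pos5, pos5 + length
    elif strand == "-":
        start, end = pos5 - length + 1, pos5 + 1
    else:
        raise ValueError(f"unknown strand {strand!r}")
    start = max(start, 0)
    if chrom_len is not None:
        end = min(end, chrom_len)
        start = min(start, chrom_len)
    return start, end


def extend_reads(
    reads: pd.DataFrame, length: int = DEFAULT_FRAGMENT, chrom_len: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fragment intervals for a single-chromosome read table."""
    pos = reads["pos5"].to_numpy(dtype=np.int64)
    plus = (reads["strand"] == "+").to_numpy()
    start = np.where(plus, pos, pos - length + 1)
    end = np.where(plus, pos + length, pos + 1)
    np.clip(start, 0, chrom_len, out=start)
    if chrom_len is not None:
        np.clip(end, 0, chrom_len, out=end)
    return start, end


def scale_factor(rs: ReadSet) -> float:
    """Depth scale: 10 million per total non-mitochondrial reads."""
    n = rs.n_nonmito
    if n == 0:
        raise ValueError("read set has no non-mitochondrial reads")
    return 1e7 / n


def coverage_array(
    rs: ReadSet,
    chrom: str,
    start: int,
    end: int,
    chrom_len: int | None = None,
    fragment: int = DEFAULT_FRAGMENT,
) -> np.ndarray:
    """Unscaled per-bp fragment coverage over [start, end) of ``chrom``."""
    if end <= start:
        raise ValueError("empty interval")
    fs, fe = extend_reads(rs.on_chrom(chrom), fragment, chrom_len)
    n = end - start
    diff = np.zeros(n + 1, dtype=np.int64)
    s = np.clip(fs - start, 0, n)
    e = np.clip(fe - start, 0, n)
    keep = e > s
    np.add.at(diff, s[keep], 1)
    np.add.at(diff, e[keep], -1)
    return np.cumsum(diff[:-1]).astype(float)


def coverage_profile(
    rs: ReadSet,
    interval: tuple[str, int, int],
    binsize: int,
    chrom_len: int | None = None,
    fragment: int = DEFAULT_FRAGMENT,
) -> DensityProfile:
    """Binned scaled tag density over a genomic interval.

    Each bin holds the mean per-bp fragment coverage in that bin times the
    depth scale factor.  Intervals extending past the chromosome are
    clipped with a warning; off-chromosome bp do not enter the bin means.
    """
    chrom, start, end = interval
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    cstart, cend = max(start, 0), end if chrom_len is None else min(end, chrom_len)
    if (cstart, cend) != (start, end):
        warnings.warn(
            f"interval {chrom}:{start}-{end} clipped to chromosome bounds", stacklevel=2
        )
    cov = coverage_array(rs, chrom, cstart, cend, chrom_len, fragment)
    # place clipped coverage back into the requested frame
    full = np.zeros(end - start, dtype=float)
    weight = np.zeros(end - start, dtype=float)
    full[cstart - start : cstart - start + cov.size] = cov
    weight[cstart - start : cstart - start + cov.size] = 1.0
    nbins = (end - start) // binsize
    full = full[: nbins * binsize].reshape(nbins, binsize)
    weight = weight[: nbins * binsize].reshape(nbins, binsize)
    with np.errstate(invalid="ignore"):
        vals = np.where(weight.sum(1) > 0, full.sum(1) / np.maximum(weight.sum(1), 1), 0.0)
    s = scale_factor(rs)
    offsets = start + binsize * np.arange(nbins)
    return DensityProfile(f"{chrom}:{start}-{end}", binsize, offsets, vals * s)


def _window_sums(
    rs: ReadSet,
    sites: pd.DataFrame,
    halfwindow: int,
    chrom_lengths: dict[str, int] | None,
    fragment: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site per-bp coverage and in-bounds weights over +-halfwindow windows.

    Returns (coverage, weight) arrays of shape (n_sites, 2*halfwindow);
    window bp k corresponds to genomic position center - halfwindow + k.
    """
    width = 2 * halfwindow
    cov = np.zeros((len(sites), width), dtype=float)
    wt = np.zeros((len(sites), width), dtype=float)
    for chrom, grp in sites.groupby("chrom", sort=False):
        clen = None if chrom_lengths is None else chrom_lengths[chrom]
        centers = grp["center"].to_numpy(dtype=np.int64)
        lo = max(int(centers.min()) - halfwindow, 0)
        hi = int(centers.max()) + halfwindow
        if clen is not None:
            hi = min(hi, clen)
        base = coverage_array(rs, chrom, lo, hi, clen, fragment)
        rows = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        for row, c in zip(rows, centers):
            gs = c - halfwindow
            cs = max(gs, lo)
            ce = min(gs + width, lo + base.size)
            if ce <= cs:
                continue
            cov[row, cs - gs : ce - gs] = base[cs - lo : ce - lo]
            wt[row, cs - gs : ce - gs] = 1.0
    return cov, wt


def aggregate_profile(
    sites: pd.DataFrame,
    rs: ReadSet,
    halfwindow: int = 500,
    binsize: int = 10,
    chrom_lengths: dict[str, int] | None = None,
    fragment: int = DEFAULT_FRAGMENT,
) -> DensityProfile:
    """Average scaled tag density around site centers (strand-agnostic).

    Mean across sites of the per-site binned coverage profile centered on
    ``center``; bins of ``binsize`` bp spanning [-halfwindow, +halfwindow).
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    cov, wt = _window_sums(rs, sites, halfwindow, chrom_lengths, fragment)
    nbins = (2 * halfwindow) // binsize
    cov = cov[:, : nbins * binsize].reshape(len(sites), nbins, binsize)
    wt = wt[:, : nbins * binsize].reshape(len(sites), nbins, binsize)
    wsum = wt.sum(2)
    with np.errstate(invalid="ignore"):
        per_site = np.where(wsum > 0, cov.sum(2) / np.maximum(wsum, 1), 0.0)
    vals = per_site.mean(axis=0) * scale_factor(rs)
    offsets = -halfwindow + binsize * np.arange(nbins)
    return DensityProfile("site centers", binsize, offsets, vals)


def site_density(
    sites: pd.DataFrame,
    rs: ReadSet,
    halfwindow: int = 100,
    chrom_lengths: dict[str, int] | None = None,
    fragment: int = DEFAULT_FRAGMENT,
) -> np.ndarray:
    """Per-site mean scaled tag density over [center-hw, center+hw).

    This is the quantity summarized in per-site box plots; vectors for two
    site classes or two conditions feed :func:`cytocross.stats.welch_t`.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    cov, wt = _window_sums(rs, sites, halfwindow, chrom_lengths, fragment)
    wsum = wt.sum(1)
    vals = np.where(wsum > 0, cov.sum(1) / np.maximum(wsum, 1), 0.0)
    return vals * scale_factor(rs)


def heatmap_matrix(
    sites: pd.DataFrame,
    rs_by_condition: dict[str, ReadSet],
    sort_condition: str,
    halfwindow: int = 4000,
    binsize: int = 100,
    chrom_lengths: dict[str, int] | None = None,
    fragment: int = DEFAULT_FRAGMENT,
) -> tuple[pd.Index, dict[str, pd.DataFrame]]:
    """Per-site binned density matrices, rows sorted by the sort condition.

    One row per site, columns are bins over +-halfwindow; rows are ordered
    by descending total density in ``sort_condition`` (ties broken stably
    by site id) and the same order is applied to every condition.
    """
    if sort_condition not in rs_by_condition:
        raise ValueError(f"unknown sort condition {sort_condition!r}")
    nbins = (2 * halfwindow) // binsize
    offsets = -halfwindow + binsize * np.arange(nbins)
    mats: dict[str, pd.DataFrame] = {}
    for cond, rs in rs_by_condition.items():
        cov, wt = _window_sums(rs, sites, halfwindow, chrom_lengths, fragment)
        cov = cov[:, : nbins * binsize].reshape(len(sites), nbins, binsize)
        wt = wt[:, : nbins * binsize].reshape(len(sites), nbins, binsize)
        wsum = wt.sum(2)
        vals = np.where(wsum > 0, cov.sum(2) / np.maximum(wsum, 1), 0.0)
        mats[cond] = pd.DataFrame(
            vals * scale_factor(rs), index=sites["name"].to_numpy(), columns=offsets
        )
    key = mats[sort_condition]
    order_df = pd.DataFrame({"total": key.sum(axis=1).to_numpy(), "name": key.index})
    order_df = order_df.sort_values(["total", "name"], ascending=[False, True], kind="stable")
    order = pd.Index(order_df["name"])
    return order, {c: m.loc[order] for c, m in mats.items()}
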