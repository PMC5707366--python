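"""Gene-level crosstalk analysis: FPKM, induction calls, synergy/antagonism.

The classifier follows the study's printed criteria: a gene is induced
by a treatment at fold change >= 1.5 and adjusted p <= 0.05 (vs NT,
boundaries inclusive); an IL-1-induced gene is antagonized by IL-6 when
its dual-treatment fold change over NT drops to <= 1.2 (and
symmetrically for IL-6-induced genes); a dual-induced gene is
synergistic when its dual fold change reaches >= 1.2 times the additive
expectation of the two single treatments.  The additive expectation is
FC_IL1 + FC_IL6 - 1 by default (each single FC contains the baseline
once), with the plain sum available as an alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import CountMatrix, nb_test

__all__ = [
    "CrosstalkThresholds",
    "compute_fpkm",
    "transform_expression",
    "condition_means",
    "fold_changes",
    "call_differential_genes",
    "classify_crosstalk",
    "build_crosstalk_records",
    "ma_values",
]

LABELS = (
    "synergistic",
    "antagonized_by_il6",
    "antagonized_by_il1",
    "additive_dual",
    "il1_only",
    "il6_only",
    "unchanged",
)

FPKM_OFFSET = 0.1


@dataclass
class CrosstalkThresholds:
    induction_fc: float = 1.5
    induction_q: float = 0.05
    antagonism_dual_fc: float = 1.2
    synergy_ratio: float = 1.2
    additivity: str = "baseline_corrected"  # or "plain_sum"

    def __post_init__(self) -> None:
        for name in ("induction_fc", "induction_q", "antagonism_dual_fc", "synergy_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")
        if self.additivity not in ("baseline_corrected", "plain_sum"):
            raise ValueError("additivity must be 'baseline_corrected' or 'plain_sum'")

    def additive_fc(self, fc_il1, fc_il6):
        if self.additivity == "baseline_corrected":
            return fc_il1 + fc_il6 - 1.0
        return fc_il1 + fc_il6


def compute_fpkm(m: CountMatrix) -> pd.DataFrame:
    """FPKM_ij = count_ij * 1e9 / (length_i * total_j)."""
    if m.lengths is None:
        raise ValueError("feature lengths are required for FPKM")
    lengths = m.lengths.to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("all feature lengths must be positive")
    totals = m.counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("every sample must have positive total counts")
    vals = m.counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(vals, index=m.counts.index, columns=m.counts.columns)


def condition_means(fpkm: pd.DataFrame, conditions) -> pd.DataFrame:
    """Per-gene mean FPKM per condition."""
    cond = pd.Series({s: conditions[s] for s in fpkm.columns})
    return fpkm.T.groupby(cond).mean().T


def transform_expression(fpkm: pd.DataFrame, conditions) -> pd.DataFrame:
    """log2(FPKM + 0.1), centered per gene on the mean of condition averages."""
    logf = np.log2(fpkm + FPKM_OFFSET)
    center = condition_means(logf, conditions).mean(axis=1)
    return logf.sub(center, axis=0)


def fold_changes(
    fpkm: pd.DataFrame, conditions, baseline: str = "NT"
) -> pd.DataFrame:
    """Per-gene FC of each condition vs baseline on offset condition-mean FPKM."""
    means = condition_means(fpkm, conditions) + FPKM_OFFSET
    if baseline not in means.columns:
        raise ValueError(f"baseline condition {baseline!r} absent")
    fc = means.div(means[baseline], axis=0).drop(columns=[baseline])
    return fc.rename(columns=lambda c: f"fc_{c.lower()}")


def call_differential_genes(
    results: dict[str, pd.DataFrame], th: CrosstalkThresholds
) -> dict[str, dict[str, set]]:
    """Induced / repressed gene sets per treatment-vs-NT contrast.

    ``results`` maps condition name -> nb_test DataFrame for (NT, cond).
    Induced iff FC >= threshold and q <= threshold (inclusive);
    repressed iff FC <= 1/threshold and q <= threshold.
    """
    out = {}
    for cond, df in results.items():
        sig = df["q"] <= th.induction_q
        out[cond] = {
            "induced": set(df.index[(df["fc"] >= th.induction_fc) & sig]),
            "repressed": set(df.index[(df["fc"] <= 1.0 / th.induction_fc) & sig]),
        }
    return out


def classify_crosstalk(rec: pd.DataFrame, th: CrosstalkThresholds) -> pd.Series:
    """Assign each gene exactly one crosstalk label.

    ``rec`` needs columns fc_il1, fc_il6, fc_dual and boolean columns
    induced_il1, induced_il6, induced_dual.  Antagonism has precedence
    over synergy, so the two can never both hold; when a gene is induced
    by both single cytokines and antagonized in the dual treatment, the
    stronger single induction decides which cytokine is the antagonist's
    victim (i.e. which antagonized class it joins).
    """
    for col in ("fc_il1", "fc_il6", "fc_dual"):
        if (rec[col] <= 0).any():
            raise ValueError("fold changes must be positive")
    fc1 = rec["fc_il1"].to_numpy(dtype=float)
    fc6 = rec["fc_il6"].to_numpy(dtype=float)
    fcd = rec["fc_dual"].to_numpy(dtype=float)
    ind1 = rec["induced_il1"].to_numpy(dtype=bool)
    ind6 = rec["induced_il6"].to_numpy(dtype=bool)
    indd = rec["induced_dual"].to_numpy(dtype=bool)

    fc_add = th.additive_fc(fc1, fc6)
    antag = fcd <= th.antagonism_dual_fc
    labels = np.full(len(rec), "unchanged", dtype=object)

    a6 = ind1 & antag & (~ind6 | (fc1 >= fc6))
    a1 = ind6 & antag & ~a6
    syn = ~a6 & ~a1 & indd & (fcd >= th.synergy_ratio * fc_add)
    add = ~a6 & ~a1 & ~syn & indd
    rest = ~(a6 | a1 | syn | add)
    only1 = rest & ind1 & (~ind6 | (fc1 >= fc6))
    only6 = rest & ind6 & ~only1
    labels[a6] = "antagonized_by_il6"
    labels[a1] = "antagonized_by_il1"
    labels[syn] = "synergistic"
    labels[add] = "additive_dual"
    labels[only1] = "il1_only"
    labels[only6] = "il6_only"
    return pd.Series(labels, index=rec.index, name="label")


def build_crosstalk_records(
    m: CountMatrix, th: CrosstalkThresholds | None = None
) -> pd.DataFrame:
    """End-to-end per-gene record table from a count matrix.

    Runs the NB test for the three treatment-vs-NT contrasts, computes
    FPKM fold changes, induction flags and the crosstalk label.
    """
    th = th or CrosstalkThresholds()
    conds = set(m.conditions.values())
    needed = {"NT", "IL1", "IL6", "DUAL"}
    if not needed.issubset(conds):
        raise ValueError(f"count matrix must contain conditions {sorted(needed)}")
    results = {c: nb_test(m, ("NT", c)) for c in ("IL1", "IL6", "DUAL")}
    fpkm = compute_fpkm(m)
    rec = fold_changes(fpkm, m.conditions)
    calls = call_differential_genes(results, th)
    for c in ("IL1", "IL6", "DUAL"):
        rec[f"induced_{c.lower()}"] = rec.index.isin(calls[c]["induced"])
        rec[f"q_{c.lower()}"] = results[c]["q"]
    rec["label"] = classify_crosstalk(rec, th)
    return rec


def ma_values(
    fpkm: pd.DataFrame, conditions, cond_a: str, cond_b: str
) -> pd.DataFrame:
    """MA-plot coordinates: M = log2 difference, A = mean of log2 values.

    Uses condition-mean FPKM with the +0.1 offset.
    """
    means = condition_means(fpkm, conditions)
    for c in (cond_a, cond_b):
        if c not in means.columns:
            raise ValueError(f"condition {c!r} absent")
    la = np.log2(means[cond_a] + FPKM_OFFSET)
    lb = np.log2(means[cond_b] + FPKM_OFFSET)
    return pd.DataFrame({"A": (la + lb) / 2.0, "M": lb - la})
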