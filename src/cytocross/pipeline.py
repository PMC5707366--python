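"""End-to-end pipeline driver.

Runs, in order: (optional) synthetic-data simulation, differential
expression and crosstalk labeling, STAT3 site classification, H3K27ac
enhancer calls, tag-density panels (priming contrast), genomic-context
analyses (proximity, motif scores) and the lost-binding statistic under
NF-kB inhibition.  Writes TSV tables plus a machine-readable
summary.json with the headline statistics; logs every threshold used.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import context, expression, sites, synthetic, tagdensity
from .config import PipelineConfig
from .expression import CrosstalkThresholds
from .io import write_annotation, write_bed, write_counts, write_truth
from .sites import SiteThresholds
from .stats import welch_t

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("cytocross")


def _write_table(df: pd.DataFrame, path: Path, header_note: str, **to_csv_kw) -> None:
    """TSV with a comment header naming the producing version and thresholds."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# cytocross {__version__} | {header_note}\n")
        df.to_csv(fh, sep="\t", **to_csv_kw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _setup_logging(level: str) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict written to disk."""
    _setup_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th_expr = CrosstalkThresholds(
        induction_fc=config.induction_fc,
        induction_q=config.induction_q,
        antagonism_dual_fc=config.antagonism_dual_fc,
        synergy_ratio=config.synergy_ratio,
        additivity=config.additivity,
    )
    th_sites = SiteThresholds(
        assisted_fc=config.assisted_fc,
        assisted_p=config.assisted_p,
        enhancer_fc=config.enhancer_fc,
        enhancer_q=config.enhancer_q,
    )
    log.info("thresholds: %s | %s", th_expr, th_sites)
    summary: dict = {"seed": config.seed, "thresholds": {**th_expr.__dict__, **th_sites.__dict__}}

    stage = "simulate"
    try:
        if not config.simulate:
            raise NotImplementedError(
                "external-data mode requires all input paths; use the individual "
                "CLI subcommands for piecemeal analyses of external files"
            )
        syn_cfg = synthetic.demo_config() if config.preset == "demo" else None
        ds = synthetic.make_dataset(syn_cfg, seed=config.seed)
        write_truth(ds.truth, outdir / "truth.json")
        write_annotation(ds.annotation, outdir / "annotation.tsv")
        write_counts(ds.counts, outdir / "counts.tsv", outdir / "conditions.tsv")
        chrom_lengths = {k: int(v) for k, v in ds.truth.meta["chrom_lengths"].items()}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "crosstalk"
    try:
        rec = expression.build_crosstalk_records(ds.counts, th_expr)
        _write_table(rec, outdir / "crosstalk_records.tsv", f"thresholds={th_expr}")
        label_counts = rec["label"].value_counts().to_dict()
        summary["label_counts"] = {k: int(v) for k, v in label_counts.items()}
        log.info("crosstalk labels: %s", summary["label_counts"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "classify-sites"
    try:
        union = sites.merge_peak_union(
            {c: ds.peaks[("STAT3", c)] for c in synthetic.CONDITIONS}
        )
        write_bed(union, outdir / "stat3_union.bed")
        stats_df = sites.membership_stats(union)
        _write_table(stats_df, outdir / "stat3_membership.tsv", "peak-union membership", index=False)
        rs_il6 = ds.readsets[("STAT3", "IL6")]
        rs_dual = ds.readsets[("STAT3", "DUAL")]
        conditions = {rs.sample_id: "IL6" for rs in rs_il6}
        conditions |= {rs.sample_id: "DUAL" for rs in rs_dual}
        counts = sites.count_fragments(
            rs_il6 + rs_dual, union, config.extension, conditions, chrom_lengths
        )
        cls, site_summary = sites.classify_sites(
            counts, union, th_sites, universe=config.universe
        )
        _write_table(cls, outdir / "site_classification.tsv", f"thresholds={th_sites}")
        summary["sites"] = site_summary
        log.info("site classification: %s", site_summary)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "enhancers"
    try:
        k27_union = sites.merge_peak_union(
            {c: ds.peaks[("H3K27ac", c)] for c in synthetic.CONDITIONS}
        )
        rs_nt = ds.readsets[("H3K27ac", "NT")]
        rs_il1 = ds.readsets[("H3K27ac", "IL1")]
        cond = {rs.sample_id: "NT" for rs in rs_nt} | {rs.sample_id: "IL1" for rs in rs_il1}
        k27_counts = sites.count_fragments(
            rs_nt + rs_il1, k27_union, config.extension, cond, chrom_lengths
        )
        induced, reduced, enh = sites.differential_enhancers(k27_counts, ("NT", "IL1"), th_sites)
        _write_table(enh, outdir / "enhancers_il1_vs_nt.tsv", f"thresholds={th_sites}")
        summary["enhancers_il1_vs_nt"] = {"induced": len(induced), "reduced": len(reduced)}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "tagdensity"
    try:
        truth_sites = ds.truth.sites
        assisted = truth_sites[truth_sites["label"] == "assisted"].assign(
            name=lambda d: d.index
        )
        unassisted = truth_sites[truth_sites["label"] == "unassisted"].assign(
            name=lambda d: d.index
        )
        panels = {}
        for cond in ("NT", "IL1"):
            replicates = ds.readsets[("H3K27ac", cond)]
            prof = tagdensity.aggregate_profile(assisted, replicates[0], 500, 10, chrom_lengths)
            _write_table(
                prof.to_frame(), outdir / f"k27_profile_assisted_{cond}.tsv",
                "aggregate tag density, 10 bp bins, +-500 bp", index=False,
            )
            for label, sdf in (("assisted", assisted), ("unassisted", unassisted)):
                # per-site density averaged over replicate libraries
                panels[(label, cond)] = np.mean(
                    [tagdensity.site_density(sdf, rs, 100, chrom_lengths) for rs in replicates],
                    axis=0,
                )
        t_a, p_a = welch_t(panels[("assisted", "NT")], panels[("assisted", "IL1")])
        t_u, p_u = welch_t(panels[("unassisted", "NT")], panels[("unassisted", "IL1")])
        summary["priming"] = {
            "assisted_nt_vs_il1_p": float(p_a),
            "unassisted_nt_vs_il1_p": float(p_u),
        }
        log.info("H3K27ac priming p-values: %s", summary["priming"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "context"
    try:
        ann = ds.annotation
        syn_genes = set(rec.index[rec["label"] == "synergistic"])
        try:
            control = set(context.match_additive_set(rec, seed=config.seed))
        except ValueError as e:
            log.warning("additive matching degraded: %s; using full additive pool", e)
            control = set(rec.index[rec["label"] == "additive_dual"])
        n_syn, n_add = context.nearest_gene_class_counts(
            assisted, syn_genes, control, ann
        )
        summary["assisted_nearest"] = {"synergistic": n_syn, "additive_control": n_add}
        hist = context.nearest_site_histogram(
            ann[ann["gene_id"].isin(syn_genes)], assisted, 2500, 50000
        )
        _write_table(hist, outdir / "nearest_site_histogram_synergistic.tsv",
                     "nearest assisted site per synergistic gene, 2.5 kb bins", index=False)
        scores_a = [
            context.best_motif_score(int(c), 100, synthetic.STAT3_PWM, ds.genome[ch])
            for ch, c in zip(assisted["chrom"], assisted["center"])
        ]
        scores_u = [
            context.best_motif_score(int(c), 100, synthetic.STAT3_PWM, ds.genome[ch])
            for ch, c in zip(unassisted["chrom"], unassisted["center"])
        ]
        t_m, p_m = welch_t(scores_a, scores_u)
        summary["stat3_motif_score"] = {
            "assisted_mean": float(np.mean(scores_a)),
            "unassisted_mean": float(np.mean(scores_u)),
            "welch_p": float(p_m),
        }
        log.info("motif score contrast: %s", summary["stat3_motif_score"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "lost-binding"
    try:
        rs_dn = ds.readsets[("STAT3", "DN_DUAL")]
        assisted_peaks = assisted[["chrom", "start", "end", "name"]]
        cond_dn = {rs.sample_id: "DN_DUAL" for rs in rs_dn}
        dn_counts = sites.count_fragments(
            rs_dn, assisted_peaks, config.extension, cond_dn, chrom_lengths
        )
        bg = sites.sample_background_windows(
            chrom_lengths, truth_sites, int(assisted_peaks.iloc[0]["end"] - assisted_peaks.iloc[0]["start"]),
            500, config.seed,
        )
        bg_counts = sites.count_fragments(rs_dn, bg, config.extension, cond_dn, chrom_lengths)
        site_vec = dn_counts.counts.mean(axis=1).to_numpy()
        bg_vec = bg_counts.counts.mean(axis=1).to_numpy()
        scale = tagdensity.scale_factor(rs_dn[0])
        n_lost, n_total, pct = sites.lost_binding_fraction(site_vec, bg_vec, scale)
        summary["lost_binding"] = {"n_lost": n_lost, "n_total": n_total, "percent": pct}
        log.info("lost binding under DN-NFkB: %s", summary["lost_binding"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete; outputs in %s", outdir)
    return summary
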