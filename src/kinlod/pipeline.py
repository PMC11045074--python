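"""End-to-end orchestration: read → dedup → frequencies → LOD → calibrate →
classify → spatial tests, with a resolved-config snapshot and a
machine-readable summary written next to every run's outputs.

All randomness flows from ``PipelineConfig.seed`` (per-stage streams are
derived from it); two runs with the same inputs, config and seed produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from . import kin_classification as kc
from . import kinship_model as km
from . import lod_calibration as lc
from . import spatial_stats as sp

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_DEFAULT_TAUS = tuple(round(0.90 + 0.01 * k, 3) for k in range(10)) + (0.995, 0.999)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for one pipeline run (YAML/JSON serialisable)."""

    genotype_path: str | None = None
    metadata_path: str | None = None
    dialect: str = "wide"
    epsilon: float = 0.0077
    error_mode: str = "freq_draw"
    hypotheses: tuple = ("PO", "FS", "HS")
    cutoffs: tuple = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    scored_hypotheses: tuple = ("HS", "PO")
    dyad_cutoff: float = 6.0
    dyad_scored_hypothesis: str = "PO"
    calibration_n: int = 1_000_000
    seed: int = 1
    dedup_threshold: float | None = None
    dedup_sim_n: int = 20_000
    wilcoxon_sector: tuple | None = (85.0, 135.0)
    quantreg_sector: tuple | None = (80.0, 135.0)
    taus: tuple = _DEFAULT_TAUS
    n_boot: int = 500
    exclude_field_mc: bool = True

    def __post_init__(self):
        for name in ("hypotheses", "cutoffs", "scored_hypotheses", "taus"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in ("wilcoxon_sector", "quantreg_sector"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, tuple(value))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    out_dir: Path
    config: PipelineConfig
    dedup: gio.DedupResult
    loci: list
    ctx: km.KinshipModelContext
    pairscores: list
    sims: dict
    cutoff_table: lc.CutoffTable
    dyads: list
    triads: list
    elapsed: pd.DataFrame
    wilcoxon: dict
    quantile_fits: list
    summary: dict


def _dyad_frame(dyads: Sequence[kc.Dyad]) -> pd.DataFrame:
    rows = []
    for d in dyads:
        ri, rj = d.rec_i, d.rec_j
        rows.append({
            "id_i": d.pair.id_i, "id_j": d.pair.id_j,
            "lod_HS": d.pair.lod.get("HS"), "lod_PO": d.pair.lod.get("PO"),
            "ml_category": d.ml_category,
            "maternal_consistency": d.maternal_consistency,
            "presumed_mother_id": d.presumed_mother_id,
            "field_confirmed": d.field_confirmed,
            "low_confidence": d.low_confidence,
            "hap_i": ri.mtdna_haplotype, "hap_j": rj.mtdna_haplotype,
            "sex_i": ri.sex, "sex_j": rj.sex,
            "length_i": ri.body_length_m, "length_j": rj.body_length_m,
            "date_i": ri.date, "date_j": rj.date,
            "lat_i": ri.lat, "lon_i": ri.lon, "lat_j": rj.lat, "lon_j": rj.lon,
        })
    return pd.DataFrame(rows)


def _lod_distribution_summary(sims, scored_hyps) -> pd.DataFrame:
    """Histogram bins and quantiles of each simulated LOD distribution."""
    qs = (0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99)
    rows = []
    for cat, sim in sims.items():
        for scored in scored_hyps:
            values = sim.lods[scored]
            counts, edges = np.histogram(values, bins=40)
            row = {"category": cat, "scored_hyp": scored, "n": sim.n,
                   "mean": float(values.mean()),
                   "bin_edges": ";".join(f"{e:.3f}" for e in edges),
                   "bin_counts": ";".join(str(c) for c in counts)}
            for q in qs:
                row[f"q{q:g}"] = float(np.quantile(values, q))
            rows.append(row)
    return pd.DataFrame(rows)


def _write_report(out: Path, summary: dict, cutoff_table: lc.CutoffTable,
                  dyad_frame: pd.DataFrame, wilcoxon: dict) -> None:
    """Human-readable Markdown summary with the main tables embedded."""
    lines = ["# Close-kin analysis report", ""]
    stages = summary["stages"]
    lines += [
        f"- samples read: {stages['read']['n_samples']}",
        f"- unique individuals after deduplication: {stages['dedup']['n_unique']}",
        f"- pairwise LOD vectors: {stages['score']['n_pairs']}",
        f"- dyads at LOD cutoff {stages['classify']['cutoff']}: "
        f"{stages['classify']['n_dyads']} "
        f"({stages['classify']['n_by_category']}); "
        f"triads: {stages['classify']['n_triads']}",
        "",
        "## Cut-off table (observed counts with expected FP/FN)", "",
        "```", cutoff_table.frame.to_string(index=False), "```", "",
        "## Dyads", "",
        "```",
        dyad_frame.to_string(index=False) if len(dyad_frame) else "(none)",
        "```", "",
        "## Wilcoxon tests on delta longitude (PO vs U)", "",
    ]
    for name, res in wilcoxon.items():
        if res.get("testable", False):
            lines.append(f"- {name}: W = {res['statistic']:.1f}, "
                         f"p = {res['pvalue']:.3g} (n = {res['n_a']}/{res['n_b']})")
        else:
            lines.append(f"- {name}: not testable ({res.get('note', '')})")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir,
                 samples: Sequence[gio.SampleRecord] | None = None) -> PipelineResult:
    """Run the full close-kin analysis and write its tables to ``out_dir``.

    ``samples`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are read from the configured paths.  Outputs: unique
    individual table, allele-frequency report, dedup audit, pair-score
    table, cutoff table, dyad/triad/elapsed-time tables, Wilcoxon and
    quantile-regression results, ECDF export, ``summary.json`` and the
    resolved config snapshot.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    t0 = time.time()
    summary: dict = {"stages": {}}

    if samples is None:
        if config.genotype_path is None or config.metadata_path is None:
            raise ValueError("no samples passed and no input paths configured")
        samples = gio.read_samples(config.genotype_path, config.metadata_path,
                                   gio.IOConfig(dialect=config.dialect))
    summary["stages"]["read"] = {"n_samples": len(samples)}

    # Dedup on provisional frequencies; re-estimate on unique individuals.
    error = km.ErrorModel(config.epsilon, config.error_mode)
    provisional = gio.estimate_allele_freqs(samples)
    ctx0 = km.KinshipModelContext(provisional, error)
    dedup = gio.deduplicate(samples, ctx0, config.dedup_threshold,
                            n_sim=config.dedup_sim_n, seed=config.seed * 7 + 1)
    unique = dedup.unique_individuals
    summary["stages"]["dedup"] = {
        "n_unique": dedup.n_unique,
        "n_merged_away": len(samples) - dedup.n_unique,
        "groups": [{"ids": list(g.sample_ids), "kind": g.kind,
                    "retained": g.retained_id} for g in dedup.duplicate_groups],
    }
    (out / "dedup_audit.json").write_text(json.dumps(summary["stages"]["dedup"], indent=1))

    loci = gio.estimate_allele_freqs(unique)
    gio.write_samples(unique, out / "unique_genotypes.csv", out / "unique_metadata.csv")
    freq_report = {l.name: {str(a): float(f) for a, f in zip(l.alleles, l.freqs)}
                   for l in loci}
    (out / "allele_freqs.json").write_text(json.dumps(freq_report, indent=1))
    hwe = [gio.hwe_check(unique, l) for l in loci]
    summary["stages"]["hwe"] = {
        r.locus: {"p": None if r.pvalue != r.pvalue else round(r.pvalue, 4),
                  "testable": r.testable} for r in hwe}

    ctx = km.KinshipModelContext(loci, error)
    pairscores = km.score_all_pairs(unique, ctx, config.hypotheses)
    km.pairs_to_frame(pairscores).to_csv(out / "pairscores.csv", index=False)
    summary["stages"]["score"] = {"n_pairs": len(pairscores),
                                  "expected_pairs": dedup.n_unique * (dedup.n_unique - 1) // 2}

    sims = {
        cat: lc.simulate_pairs(ctx, cat, config.calibration_n,
                               config.seed * 1000 + k, scored=config.hypotheses)
        for k, cat in enumerate(("U", "PO", "HS"))
    }
    cutoff_table = lc.build_cutoff_table(pairscores, sims, config.cutoffs,
                                         scored_hyps=config.scored_hypotheses)
    cutoff_table.frame.to_csv(out / "cutoff_table.csv", index=False)
    _lod_distribution_summary(sims, config.scored_hypotheses).to_csv(
        out / "lod_distributions.csv", index=False)

    dyads = [kc.annotate_maternal(d) for d in kc.select_dyads(
        pairscores, unique, config.dyad_scored_hypothesis, config.dyad_cutoff)]
    dyad_frame = _dyad_frame(dyads)
    dyad_frame.to_csv(out / "dyads.csv", index=False)
    triads = kc.build_triads(dyads)
    (out / "triads.txt").write_text("\n".join(
        f"{' '.join(t.member_ids)} | shared: {' '.join(t.shared_ids)} | edges: "
        + "; ".join(f"{a}-{b}" for a, b in t.edges) for t in triads) + "\n")
    elapsed = kc.elapsed_time_summary(dyads)
    elapsed.to_csv(out / "elapsed_time.csv", index=False)
    summary["stages"]["classify"] = {
        "cutoff": config.dyad_cutoff,
        "n_dyads": len(dyads),
        "n_by_category": dyad_frame.ml_category.value_counts().to_dict() if len(dyads) else {},
        "n_triads": len(triads),
        "max_elapsed_years": elapsed.attrs.get("max_elapsed_years"),
    }

    # Spatial association: Wilcoxon on the full set and the restricted sector,
    # quantile regression on the (possibly different) regression sector.
    pairs_full = sp.make_spatial_pairs(unique, pairscores,
                                       exclude_field_mc=config.exclude_field_mc)
    pd.DataFrame([dataclasses.asdict(p) for p in pairs_full]).to_csv(
        out / "spatial_pairs.csv", index=False)
    wilcoxon = {"full": dataclasses.asdict(sp.wilcoxon_delta_lon(pairs_full))}
    if config.wilcoxon_sector is not None:
        pairs_sector = sp.make_spatial_pairs(unique, pairscores,
                                             sector_filter=config.wilcoxon_sector,
                                             exclude_field_mc=config.exclude_field_mc)
        wilcoxon["sector"] = dataclasses.asdict(sp.wilcoxon_delta_lon(pairs_sector))
    (out / "wilcoxon.json").write_text(json.dumps(wilcoxon, indent=1))

    pairs_qr = sp.make_spatial_pairs(unique, pairscores,
                                     sector_filter=config.quantreg_sector,
                                     exclude_field_mc=config.exclude_field_mc)
    quantile_fits: list = []
    if len(pairs_qr) >= 10:
        quantile_fits = sp.quantile_regression(pairs_qr, config.taus,
                                               n_boot=config.n_boot,
                                               seed=config.seed * 31 + 5)
        qr_rows = [{"tau": f.tau, **{f"b_{t}": f.coef[t] for t in sp._TERMS},
                    **{f"lo_{t}": f.ci_low[t] for t in sp._TERMS},
                    **{f"hi_{t}": f.ci_high[t] for t in sp._TERMS}}
                   for f in quantile_fits]
        pd.DataFrame(qr_rows).to_csv(out / "quantreg.csv", index=False)
        hs_median = sims["HS"].distribution("HS").quantile(0.5)
        ecdf = sp.ecdf_compare(pairs_qr, reference_lod=hs_median)
        ecdf.frame().to_csv(out / "ecdf.csv", index=False)
        summary["stages"]["spatial"] = {
            "n_pairs_full": len(pairs_full), "n_pairs_quantreg": len(pairs_qr),
            "hs_lod_median_simulated": hs_median,
        }
    summary["wilcoxon"] = wilcoxon
    summary["runtime_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    _write_report(out, summary, cutoff_table, dyad_frame, wilcoxon)

    return PipelineResult(out, config, dedup, loci, ctx, pairscores, sims,
                          cutoff_table, dyads, triads, elapsed, wilcoxon,
                          quantile_fits, summary)
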