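"""Summary aggregation, correlations and pipeline orchestration.

Per-population results — region counts from the sweep scan, gene counts
from annotation, ROH counts, SNPs in ROH, F_ROH moments and conserved-ROH
statistics — are aggregated into totals with derived percentages under one
fixed rounding rule (half-up, one decimal). Two small tab-separated fixture
tables transcribing the per-breed summary statistics of a published
six-population Ugandan cattle WGS panel ship with the package so that the
aggregation surface can be exercised (and its printed totals reproduced)
without any external data.

:func:`run_pipeline` wires the whole method together on real inputs:
VCF -> site filter -> µ scan -> two-step percentile filter, in parallel
VCF -> ROH calling -> F_ROH / incidence / conserved regions, then gene and
QTL annotation of both region sets, and finally aggregation.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import annotation as ann
from . import roh as roh_mod
from . import sweep_select as sw
from . import variant_io as vio
from .mu_scan import MuParams, mu_scan as run_mu_scan, write_mu_report

logger = logging.getLogger(__name__)


@dataclass
class BreedSummary:
    """One population's summary row (all counts >= 0)."""

    population_label: str
    raw_region_count: int = 0
    filtered_region_count: int = 0
    novel_gene_count: int = 0
    known_gene_count: int = 0
    n_animals: int = 0
    roh_count: int = 0
    snps_in_roh: int = 0
    froh_mean: float = float("nan")
    froh_sd: float = float("nan")
    conserved_segment_count: int = 0
    candidate_gene_count: int = 0
    roh_novel_gene_count: int = 0


def pct(numerator: float, denominator: float) -> float | None:
    """Percentage under the package-wide rounding rule: half-up, 1 decimal.

    Returns None when the denominator is zero (undefined).
    """
    if denominator == 0:
        return None
    raw = Decimal(100 * numerator) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryTotals:
    raw_region_total: int
    filtered_region_total: int
    novel_gene_total: int
    known_gene_total: int
    n_animals_total: int
    roh_total: int
    snps_in_roh_total: int
    conserved_segment_total: int
    candidate_gene_total: int
    roh_novel_gene_total: int
    filtered_region_pct: float | None
    novel_gene_pct: float | None
    known_gene_pct: float | None
    roh_novel_gene_pct: float | None


def aggregate(summaries: list[BreedSummary]) -> SummaryTotals:
    """Column sums over populations plus the derived percentages.

    Percentages: filtered regions over raw regions; novel and known genes
    over their sum (the annotated total); novel ROH-derived genes over
    ROH-derived candidate genes.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    tot = lambda f: sum(getattr(s, f) for s in summaries)  # noqa: E731
    raw, filt = tot("raw_region_count"), tot("filtered_region_count")
    novel, known = tot("novel_gene_count"), tot("known_gene_count")
    cand, roh_novel = tot("candidate_gene_count"), tot("roh_novel_gene_count")
    return SummaryTotals(
        raw_region_total=raw,
        filtered_region_total=filt,
        novel_gene_total=novel,
        known_gene_total=known,
        n_animals_total=tot("n_animals"),
        roh_total=tot("roh_count"),
        snps_in_roh_total=tot("snps_in_roh"),
        conserved_segment_total=tot("conserved_segment_count"),
        candidate_gene_total=cand,
        roh_novel_gene_total=roh_novel,
        filtered_region_pct=pct(filt, raw),
        novel_gene_pct=pct(novel, novel + known),
        known_gene_pct=pct(known, novel + known),
        roh_novel_gene_pct=pct(roh_novel, cand),
    )


def correlate(x, y) -> dict[str, float]:
    """Pearson and Spearman correlations with two-sided p-values.

    Returns NaNs when either vector has zero variance (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("correlate: zero variance; correlations undefined")
        nan = float("nan")
        return {"pearson_r": nan, "pearson_p": nan, "spearman_rho": nan, "spearman_p": nan}
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }


# ---------------------------------------------------------------------------
# shipped per-breed fixture tables (six-population Ugandan cattle WGS panel)

def load_sweep_summary_table() -> pd.DataFrame:
    """Per-breed sweep-scan summary: raw/filtered region and gene counts."""
    with resources.files("sweeproh.data").joinpath("breed_sweep_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_roh_summary_table() -> pd.DataFrame:
    """Per-breed ROH summary: segment counts, SNPs in ROH, F_ROH moments,
    breed thresholds, conserved segments and candidate genes."""
    with resources.files("sweeproh.data").joinpath("breed_roh_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def summaries_from_fixture_tables() -> list[BreedSummary]:
    """Join the two shipped tables into BreedSummary rows (one per breed)."""
    sweep = load_sweep_summary_table().set_index("breed")
    rohtab = load_roh_summary_table().set_index("breed")
    out = []
    for breed in sweep.index:
        s, r = sweep.loc[breed], rohtab.loc[breed]
        out.append(
            BreedSummary(
                population_label=breed,
                raw_region_count=int(s.raw_regions),
                filtered_region_count=int(s.filtered_regions),
                novel_gene_count=int(s.novel_genes),
                known_gene_count=int(s.known_genes),
                n_animals=int(r.n_animals),
                roh_count=int(r.n_roh),
                snps_in_roh=int(r.snps_in_roh),
                froh_mean=float(r.froh_mean),
                froh_sd=float(r.froh_sd),
                conserved_segment_count=int(r.conserved_segments),
                candidate_gene_count=int(r.candidate_genes),
                roh_novel_gene_count=int(r.novel_genes),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline orchestration

@dataclass
class PopulationConfig:
    label: str
    vcf: str
    roh_threshold_prop: float = 0.5


@dataclass
class PipelineConfig:
    populations: list[PopulationConfig]
    gtf: str | None = None
    qtl: str | None = None
    out_dir: str = "sweeproh_out"
    filter_before_scan: bool = False      # µ_SFS needs rare alleles; see docs
    site_filter: vio.SiteFilterParams = field(default_factory=vio.SiteFilterParams)
    mu: MuParams = field(default_factory=MuParams)
    sweep: sw.SweepFilterParams = field(default_factory=sw.SweepFilterParams)
    roh: roh_mod.RohParams = field(default_factory=roh_mod.RohParams)
    l_auto_kb: float | None = None        # default: span of analyzed SNPs
    min_gene_overlap_bp: int = 50_000

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pops = [PopulationConfig(**p) for p in raw.pop("populations")]
        kwargs = {}
        for key, typ in (
            ("site_filter", vio.SiteFilterParams),
            ("mu", MuParams),
            ("sweep", sw.SweepFilterParams),
            ("roh", roh_mod.RohParams),
        ):
            if key in raw:
                kwargs[key] = typ(**raw.pop(key))
        return cls(populations=pops, **raw, **kwargs)


def _auto_l_auto_kb(matrix: vio.GenotypeMatrix) -> float:
    """Autosomal length covered by the analyzed SNPs, in kb."""
    total = 0
    for c in matrix.chroms.values():
        if c.n_sites:
            total += int(c.positions[-1]) - int(c.positions[0]) + 1
    return total / 1000.0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full method for every configured population.

    Writes per-population scan reports, candidate-region BEDs, ROH segment
    tables, F_ROH tables, conserved-region BEDs, annotation summaries and a
    run manifest under ``config.out_dir``; returns the summary dict. Stage
    failures abort with a stage-labelled error; prior outputs are left on
    disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = ann.read_gtf(config.gtf) if config.gtf else []
    qtls = ann.read_qtl_table(config.qtl) if config.qtl else []
    manifest = {
        "populations": [p.label for p in config.populations],
        "parameters": {
            "site_filter": asdict(config.site_filter),
            "mu": asdict(config.mu),
            "sweep": asdict(config.sweep),
            "roh": asdict(config.roh),
            "min_gene_overlap_bp": config.min_gene_overlap_bp,
        },
        "stages": {},
    }
    summaries: list[BreedSummary] = []
    per_pop_genes: dict[str, set[str]] = {}
    results: dict = {"populations": {}}

    for pop in config.populations:
        label = pop.label
        t0 = time.perf_counter()
        try:
            matrix = vio.read_vcf(pop.vcf)
        except Exception as exc:
            raise RuntimeError(f"[{label}/read_vcf] {exc}") from exc
        scan_matrix = (
            vio.filter_sites(matrix, config.site_filter)
            if config.filter_before_scan
            else matrix
        )
        try:
            windows = run_mu_scan(scan_matrix, params=config.mu)
            regions = sw.two_step_filter(windows, config.sweep, population_label=label)
        except Exception as exc:
            raise RuntimeError(f"[{label}/mu_scan] {exc}") from exc
        write_mu_report(windows, str(out_dir / f"{label}.mu.tsv"))
        sw.write_regions_bed(regions, str(out_dir / f"{label}.sweep_regions.bed"))
        stage1 = sw.stage1_windows(windows, config.sweep)

        try:
            segments = roh_mod.call_roh_all(matrix, config.roh)
        except Exception as exc:
            raise RuntimeError(f"[{label}/call_roh] {exc}") from exc
        l_auto = config.l_auto_kb or _auto_l_auto_kb(matrix)
        froh_results = [
            roh_mod.froh(segs, l_auto, sample=s) for s, segs in segments.items()
        ]
        track = roh_mod.snp_incidence(segments, matrix)
        conserved = roh_mod.conserved_regions(
            track, len(matrix.samples), pop.roh_threshold_prop, segments, label
        )
        roh_mod.write_segments(segments, str(out_dir / f"{label}.roh.tsv"))
        roh_mod.write_froh(froh_results, str(out_dir / f"{label}.froh.tsv"))
        sw.write_regions_bed(conserved, str(out_dir / f"{label}.conserved.bed"))

        sweep_hits = ann.annotate_regions(regions, genes, config.min_gene_overlap_bp)
        conserved_hits = ann.annotate_regions(conserved, genes, config.min_gene_overlap_bp)
        sweep_gene_ids = {h.gene.gene_id for h in sweep_hits}
        per_pop_genes[label] = sweep_gene_ids
        qtl_summary = ann.qtl_overlap_summary(regions, qtls) if qtls else None

        froh_vals = np.array([f.froh for f in froh_results])
        contributing = {s for r in conserved for s in r.contributing_segments}
        cand_genes = {h.gene.gene_id for h in conserved_hits}
        summaries.append(
            BreedSummary(
                population_label=label,
                raw_region_count=len(stage1),
                filtered_region_count=len({id(h.region) for h in sweep_hits}),
                novel_gene_count=len({h.gene.gene_id for h in sweep_hits if h.status == "novel"}),
                known_gene_count=len({h.gene.gene_id for h in sweep_hits if h.status == "known"}),
                n_animals=len(matrix.samples),
                roh_count=sum(len(v) for v in segments.values()),
                snps_in_roh=int(
                    sum(int(inc.astype(bool).sum()) for _, inc in track.chroms.values())
                ),
                froh_mean=float(froh_vals.mean()) if froh_vals.size else float("nan"),
                froh_sd=float(froh_vals.std(ddof=1)) if froh_vals.size > 1 else 0.0,
                conserved_segment_count=len(contributing),
                candidate_gene_count=len(cand_genes),
                roh_novel_gene_count=len(
                    {h.gene.gene_id for h in conserved_hits if h.status == "novel"}
                ),
            )
        )
        results["populations"][label] = {
            "n_windows": len(windows),
            "n_stage1": len(stage1),
            "sweep_regions": [asdict(r) for r in regions],
            "n_roh": sum(len(v) for v in segments.values()),
            "froh": {f.sample: f.froh for f in froh_results},
            "n_conserved_regions": len(conserved),
            "qtl_summary": qtl_summary,
        }
        manifest["stages"][label] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("pipeline: %s done in %.1fs", label, time.perf_counter() - t0)

    if len(per_pop_genes) >= 2:
        unique, common = ann.gene_set_intersections(per_pop_genes)
        results["gene_intersections"] = {
            "unique_counts": {k: len(v) for k, v in unique.items()},
            "common_count": len(common),
        }
    totals = aggregate(summaries)
    results["summaries"] = [asdict(s) for s in summaries]
    results["totals"] = asdict(totals)
    write_summary_table(summaries, totals, str(out_dir / "summary.tsv"))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return results


def write_summary_table(
    summaries: list[BreedSummary], totals: SummaryTotals, path: str
) -> None:
    """Tab-separated per-population summary with a totals row."""
    cols = [
        "population_label", "raw_region_count", "filtered_region_count",
        "novel_gene_count", "known_gene_count", "n_animals", "roh_count",
        "snps_in_roh", "froh_mean", "froh_sd", "conserved_segment_count",
        "candidate_gene_count", "roh_novel_gene_count",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            fh.write("\t".join(str(getattr(s, c)) for c in cols) + "\n")
        fmt = lambda v: "NA" if v is None else str(v)  # noqa: E731
        fh.write(
            "Total\t"
            + "\t".join(
                fmt(v)
                for v in (
                    totals.raw_region_total,
                    f"{totals.filtered_region_total} ({fmt(totals.filtered_region_pct)})",
                    f"{totals.novel_gene_total} ({fmt(totals.novel_gene_pct)})",
                    f"{totals.known_gene_total} ({fmt(totals.known_gene_pct)})",
                    totals.n_animals_total,
                    totals.roh_total,
                    totals.snps_in_roh_total,
                    "", "",
                    totals.conserved_segment_total,
                    totals.candidate_gene_total,
                    f"{totals.roh_novel_gene_total} ({fmt(totals.roh_novel_gene_pct)})",
                )
            )
            + "\n"
        )


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logging to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
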