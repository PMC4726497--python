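"""End-to-end pipeline: simulate -> scan -> DE -> RIP -> enrichment ->
tripartite screen -> signature -> survival.

Each stage reads its inputs from, and writes its outputs to, a shared
output directory, so stages can be re-run individually from the CLI; a
stage whose inputs are missing fails with an error naming the stage and
the missing file. ``run_all`` executes the requested stages in order and
aggregates a JSON run report whose filter chain mirrors the study's
accounting (dysregulated -> anticorrelated -> RIP-intersected ->
tripartite; genome tripartite -> expressed -> final).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io
from .enrichment import apply_min_count_filter, motif_panel, panel_summary
from .expression import anticorrelated_genes, call_anticorrelated
from .motifs import MotifDefinition, default_motifs, load_motif_config, write_motif_config
from .rip import call_enriched, enriched_genes, intersect_anticorrelated
from .scan import annotate, scan_all
from .screen import TRIPARTITE_MOTIFS, detect_expressed, genes_with_all, percent, screen, venn
from .simulate import SimulationConfig, simulate_cohort, simulate_expression, \
    simulate_ortholog_map, simulate_rip, simulate_utrs
from .survival import GeneSignature, build_signature, map_orthologs, score_patients, \
    stratify_logrank

log = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "de", "rip", "enrich", "screen", "signature", "survival")
DRIVER = "Cnot7"


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the full run (all stages)."""

    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    alpha: float = 0.01  # DE significance level
    dysreg_rule: str = "combined"
    rip_threshold: float = 2.0
    rip_pseudocount: float = 0.5
    n_perm: int = 1000
    enrich_alpha: float = 0.05
    min_genes: int = 10  # motif-carrier floor for panel consideration
    detect_quantile: float = 0.25
    motif_config: str | None = None

    def motifs(self) -> list[MotifDefinition]:
        if self.motif_config:
            return load_motif_config(self.motif_config)
        return default_motifs()

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"]["motif_prevalence"] = dict(sorted(d["sim"]["motif_prevalence"].items()))
        return io.config_hash(d)


def _require(out: Path, stage: str, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r}: missing input {p} (run the producing stage first)"
            )
        paths.append(p)
    return paths


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.sim
    motifs = cfg.motifs()
    utrs, utr_truth = simulate_utrs(sim, motifs)
    io.write_fasta(utrs, out / "utrs.fasta")
    io.write_tsv(utr_truth, out / "utr_truth.tsv", seed=sim.seed, index=False)
    write_motif_config(motifs, str(out / "motifs.yaml"))

    matrix, anticorr_truth = simulate_expression(sim)
    io.write_expression(matrix, out / "expression.tsv", out / "groups.tsv", seed=sim.seed)
    io.write_gene_list(anticorr_truth, out / "anticorrelated_truth.txt")

    # joint planting: RIP enrichment is planted on the anticorrelated
    # truth genes, the direct-target scenario the pipeline looks for
    counts, rip_truth = simulate_rip(sim, enriched_genes=anticorr_truth or None)
    io.write_tsv(counts, out / "rip_counts.tsv", seed=sim.seed)
    io.write_gene_list(rip_truth, out / "rip_truth.txt")

    omap = simulate_ortholog_map([f"gene{i:05d}" for i in range(sim.n_genes)],
                                 seed=sim.seed)
    io.write_tsv(
        pd.DataFrame({"mouse": list(omap), "human": list(omap.values())}),
        out / "ortholog_map.tsv", seed=sim.seed, index=False,
    )


def stage_scan(cfg: PipelineConfig, out: Path) -> None:
    (fasta,) = _require(out, "scan", "utrs.fasta")
    utrs = io.read_fasta(fasta)
    motifs = cfg.motifs()
    sites = scan_all(utrs, motifs)
    io.write_tsv(sites, out / "motif_sites.tsv", seed=cfg.sim.seed, index=False)
    annotation = annotate(utrs, motifs)
    io.write_tsv(annotation, out / "annotation.tsv", seed=cfg.sim.seed)


def stage_de(cfg: PipelineConfig, out: Path) -> None:
    values_p, groups_p = _require(out, "de", "expression.tsv", "groups.tsv")
    matrix = io.read_expression(values_p, groups_p)
    results = call_anticorrelated(matrix, alpha=cfg.alpha, dysreg_rule=cfg.dysreg_rule)
    io.write_tsv(results, out / "de_results.tsv", seed=cfg.sim.seed)
    io.write_gene_list(anticorrelated_genes(results), out / "anticorrelated.txt")


def stage_rip(cfg: PipelineConfig, out: Path) -> None:
    counts_p, de_p = _require(out, "rip", "rip_counts.tsv", "de_results.tsv")
    counts = io.read_tsv(counts_p)
    calls = call_enriched(counts, cfg.rip_threshold, cfg.rip_pseudocount)
    io.write_tsv(calls, out / "rip_calls.tsv", seed=cfg.sim.seed)
    io.write_gene_list(enriched_genes(calls), out / "rip_enriched.txt")
    de = io.read_tsv(de_p)
    io.write_gene_list(intersect_anticorrelated(calls, de), out / "intersection.txt")


def stage_enrich(cfg: PipelineConfig, out: Path) -> None:
    inter_p, ann_p = _require(out, "enrich", "intersection.txt", "annotation.tsv")
    target = io.read_gene_list(inter_p)
    annotation = io.read_tsv(ann_p)
    if not target:
        log.warning("enrich: empty intersection set; writing empty panel")
        io.write_tsv(pd.DataFrame(), out / "enrichment_panel.tsv", seed=cfg.sim.seed)
        return
    results = motif_panel(target, annotation, n_perm=cfg.n_perm, seed=cfg.sim.seed,
                          alpha=cfg.enrich_alpha)
    results = apply_min_count_filter(results, cfg.min_genes)
    io.write_tsv(panel_summary(results), out / "enrichment_panel.tsv", seed=cfg.sim.seed)


def stage_screen(cfg: PipelineConfig, out: Path) -> None:
    ann_p, values_p, anti_p = _require(
        out, "screen", "annotation.tsv", "expression.tsv", "anticorrelated.txt"
    )
    annotation = io.read_tsv(ann_p)
    values = io.read_tsv(values_p)
    universe = set(annotation.index)
    expressed = detect_expressed(values.loc[values.index.isin(universe)],
                                 cfg.detect_quantile)
    anticorr = io.read_gene_list(anti_p) & universe
    report = screen(annotation, expressed, anticorr)
    io.write_json({"seed": cfg.sim.seed, **report.as_dict()}, out / "screen.json")
    io.write_gene_list(report.final_genes, out / "screen_final_genes.txt")

    # overlap accounting among the three tripartite motifs, within the
    # RIP-intersected set when available, else genome-wide
    inter_p = out / "intersection.txt"
    base = io.read_gene_list(inter_p) & universe if inter_p.exists() else universe
    sets = [
        {g for g in base if annotation.at[g, m] >= 1} for m in TRIPARTITE_MOTIFS
    ]
    regions = venn(sets)
    io.write_tsv(
        pd.DataFrame([regions]).T.rename(columns={0: "count"}).rename_axis("region"),
        out / "venn_tripartite.tsv", seed=cfg.sim.seed,
    )


def stage_signature(cfg: PipelineConfig, out: Path) -> None:
    genes_p, values_p, groups_p, omap_p = _require(
        out, "signature", "screen_final_genes.txt", "expression.tsv", "groups.tsv",
        "ortholog_map.tsv",
    )
    genes = io.read_gene_list(genes_p)
    source = "screen_final"
    if not genes:
        # fall back to the RIP-intersected anticorrelated set when the
        # genome screen is empty (small universes)
        inter_p = out / "intersection.txt"
        if inter_p.exists():
            genes = io.read_gene_list(inter_p)
            source = "rip_intersection"
            log.warning("signature: screen final set empty; using the "
                        "RIP-intersected set (%d genes)", len(genes))
    if not genes:
        raise ValueError("stage 'signature': no genes available for a signature")
    matrix = io.read_expression(values_p, groups_p)
    signature = build_signature(genes, matrix, driver=DRIVER)
    omap_df = io.read_tsv(omap_p, index_col=None)
    omap = dict(zip(omap_df["mouse"], omap_df["human"]))
    mapped, coverage = map_orthologs(signature, omap)
    if mapped is None:
        raise ValueError("stage 'signature': no signature gene has a human ortholog")
    io.write_tsv(
        pd.DataFrame({"gene": mapped.genes,
                      "weight": [mapped.entries[g] for g in mapped.genes]}),
        out / "signature.tsv", seed=cfg.sim.seed, index=False,
    )
    io.write_json(
        {"source": source,
         "n_genes": len(signature.entries), "n_mapped": len(mapped.entries),
         "ortholog_coverage": round(coverage, 4),
         "coverage_percent": percent(len(mapped.entries), len(signature.entries))},
        out / "signature_coverage.json",
    )


def stage_survival(cfg: PipelineConfig, out: Path) -> None:
    (sig_p,) = _require(out, "survival", "signature.tsv")
    sig_df = io.read_tsv(sig_p, index_col=None)
    signature = GeneSignature(dict(zip(sig_df["gene"], sig_df["weight"])))
    cohort = simulate_cohort(signature, cfg.sim)
    io.write_tsv(cohort.clinical, out / "cohort_clinical.tsv", seed=cfg.sim.seed)
    io.write_tsv(cohort.expression, out / "cohort_expression.tsv", seed=cfg.sim.seed)
    scores = score_patients(signature, cohort)
    result = stratify_logrank(scores, cohort)
    io.write_tsv(result.scores.to_frame().join(result.labels),
                 out / "patient_scores.tsv", seed=cfg.sim.seed)
    io.write_json(
        {
            "chi_square": result.chi_square,
            "p_value": result.p_value,
            "groups": {
                g: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for g, row in result.group_stats.to_dict("index").items()
            },
        },
        out / "stratification.json",
    )


_STAGE_FNS = {
    "simulate": stage_simulate,
    "scan": stage_scan,
    "de": stage_de,
    "rip": stage_rip,
    "enrich": stage_enrich,
    "screen": stage_screen,
    "signature": stage_signature,
    "survival": stage_survival,
}


def run_all(
    cfg: PipelineConfig, out_dir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the requested stages in order and write run_report.json.

    Returns the report dict. Fully deterministic under a fixed config:
    the same config and seed give a byte-identical report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)!r}")
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("[%s] running", stage)
        try:
            _STAGE_FNS[stage](cfg, out)
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report: dict = {
        "version": __version__,
        "seed": cfg.sim.seed,
        "config_hash": cfg.hash(),
        "stages_run": [s for s in STAGES if s in stages],
    }
    de_p = out / "de_results.tsv"
    if de_p.exists():
        de = io.read_tsv(de_p)
        ann = io.read_tsv(out / "annotation.tsv") if (out / "annotation.tsv").exists() else None
        chain = {
            "n_genes": int(len(de)),
            "n_dysregulated": int(de["dysregulated"].sum()),
            "n_anticorrelated": int(de["anticorrelated"].sum()),
        }
        inter_p = out / "intersection.txt"
        if inter_p.exists():
            inter = io.read_gene_list(inter_p)
            chain["n_rip_intersected"] = len(inter)
            if ann is not None and inter:
                tri = genes_with_all(ann, list(TRIPARTITE_MOTIFS)) & inter
                chain["n_tripartite_in_intersection"] = len(tri)
                chain["tripartite_percent"] = percent(len(tri), len(inter))
        report["target_chain"] = chain
    screen_p = out / "screen.json"
    if screen_p.exists():
        import json

        report["genome_screen"] = json.loads(screen_p.read_text())
    cov_p = out / "signature_coverage.json"
    if cov_p.exists():
        import json

        report["signature"] = json.loads(cov_p.read_text())
    strat_p = out / "stratification.json"
    if strat_p.exists():
        import json

        report["survival"] = json.loads(strat_p.read_text())
    io.write_json(report, out / "run_report.json")
    return report
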