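"""End-to-end orchestration: simulate/load -> homology -> boundary ->
expression -> knockout -> integrate, with stage-tagged logging and full
parameter provenance in every report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import simulate
from .boundary import (ClusterScoringParams, DEFAULT_SCORING, boundary_report,
                       predict_cluster)
from .core import GenomeTable, load_genome, write_genome
from .expression import (DEFAULT_THRESHOLDS, ExpressionThresholds, analyze_locus,
                         load_ct_table, write_results)
from .homology import AlignmentParams, DEFAULT_PARAMS, write_graph
from .integrate import build_evidence, call_bgc, render_report, write_report
from .knockout import (DEFAULT_KO_THRESHOLDS, KnockoutThresholds,
                       evaluate_knockout_panel, load_profiles, write_phenotypes)

log = logging.getLogger("bgcbound")

FIXTURES = ("m7_atcc18224", "pm1_nonsyntenic", "fig2b", "fig4")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs and parameters for one run.

    Either ``fixture`` (with ``seed``) or explicit file paths must be given.
    Defaults reproduce the reference analysis: E-value cutoff 1e-10,
    extension to 35 genes, negative penalty -0.3, significance level 0.05.
    """

    fixture: Optional[str] = None
    seed: int = 42
    genome_a_table: Optional[str] = None
    genome_a_fasta: Optional[str] = None
    genome_b_table: Optional[str] = None
    genome_b_fasta: Optional[str] = None
    ct_table: Optional[str] = None
    ref_gene: str = "GAPDH"
    strain_case: str = "dmrpigB"
    strain_calibrator: str = "M7"
    profiles: Optional[str] = None
    wt_strain: str = "M7"
    strain_gene_map: dict[str, str] = field(default_factory=dict)
    alignment: AlignmentParams = DEFAULT_PARAMS
    scoring: ClusterScoringParams = DEFAULT_SCORING
    expression_thresholds: ExpressionThresholds = DEFAULT_THRESHOLDS
    knockout_thresholds: KnockoutThresholds = DEFAULT_KO_THRESHOLDS
    out_dir: Optional[str] = None


@dataclass
class RunResult:
    status: str                  # "success" | "no-cluster"
    report: dict
    call: object = None
    prediction: object = None

    @property
    def exit_code(self) -> int:
        return {"success": 0, "no-cluster": 3}[self.status]


def _resolve_inputs(config: PipelineConfig):
    """Return (genome_a, genome_b, ct_df or None, (wt, mutants) or None, gene_map)."""
    if config.fixture is not None:
        if config.fixture == "m7_atcc18224":
            pair = simulate.fixture_m7_atcc18224(config.seed)
            ct = simulate.fixture_fig2b(config.seed + 1)
            panel = simulate.fixture_fig4(config.seed + 2)
            return pair.genome_a, pair.genome_b, ct, panel, dict(simulate.FIG4_STRAIN_GENES)
        if config.fixture == "pm1_nonsyntenic":
            pair = simulate.fixture_pm1_nonsyntenic(config.seed)
            return pair.genome_a, pair.genome_b, None, None, {}
        raise PipelineError(f"fixture {config.fixture!r} is not runnable end-to-end "
                            f"(choose from m7_atcc18224, pm1_nonsyntenic)")
    if not all([config.genome_a_table, config.genome_a_fasta,
                config.genome_b_table, config.genome_b_fasta]):
        raise PipelineError("need either a fixture or both genomes' table+fasta paths")
    ga = load_genome(config.genome_a_table, config.genome_a_fasta)
    gb = load_genome(config.genome_b_table, config.genome_b_fasta)
    ct = load_ct_table(config.ct_table) if config.ct_table else None
    panel = None
    if config.profiles:
        profs = load_profiles(config.profiles)
        if config.wt_strain not in profs:
            raise PipelineError(f"wild-type strain {config.wt_strain!r} absent from profiles")
        wt = profs.pop(config.wt_strain)
        panel = (wt, list(profs.values()))
    return ga, gb, ct, panel, dict(config.strain_gene_map)


def _provenance(config: PipelineConfig) -> dict:
    return {
        "fixture": config.fixture,
        "seed": config.seed,
        "alignment": dict(config.alignment.__dict__),
        "scoring": dict(config.scoring.__dict__),
        "expression_thresholds": dict(config.expression_thresholds.__dict__),
        "knockout_thresholds": dict(config.knockout_thresholds.__dict__),
    }


def run_all(config: PipelineConfig) -> RunResult:
    """Run every stage and emit the consensus report.

    Returns a RunResult whose ``status`` is "no-cluster" when the
    comparative stage finds no seed, "success" otherwise; stage failures
    raise with the stage name.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    log.info("[inputs] resolving genomes and assay tables")
    genome_a, genome_b, ct, panel, gene_map = _resolve_inputs(config)

    log.info("[boundary] comparative stage on %s vs %s",
             genome_a.genome_id, genome_b.genome_id)
    prediction = predict_cluster(genome_a, genome_b, config.alignment, config.scoring)
    if out and prediction.graph is not None:
        write_graph(prediction.graph, out / "homologs.tsv")
    b_report = boundary_report(prediction)
    if not prediction.found:
        log.warning("[boundary] no cluster found: %s", prediction.reason)
        report = {"status": "no-cluster", "boundary": b_report,
                  "params": _provenance(config)}
        if out:
            import json
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2)
        return RunResult(status="no-cluster", report=report)
    call = prediction.call
    log.info("[boundary] trimmed span %s..%s (%d genes), CB=%.3f",
             call.i_begin, call.i_end, call.n_genes_a, call.cb_score)

    expression = None
    if ct is not None:
        log.info("[expression] comparative-CT analysis (%s vs %s, ref %s)",
                 config.strain_case, config.strain_calibrator, config.ref_gene)
        expression = analyze_locus(ct, config.ref_gene, config.strain_case,
                                   config.strain_calibrator,
                                   config.expression_thresholds)
        if out:
            write_results(expression, out / "expression.tsv")

    phenotypes = None
    ko_by_gene = None
    if panel is not None:
        wt, mutants = panel
        log.info("[knockout] classifying %d mutant profiles against %s",
                 len(mutants), wt.strain)
        phenotypes = evaluate_knockout_panel(wt, mutants, config.knockout_thresholds)
        if out:
            write_phenotypes(phenotypes, out / "phenotypes.tsv")
        ko_by_gene = {}
        for strain, ph in phenotypes.items():
            gene = gene_map.get(strain)
            if gene is not None:
                ko_by_gene[gene] = ph.category

    log.info("[integrate] consensus call from %d evidence streams",
             1 + (expression is not None) + (phenotypes is not None))
    contig = call.genes_a[0].contig
    locus_order = [g.gene_id for g in genome_a.genes if g.contig == contig]
    known = set(locus_order)
    if expression is not None:
        expression_for_call = [r for r in expression if r.gene in known]
    else:
        expression_for_call = None
    evidence = build_evidence(locus_order, [g.gene_id for g in call.genes_a],
                              expression_for_call, ko_by_gene)
    bgc = call_bgc(evidence)
    log.info("[integrate] final call %s..%s (%d genes)",
             bgc.first_gene, bgc.last_gene, bgc.n_genes)

    report = render_report(bgc, boundary=b_report, expression=expression,
                           phenotypes=phenotypes, params=_provenance(config))
    report["status"] = "success"
    if out:
        write_report(report, out / "report.json", out / "report.txt")
    return RunResult(status="success", report=report, call=bgc, prediction=prediction)


def write_fixture(fixture: str, seed: int, out_dir) -> list[str]:
    """Materialize a named fixture's standard input files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def genomes(pair):
        for genome, tag in ((pair.genome_a, "a"), (pair.genome_b, "b")):
            t = out / f"genome_{tag}.tsv"
            f = out / f"genome_{tag}.fasta"
            write_genome(genome, t, f)
            written.extend([str(t), str(f)])

    if fixture == "m7_atcc18224":
        genomes(simulate.fixture_m7_atcc18224(seed))
    elif fixture == "pm1_nonsyntenic":
        genomes(simulate.fixture_pm1_nonsyntenic(seed))
    elif fixture == "fig2b":
        p = out / "ct_table.csv"
        simulate.write_ct_table(simulate.fixture_fig2b(seed), p)
        written.append(str(p))
    elif fixture == "fig4":
        wt, mutants = simulate.fixture_fig4(seed)
        p = out / "profiles.csv"
        simulate.write_profiles(wt, mutants, p)
        written.append(str(p))
    else:
        raise PipelineError(f"unknown fixture {fixture!r}; choose from {FIXTURES}")
    return written
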