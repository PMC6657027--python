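"""End-to-end pipeline wiring the analysis stages over files on disk.

Each stage reads validated tables, runs the corresponding library module
and writes result TSVs with provenance headers.  ``run_pipeline`` executes
the stages in dependency order; an optional evaluation step joins the
recovered signals against a simulation manifest by exact key and prints
recovery metrics.  Logging goes to standard error; result tables never do.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hotspot as hotspot_mod
from . import intersect as intersect_mod
from . import io_tables
from . import rewiring as rewiring_mod
from . import spectra as spectra_mod
from .model import MutationSource, Relation

logger = logging.getLogger("ptmut")

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_VALIDATION = 3
EXIT_STAGE = 4


@dataclass
class PipelineConfig:
    """Paths and stage parameters; defaults are the standard analysis
    settings (3-tumor recurrence cutoff, +/-5 compile window, +/-7 flank,
    no stringency threshold)."""

    fasta: str
    ptm_table: str
    somatic_table: str
    germline_table: str | None = None
    pssm_dir: str | None = None
    external_scores: str | None = None
    outdir: str = "ptmut_out"
    min_tumors: int = 3
    compile_window: int = 5
    flank_half_width: int = 7
    stringency_percentile: float | None = None
    grouping: str = "wt_residue"
    score_orientation: int = 1
    adjust_p: bool = False
    deterministic_headers: bool = False
    manifest: str | None = None
    column_maps: dict = field(default_factory=dict)

    def writer_kwargs(self, **params) -> dict:
        return {"params": params, "deterministic_header": self.deterministic_headers}


def _load_inputs(config: PipelineConfig):
    proteome = io_tables.index_proteome(io_tables.read_fasta(config.fasta))
    sites, site_rejects = io_tables.read_ptm_table(
        config.ptm_table, proteome, column_map=config.column_maps.get("ptm")
    )
    somatic, somatic_rejects = io_tables.read_mutation_table(
        config.somatic_table, MutationSource.SOMATIC,
        column_map=config.column_maps.get("somatic"),
    )
    germline: list = []
    if config.germline_table:
        germline, _ = io_tables.read_mutation_table(
            config.germline_table, MutationSource.GERMLINE,
            column_map=config.column_maps.get("germline"),
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, report in (("ptm", site_rejects), ("somatic", somatic_rejects)):
        if len(report):
            io_tables.write_table(
                report.to_frame(), outdir / f"rejected_{name}.tsv",
                **config.writer_kwargs(stage="validation"),
            )
    return proteome, sites, somatic, germline


def stage_hotspot(config: PipelineConfig, proteome, somatic) -> list:
    outdir = Path(config.outdir)
    profiles = hotspot_mod.profile_all(somatic)
    rows = []
    for p in profiles:
        top_type, top_count = max(p.type_counts.items(), key=lambda kv: (kv[1], kv[0]))
        record = {
            "protein_id": p.protein_id, "n": p.n, "k": p.k,
            "S": p.entropy_S, "S0": p.entropy_S0, "delta_S": p.delta_S,
            "top_mutation": f"{top_type[2]}{top_type[1]}{top_type[3]}",
            "top_count": top_count,
        }
        if p.protein_id in proteome:
            log_density, ratio = hotspot_mod.mutation_density(p, proteome[p.protein_id])
            record["log_density"] = log_density
            record["density"] = ratio
        rows.append(record)
    io_tables.write_table(
        pd.DataFrame(rows), outdir / "hotspot_scores.tsv",
        **config.writer_kwargs(stage="hotspot"),
    )
    hotspots = hotspot_mod.recurrence_filter(somatic, min_tumors=config.min_tumors)
    contexts = sorted({c for h in hotspots for c in h.per_context_counts})
    hs_rows = [
        {
            "protein_id": h.mutation_type[0], "position": h.mutation_type[1],
            "wt_residue": h.mutation_type[2], "mut_residue": h.mutation_type[3],
            "tumor_count": h.tumor_count,
            **{f"n_{c}": h.per_context_counts.get(c, 0) for c in contexts},
        }
        for h in hotspots
    ]
    io_tables.write_table(
        pd.DataFrame(hs_rows), outdir / "hotspot_mutations.tsv",
        **config.writer_kwargs(stage="hotspot", min_tumors=config.min_tumors),
    )
    logger.info("hotspot: %d profiles, %d hotspot mutations", len(profiles), len(hotspots))
    return hotspots


def _hotspot_records(somatic, hotspots):
    """Mutation records restricted to the recurrent hotspot types."""
    keep = {h.mutation_type for h in hotspots}
    return [m for m in somatic if m.mutation_type in keep]


def stage_intersect(config: PipelineConfig, proteome, sites, somatic_hotspot_records, germline):
    outdir = Path(config.outdir)
    all_records = []
    for mutations in (somatic_hotspot_records, germline):
        if not mutations:
            continue
        all_records.extend(intersect_mod.find_direct_hits(mutations, sites))
        all_records.extend(
            intersect_mod.find_flank_hits(mutations, sites, half_width=config.compile_window)
        )
    rows = [
        {
            "protein_id": r.site.protein_id, "site_position": r.site.position,
            "site_residue": r.site.residue, "ptm_type": r.site.ptm_type,
            "evidence_refs": r.site.evidence_refs,
            "mutation_position": r.mutation_type[1],
            "wt_residue": r.mutation_type[2], "mut_residue": r.mutation_type[3],
            "relation": r.relation.value, "offset": r.offset, "source": r.source.value,
        }
        for r in sorted(
            all_records,
            key=lambda r: (r.site.protein_id, r.site.position, r.offset,
                           r.site.ptm_type, r.mutation_type, r.source.value),
        )
    ]
    io_tables.write_table(
        pd.DataFrame(rows), outdir / "intersections.tsv",
        **config.writer_kwargs(stage="intersect", compile_window=config.compile_window),
    )
    mutations_for_enrichment = list(somatic_hotspot_records) + list(germline)
    enrichment = intersect_mod.expected_ptm_mutations(
        mutations_for_enrichment, sites, proteome, adjust=config.adjust_p
    )
    enr_rows = [
        {
            "category": e.category, "observed": e.observed, "expected": e.expected,
            "site_mutated": e.contingency[0][0], "site_unmutated": e.contingency[0][1],
            "nonsite_mutated": e.contingency[1][0], "nonsite_unmutated": e.contingency[1][1],
            "p_value": e.p_value, "adjusted_p": e.adjusted_p,
        }
        for e in enrichment
    ]
    io_tables.write_table(
        pd.DataFrame(enr_rows), outdir / "enrichment.tsv",
        **config.writer_kwargs(stage="intersect", adjust=config.adjust_p),
    )
    logger.info("intersect: %d pairs, %d enrichment categories", len(all_records), len(enrichment))
    return all_records


def stage_rewire(config: PipelineConfig, proteome, intersections):
    outdir = Path(config.outdir)
    pssms = io_tables.read_pssm_dir(config.pssm_dir)
    flank_hits = [r for r in intersections if r.relation is Relation.FLANK]
    pairs = rewiring_mod.build_flank_pairs(flank_hits, proteome, half_width=config.flank_half_width)
    background = None
    if config.stringency_percentile is not None:
        background = {
            p.kinase_name: rewiring_mod.calibrate_background(p, proteome) for p in pssms
        }
    scores = rewiring_mod.score_all(
        pairs, pssms, background=background,
        stringency_percentile=config.stringency_percentile,
    )
    io_tables.write_table(
        rewiring_mod.delta_scores_to_frame(scores), outdir / "delta_scores.tsv",
        **config.writer_kwargs(stage="rewire", half_width=config.flank_half_width),
    )
    logger.info("rewire: %d flank pairs x %d kinases -> %d scores",
                len(pairs), len(pssms), len(scores))
    if config.external_scores:
        external = rewiring_mod.read_delta_scores(
            config.external_scores, score_orientation=config.score_orientation
        )
        report = rewiring_mod.sign_agreement(scores, external)
        rep_rows = [{
            "n_matched": report.n_matched, "n_agree": report.n_agree,
            "n_zero_excluded": report.n_zero_excluded,
            "fraction_agree": report.fraction_agree,
        }]
        for group, (m, ag) in report.per_group.items():
            rep_rows.append({"kinase_group": group, "n_matched": m, "n_agree": ag,
                             "fraction_agree": ag / m if m else None})
        io_tables.write_table(
            pd.DataFrame(rep_rows), outdir / "sign_agreement.tsv",
            **config.writer_kwargs(stage="rewire"),
        )
    return scores


def stage_spectra(config: PipelineConfig, mutations, sites):
    outdir = Path(config.outdir)
    matrix = spectra_mod.count_substitutions(mutations, sites, grouping=config.grouping)
    spectra_mod.normalize_rows(matrix)
    io_tables.write_table(
        matrix.counts.reset_index(names="category"), outdir / "spectrum_counts.tsv",
        **config.writer_kwargs(stage="spectra", grouping=config.grouping),
    )
    io_tables.write_table(
        matrix.normalized.reset_index(names="category"), outdir / "spectrum_normalized.tsv",
        **config.writer_kwargs(stage="spectra", grouping=config.grouping),
    )
    nonzero = matrix.normalized.loc[matrix.normalized.sum(axis=1) > 0]
    if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2:
        pruned = spectra_mod.SubstitutionMatrix(
            counts=matrix.counts.loc[nonzero.index], normalized=nonzero,
            grouping=matrix.grouping,
        )
        clusters = spectra_mod.cluster_rows_cols(pruned)
        with open(outdir / "spectrum_clusters.txt", "w") as fh:
            fh.write("row_order\t" + "\t".join(clusters.row_order) + "\n")
            fh.write("col_order\t" + "\t".join(clusters.col_order) + "\n")
            fh.write("row_tree\t" + clusters.row_tree + "\n")
            fh.write("col_tree\t" + clusters.col_tree + "\n")
    logger.info("spectra: %d x %d matrix, total %d", *matrix.counts.shape, matrix.total)
    return matrix


def evaluate_against_manifest(config: PipelineConfig, hotspots, intersections) -> pd.DataFrame:
    """Join recovered signals against the simulation manifest by exact key."""
    manifest = pd.read_csv(config.manifest, sep="\t", comment="#", keep_default_na=False)
    recovered_hotspots = {h.mutation_type for h in hotspots}
    mimic_records = {
        (r.mutation_type[0], r.mutation_type[1], r.mutation_type[2], r.mutation_type[3])
        for r in intersections if r.relation is Relation.MIMIC
    }
    rows = []
    for row in manifest.itertuples(index=False):
        key = (str(row.protein_id), int(row.position), str(row.wt_residue), str(row.mut_residue))
        if row.kind in ("hotspot", "flank_event"):
            planted_count = int(float(row.tumor_count))
            recovered = (
                key in recovered_hotspots
                if planted_count >= config.min_tumors
                else key not in recovered_hotspots
            )
        elif row.kind == "mimic":
            recovered = key in mimic_records
        else:
            recovered = False
        rows.append({"kind": row.kind, "protein_id": key[0], "position": key[1],
                     "wt_residue": key[2], "mut_residue": key[3], "recovered": recovered})
    frame = pd.DataFrame(rows)
    if len(frame):
        by_kind = frame.groupby("kind")["recovered"].agg(["sum", "count"])
        for kind, (n_rec, n_tot) in by_kind.iterrows():
            logger.info("evaluate: %s recovered %d/%d", kind, n_rec, n_tot)
    io_tables.write_table(frame, Path(config.outdir) / "recovery.tsv",
                          **config.writer_kwargs(stage="evaluate"))
    return frame


def run_pipeline(config: PipelineConfig, evaluate: bool = False) -> int:
    t0 = time.time()
    for path in (config.fasta, config.ptm_table, config.somatic_table,
                 config.germline_table, config.external_scores, config.manifest):
        if path and not os.path.exists(path):
            logger.error("missing input file: %s", path)
            return EXIT_CONFIG
    if config.pssm_dir and not os.path.isdir(config.pssm_dir):
        logger.error("missing PSSM directory: %s", config.pssm_dir)
        return EXIT_CONFIG
    proteome, sites, somatic, germline = _load_inputs(config)
    hotspots = stage_hotspot(config, proteome, somatic)
    hotspot_records = _hotspot_records(somatic, hotspots)
    intersections = stage_intersect(config, proteome, sites, hotspot_records, germline)
    if config.pssm_dir:
        stage_rewire(config, proteome, intersections)
    stage_spectra(config, hotspot_records + germline, sites)
    if evaluate:
        if not config.manifest:
            logger.error("--evaluate requires a manifest path")
            return EXIT_CONFIG
        evaluate_against_manifest(config, hotspots, intersections)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return EXIT_OK
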