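"""End-to-end orchestration: from gene sets to the full report bundle.

Runs, per species: validation and length filtering; per-gene composition,
RSCU, ENC, GRAVY, AROMO; self-referential CAI weights and CAI; the ΔRSCU
optimal-codon procedure and the CBI/FOP indices it feeds; neutrality,
ENC-plot and PR2 diagnostics; index correlations; and correspondence
analysis of the gene x codon RSCU matrix. Across species it pools RSCU
per species and clusters species hierarchically. Stages fail soft: an
error in one stage is recorded and later stages still run where their
inputs exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_statistics as cstat
from . import expression_indices as expr
from . import selection_analyses as sel
from . import coa_optimal as coa
from .genetic_code import get_code
from .sequence_io import GeneSet, load_fasta, filter_min_length, validate_gene_set

log = logging.getLogger(__name__)

INDEX_COLUMNS = [
    "species", "gene", "n_codons", "pct_A", "pct_T", "pct_G", "pct_C",
    "GC", "GC1", "GC2", "GC3", "GC12", "GC3s", "A3s", "T3s", "G3s", "C3s",
    "ENC", "CAI", "CBI", "FOP", "GRAVY", "AROMO",
]

CORRELATION_INDICATORS = [
    "GC1", "GC2", "GC3", "GC3s", "GC", "ENC", "CAI", "CBI", "FOP", "GRAVY", "AROMO",
]

AXIS_INDICATORS = ["GC", "GC3s", "ENC", "CAI", "CBI", "FOP"]


@dataclass
class AnalysisConfig:
    transl_table: int = 1
    min_aa: int = 100
    cai_ref: str | Path | None = None  # FASTA of reference genes; None = self
    frac: float = coa.HIGH_LOW_FRACTION
    delta_threshold: float = coa.DELTA_RSCU_THRESHOLD
    pr2_scope: str = "fourfold"
    neutrality_gc3: str = "GC3"  # or "GC3s"
    linkage: str = "average"
    metric: str = "euclidean"
    output_dir: str | Path | None = None

    def serialize(self) -> str:
        return "\n".join(f"{k}={getattr(self, k)}" for k in vars(self)) + "\n"


@dataclass
class SpeciesResult:
    species: str
    index_table: pd.DataFrame
    rscu_long: pd.DataFrame
    optimal_report: coa.OptimalCodonReport | None = None
    neutrality: sel.NeutralityFit | None = None
    enc_plot: list[sel.ENCPlotRecord] = field(default_factory=list)
    pr2: list[sel.PR2Record] = field(default_factory=list)
    correlations: pd.DataFrame | None = None
    coa_result: coa.COAResult | None = None
    axis_corr: pd.DataFrame | None = None
    pooled_rscu: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class ReportBundle:
    per_species: list[SpeciesResult]
    species_means: pd.DataFrame
    species_rscu_matrix: pd.DataFrame | None = None
    tree: coa.SpeciesTree | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def index_table(self) -> pd.DataFrame:
        return pd.concat([s.index_table for s in self.per_species], ignore_index=True)


def _analyze_species(gs: GeneSet, cfg: AnalysisConfig) -> SpeciesResult:
    code = gs.code
    errors: dict[str, str] = {}
    counts = {g.gene: cstat.count_codons(g, code) for g in gs}
    profiles = {g.gene: cstat.base_composition(counts[g.gene]) for g in gs}

    ref = load_fasta(cfg.cai_ref, species="cai-ref", code=code) if cfg.cai_ref else gs
    weights = expr.cai_weights(ref, code)
    cai_by_gene = {g.gene: expr.cai(counts[g.gene], weights, code) for g in gs}

    optimal_report = None
    try:
        optimal_report = coa.optimal_codons(
            gs, cai_by_gene, frac=cfg.frac, delta_threshold=cfg.delta_threshold
        )
        opt_set = expr.OptimalCodonSet(codons=optimal_report.optimal)
    except ValueError as e:
        errors["optimal_codons"] = str(e)
        opt_set = expr.OptimalCodonSet(codons=frozenset())

    records: list[expr.UsageIndexRecord] = []
    rows = []
    rscu_rows = []
    for g in gs:
        cct = counts[g.gene]
        prof = profiles[g.gene]
        third = cstat.synonymous_third_position_stats(cct, code)
        enc_rec = cstat.enc(cct, code)
        vals: dict[str, float | None] = {
            "n_codons": cct.n_codons_total,
            "pct_A": prof.pct_A, "pct_T": prof.pct_T,
            "pct_G": prof.pct_G, "pct_C": prof.pct_C,
            "GC": prof.GC, "GC1": prof.GC1, "GC2": prof.GC2,
            "GC3": prof.GC3, "GC12": prof.GC12,
            "GC3s": None if third["GC3s"] is None else 100.0 * third["GC3s"],
            "A3s": None if third["A3s"] is None else 100.0 * third["A3s"],
            "T3s": None if third["T3s"] is None else 100.0 * third["T3s"],
            "G3s": None if third["G3s"] is None else 100.0 * third["G3s"],
            "C3s": None if third["C3s"] is None else 100.0 * third["C3s"],
            "ENC": enc_rec.enc,
            "CAI": cai_by_gene[g.gene],
            "GRAVY": cstat.gravy(g, code),
            "AROMO": cstat.aromo(g, code),
        }
        if len(opt_set):
            try:
                vals["CBI"] = expr.cbi(cct, opt_set, code)
            except ValueError as e:
                vals["CBI"] = None
                errors.setdefault("cbi", str(e))
            vals["FOP"] = expr.fop(cct, opt_set, code)
        else:
            vals["CBI"] = None
            vals["FOP"] = None
        records.append(
            expr.UsageIndexRecord(
                species=gs.species, gene=g.gene, n_codons=cct.n_codons_total, values=vals
            )
        )
        rows.append({"species": gs.species, "gene": g.gene, **vals})
        gene_rscu = cstat.rscu(cct, code)
        for c in code.synonymous_codons:
            rscu_rows.append(
                dict(
                    species=gs.species, scope=g.gene, codon=c,
                    aa=code.codon_to_aa[c], count=cct.get(c),
                    rscu=gene_rscu.rscu.get(c, 0.0),
                )
            )

    index_table = pd.DataFrame(rows)[INDEX_COLUMNS]
    result = SpeciesResult(
        species=gs.species,
        index_table=index_table,
        rscu_long=pd.DataFrame(rscu_rows),
        optimal_report=optimal_report,
        errors=errors,
    )

    try:
        profs = [profiles[g.gene] for g in gs]
        if cfg.neutrality_gc3 == "GC3s":
            result.neutrality = _neutrality_on_gc3s(index_table)
        else:
            result.neutrality = sel.neutrality_fit(profs)
    except ValueError as e:
        errors["neutrality"] = str(e)

    for g in gs:
        third = cstat.synonymous_third_position_stats(counts[g.gene], code)
        enc_rec = cstat.enc(counts[g.gene], code)
        if third["GC3s"] is not None and enc_rec.enc is not None:
            result.enc_plot.append(
                sel.ENCPlotRecord(
                    gene=g.gene,
                    gc3s=third["GC3s"],
                    enc_obs=enc_rec.enc,
                    enc_exp=sel.enc_expected(third["GC3s"]),
                )
            )
        result.pr2.append(sel.pr2_point(counts[g.gene], code, gene=g.gene, scope=cfg.pr2_scope))

    try:
        result.correlations = sel.index_correlations(records, CORRELATION_INDICATORS)
    except ValueError as e:
        errors["correlations"] = str(e)

    try:
        mat = coa.rscu_matrix_from_genes(gs)
        result.coa_result = coa.coa_on_rscu(mat)
        result.axis_corr = coa.axis_correlations(result.coa_result, records, AXIS_INDICATORS)
    except ValueError as e:
        errors["coa"] = str(e)

    result.pooled_rscu = cstat.rscu(cstat.pooled_counts(gs), code).rscu
    return result


def _neutrality_on_gc3s(index_table: pd.DataFrame) -> sel.NeutralityFit:
    from .codon_statistics import CompositionProfile

    profs = [
        CompositionProfile(
            pct_A=0, pct_T=0, pct_G=0, pct_C=0, GC=0,
            GC1=row.GC1, GC2=row.GC2, GC3=row.GC3s,
        )
        for row in index_table.itertuples()
        if not pd.isna(row.GC3s)
    ]
    return sel.neutrality_fit(profs)


def summarize_species(index_table: pd.DataFrame) -> pd.Series:
    """Unweighted arithmetic means of every index across one species' genes."""
    if index_table.empty:
        raise ValueError("no gene records to summarize")
    return index_table.drop(columns=["species", "gene"]).mean(numeric_only=True)


def run_full_analysis(
    gene_sets: list[GeneSet],
    cfg: AnalysisConfig | None = None,
    prefiltered: bool = False,
) -> ReportBundle:
    """Full per-species and cross-species analysis over validated gene sets."""
    cfg = cfg or AnalysisConfig()
    if not gene_sets:
        raise ValueError("no input gene sets")
    errors: dict[str, str] = {}
    per_species: list[SpeciesResult] = []
    for gs in gene_sets:
        try:
            gs = validate_gene_set(gs)
            if not prefiltered:
                gs = filter_min_length(gs, cfg.min_aa)
            per_species.append(_analyze_species(gs, cfg))
        except Exception as e:  # fail-soft per species
            errors[gs.species] = str(e)
            log.error("species %s failed: %s", gs.species, e)
    if not per_species:
        raise RuntimeError(f"every species failed: {errors}")

    means = pd.DataFrame(
        {s.species: summarize_species(s.index_table) for s in per_species}
    ).T.rename_axis("species").reset_index()

    bundle = ReportBundle(per_species=per_species, species_means=means, errors=errors)
    if len(per_species) >= 2:
        code = get_code(cfg.transl_table)
        cols = list(code.synonymous_codons)
        mat = pd.DataFrame.from_dict(
            {s.species: [s.pooled_rscu.get(c, 0.0) for c in cols] for s in per_species},
            orient="index",
            columns=cols,
        )
        bundle.species_rscu_matrix = mat
        try:
            bundle.tree = coa.rscu_cluster(mat, method=cfg.linkage, metric=cfg.metric)
        except ValueError as e:
            errors["clustering"] = str(e)
    else:
        log.info("single species: cross-species clustering skipped")
    return bundle


def run_from_fasta(
    inputs: dict[str, str | Path], cfg: AnalysisConfig | None = None
) -> ReportBundle:
    """Load one FASTA per species and run the full analysis."""
    cfg = cfg or AnalysisConfig()
    code = get_code(cfg.transl_table)
    gene_sets = [load_fasta(p, species=sp, code=code) for sp, p in inputs.items()]
    return run_full_analysis(gene_sets, cfg)


def _round2(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(2)


def write_bundle(bundle: ReportBundle, out_dir: str | Path, cfg: AnalysisConfig | None = None) -> Path:
    """Write the TSV bundle (2-decimal tables plus full-precision copies).

    Verifies on write that per-species means equal the mean of the per-gene
    rows being written (internal consistency).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = bundle.index_table
    for s in bundle.per_species:
        want = summarize_species(s.index_table)
        got = bundle.species_means.set_index("species").loc[s.species]
        if not np.allclose(want.values.astype(float), got[want.index].values.astype(float), equal_nan=True):
            raise AssertionError(f"species-mean consistency violated for {s.species}")
    _round2(idx).to_csv(out / "gene_indices.tsv", sep="\t", index=False)
    idx.to_csv(out / "gene_indices_full.tsv", sep="\t", index=False)
    _round2(bundle.species_means).to_csv(out / "species_means.tsv", sep="\t", index=False)
    pd.concat([s.rscu_long for s in bundle.per_species]).to_csv(
        out / "rscu_long.tsv", sep="\t", index=False, float_format="%.4f"
    )
    neut_rows = []
    for s in bundle.per_species:
        if s.neutrality:
            f = s.neutrality
            neut_rows.append(
                dict(species=s.species, slope=f.slope, intercept=f.intercept,
                     r_squared=f.r_squared, pearson_r=f.pearson_r, p_value=f.p_value)
            )
        if s.enc_plot:
            pd.DataFrame(
                [dict(species=s.species, gene=r.gene, gc3s=r.gc3s, enc_obs=r.enc_obs,
                      enc_exp=r.enc_exp, enc_ratio_pct=100 * r.enc_ratio) for r in s.enc_plot]
            ).to_csv(out / f"enc_plot_{s.species}.tsv", sep="\t", index=False, float_format="%.4f")
        if s.pr2:
            pd.DataFrame(
                [dict(species=s.species, gene=r.gene, x_g3=r.x, y_a3=r.y, ok=r.ok) for r in s.pr2]
            ).to_csv(out / f"pr2_{s.species}.tsv", sep="\t", index=False, float_format="%.4f")
        if s.correlations is not None:
            s.correlations.to_csv(out / f"correlations_{s.species}.tsv", sep="\t", index=False, float_format="%.4g")
        if s.coa_result is not None:
            s.coa_result.row_coords.to_csv(out / f"coa_genes_{s.species}.tsv", sep="\t", float_format="%.6g")
            pd.DataFrame(
                {"inertia": s.coa_result.inertias, "contribution_pct": s.coa_result.contribution_pct}
            ).to_csv(out / f"coa_inertia_{s.species}.tsv", sep="\t", index=False, float_format="%.6g")
        if s.optimal_report is not None:
            s.optimal_report.as_frame().to_csv(
                out / f"optimal_codons_{s.species}.tsv", sep="\t", index=False, float_format="%.4f"
            )
    if neut_rows:
        pd.DataFrame(neut_rows).to_csv(out / "neutrality.tsv", sep="\t", index=False, float_format="%.4f")
    if bundle.species_rscu_matrix is not None:
        bundle.species_rscu_matrix.to_csv(out / "species_rscu_matrix.tsv", sep="\t", float_format="%.4f")
    if bundle.tree is not None:
        (out / "species_tree.nwk").write_text(bundle.tree.newick + "\n")
    if cfg is not None:
        (out / "analysis_config.txt").write_text(cfg.serialize())
    return out
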