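"""A designed end-to-end "mini-study" fixture.

A fully synthetic miniature of the study design: one methylome
comparison (treated vs control) with planted DMRs whose nearest genes
are chosen by construction, plus a 2-exposure-group × 2-timepoint
expression experiment with planted DEGs, wired so that the DEG /
DMR-linked-gene intersection table has a designed, hand-computable
expected value.  The whole pipeline — simulate → call DMRs → annotate
→ call DEGs → enrich → intersect — is deterministic given the seed,
which makes this fixture the package's strongest end-to-end test:
the produced intersection table must equal the designed one exactly,
and two runs with one seed must be byte-identical on disk.

Design (12 planted DMRs, each containing the TSS of its designed gene
LG01..LG12 so the nearest-TSS link is unambiguous at distance 0):

* LG01..LG06 overlap an enhancer (regulatory-restricted links);
  LG07..LG12 do not.
* LG11 has a "Gm…" symbol and LG12 a pseudogene biotype, so both are
  removed by the identifier exclusion rules.
* The expression panel holds 300 genes (LG01..LG12, B01..B50 and
  filler); each treatment cell has designed planted DEGs drawn from
  the LG and B genes.
* Two pathways P1/P2 are loaded with DEGs (enriched by construction),
  P3 is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import expression as expr
from . import integration as integ
from . import methylome as meth
from .simulate import MethylSimConfig, simulate_methylome

__all__ = ["MiniStudyResult", "designed_intersection_table", "run_mini_study"]

_LG = [f"LG{i:02d}" for i in range(1, 13)]
_B = [f"B{i:02d}" for i in range(1, 51)]
_N_PANEL = 300

#: planted DEG design per treatment cell (group, timepoint)
_DEG_DESIGN: dict[str, list[str]] = {
    "direct_t1": ["LG01", "LG02", "LG07"] + _B[0:20],
    "direct_t2": ["LG01", "LG03", "LG08", "LG11"] + _B[9:29],
    "stop_t1": ["LG04", "LG09"] + _B[29:44],
    "stop_t2": ["LG05", "LG06", "LG10"] + _B[39:49],
}

_PATHWAYS: dict[str, list[str]] = {
    "P1": ["LG01", "LG03", "LG04", "LG06"] + _B[0:15],
    "P2": ["LG05", "LG07", "LG09"] + _B[29:39],
    "P3": [],  # filled with filler genes at build time; never enriched
}

_TSS_LINKED = [f"LG{i:02d}" for i in range(1, 11)]  # LG11/LG12 excluded
_REG_LINKED = [f"LG{i:02d}" for i in range(1, 7)]


@dataclass
class MiniStudyResult:
    dmrs: pd.DataFrame
    links_tss: pd.DataFrame
    links_reg: pd.DataFrame
    deg_tables: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    intersection_table: pd.DataFrame
    designed_table: pd.DataFrame
    tss_table: pd.DataFrame
    features: pd.DataFrame


def designed_intersection_table() -> pd.DataFrame:
    """The hand-computable expected table, from the design sets alone.

    Assumes perfect recovery and that exactly P1 and P2 come out
    enriched — both guaranteed by the fixture's effect sizes.
    """
    pathway_genes = set(_PATHWAYS["P1"]) | set(_PATHWAYS["P2"])
    return integ.build_intersection_table(
        {cell: set(genes) for cell, genes in _DEG_DESIGN.items()},
        _TSS_LINKED, _REG_LINKED, pathway_genes,
    )


def _methylome_arm(seed: int):
    config = MethylSimConfig(
        n_chroms=2, chrom_length=2_000_000, n_cpgs=4000, island_fraction=0.35,
        sample_concentration=150.0, coverage_mean=50.0, coverage_dispersion=8.0,
        n_treat=5, n_control=5, n_dmrs_planted=12, dmr_width_cpgs=6,
        dmr_delta=40.0, dmr_direction_mix=0.5, seed=seed,
    )
    matrix, truth = simulate_methylome(config)
    return matrix, truth.planted_dmrs


def _annotation_arm(planted: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSS table and features built around the planted DMRs."""
    tss_rows = []
    for i, rec in enumerate(planted.itertuples()):
        gene = _LG[i]
        symbol, biotype = gene, "protein_coding"
        if gene == "LG11":
            symbol = "Gm90011"
        elif gene == "LG12":
            biotype = "processed_pseudogene"
        tss_rows.append({
            "gene_id": gene, "gene_symbol": symbol, "chrom": rec.chrom,
            "tss": int((rec.start + rec.end) // 2), "strand": "+",
            "biotype": biotype,
        })
    # background genes on a coarse grid, kept >5 kb away from any DMR
    grid = [(c, p) for c in ("chr1", "chr2")
            for p in range(60_000, 2_000_000, 90_000)]
    bg = []
    for chrom, pos in grid:
        near = planted[(planted["chrom"] == chrom)
                       & (planted["start"] - 5000 < pos)
                       & (planted["end"] + 5000 > pos)]
        if near.empty:
            bg.append((chrom, pos))
    for j, (chrom, pos) in enumerate(bg[: len(_B)]):
        tss_rows.append({
            "gene_id": _B[j], "gene_symbol": _B[j], "chrom": chrom,
            "tss": pos, "strand": "+", "biotype": "protein_coding",
        })
    tss = pd.DataFrame(tss_rows).sort_values(
        ["chrom", "tss"], kind="mergesort").reset_index(drop=True)

    feat_rows = []
    for i, rec in enumerate(planted.itertuples()):
        if _LG[i] in _REG_LINKED:
            feat_rows.append({
                "chrom": rec.chrom, "start": int(rec.start) - 201,
                "end": int(rec.end) + 200, "feature_class": "enhancer",
                "source_label": "designed",
            })
    # decoy enhancers far from everything that matters
    for chrom in ("chr1", "chr2"):
        feat_rows.append({"chrom": chrom, "start": 1_990_000, "end": 1_991_000,
                          "feature_class": "enhancer", "source_label": "decoy"})
    features = pd.DataFrame(feat_rows).sort_values(
        ["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return tss, features


def _expression_arm(seed: int):
    """Panel counts for 4 treatment cells + 2 control cells (n=6 each)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
    filler = [f"F{i:03d}" for i in range(1, _N_PANEL - len(_LG) - len(_B) + 1)]
    genes = _LG + _B + filler
    cells = [("direct", "t1"), ("direct", "t2"), ("stop", "t1"),
             ("stop", "t2"), ("control", "t1"), ("control", "t2")]
    n_per_cell = 6
    samples, info_rows = [], []
    for group, tp in cells:
        for k in range(n_per_cell):
            sid = f"{group}_{tp}_{k + 1}"
            samples.append(sid)
            info_rows.append({"sample": sid, "group": group, "timepoint": tp})
    sample_info = pd.DataFrame(info_rows).set_index("sample")

    mu = np.exp(rng.uniform(np.log(200.0), np.log(20000.0), size=len(genes)))
    sf = np.exp(rng.uniform(np.log(0.8), np.log(1.25), size=len(samples)))
    l2fc = np.zeros((len(genes), len(samples)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    signs = {}
    for cell, deg_genes in _DEG_DESIGN.items():
        group, tp = cell.split("_")
        cols = [j for j, s in enumerate(samples)
                if sample_info.loc[s, "group"] == group
                and sample_info.loc[s, "timepoint"] == tp]
        for g in deg_genes:
            sgn = signs.setdefault(g, 1.0 if rng.random() < 0.5 else -1.0)
            l2fc[gene_idx[g], cols] = sgn * 3.0
    mean = mu[:, None] * (2.0 ** l2fc) * sf[None, :]
    disp = 0.005
    size = 1.0 / disp
    counts = rng.negative_binomial(size, size / (size + mean))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    probe_map = pd.Series(genes, index=genes, name="gene_id")
    return counts_df, probe_map, sample_info


def run_mini_study(seed: int, outdir: str | Path | None = None) -> MiniStudyResult:
    """Run the full pipeline on the designed fixture.

    When ``outdir`` is given, writes the DMR table, link tables, DEG
    tables, enrichment tables and the intersection table as TSVs
    (used for byte-identity checks across runs).
    """
    matrix, planted = _methylome_arm(seed)
    dmr_cfg = meth.DmrConfig()
    dmrs = meth.call_dmrs(matrix, cfg=dmr_cfg)

    tss, features = _annotation_arm(planted)
    links = ann.link_nearest_tss(dmrs, tss)
    links_tss, _removed = ann.filter_gene_ids(links, tss)
    links_reg = ann.restrict_to_regulatory(links_tss, features)

    counts_df, probe_map, sample_info = _expression_arm(seed)
    cm = expr.read_counts(counts_df, probe_map, sample_info)
    expr.sample_rank_qc(cm)
    expr.enforce_min_group_n(cm)
    expr.median_ratio_normalize(cm)
    cm_f = expr.filter_low_expression(cm)

    deg_tables: dict[str, pd.DataFrame] = {}
    for cell in _DEG_DESIGN:
        group, tp = cell.split("_")
        treat_ids = [s for s in cm_f.samples
                     if cm_f.sample_info.loc[s, "group"] == group
                     and cm_f.sample_info.loc[s, "timepoint"] == tp]
        control_ids = [s for s in cm_f.samples
                       if cm_f.sample_info.loc[s, "group"] == "control"
                       and cm_f.sample_info.loc[s, "timepoint"] == tp]
        deg_tables[cell] = expr.test_differential_expression(
            cm_f, treat_ids, control_ids)

    universe = frozenset(cm_f.counts.index)
    filler = sorted(universe - set(_LG) - set(_B))
    pathways = {name: list(members) for name, members in _PATHWAYS.items()}
    pathways["P3"] = filler[:20]
    collection = integ.GeneSetCollection(
        {n: frozenset(m) for n, m in pathways.items()}, universe)

    enrichment: dict[str, pd.DataFrame] = {}
    pathway_genes: set[str] = set()
    for cell, table in deg_tables.items():
        query = set(table.index[table["significant"]])
        res = integ.fisher_enrichment(query, collection)
        enrichment[cell] = res
        pathway_genes |= integ.pathway_member_genes(res, collection)

    table = integ.build_intersection_table(
        {cell: set(t.index[t["significant"]]) for cell, t in deg_tables.items()},
        set(links_tss["gene_id"]), set(links_reg["gene_id"]), pathway_genes,
    )

    result = MiniStudyResult(
        dmrs=dmrs, links_tss=links_tss, links_reg=links_reg,
        deg_tables=deg_tables, enrichment=enrichment,
        intersection_table=table, designed_table=designed_intersection_table(),
        tss_table=tss, features=features,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dmrs.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        links_tss.to_csv(outdir / "links_tss.tsv", sep="\t", index=False)
        links_reg.to_csv(outdir / "links_reg.tsv", sep="\t", index=False)
        for cell, t in deg_tables.items():
            t.to_csv(outdir / f"degs_{cell}.tsv", sep="\t")
        for cell, t in enrichment.items():
            t.to_csv(outdir / f"enrichment_{cell}.tsv", sep="\t", index=False)
        table.to_csv(outdir / "intersection_table.tsv", sep="\t")
    return result
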