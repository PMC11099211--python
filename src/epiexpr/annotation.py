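"""DMR annotation: feature intersection, nearest-TSS gene linking,
and gene-identifier exclusion rules.

Feature intervals are 0-based half-open (BED); DMR spans are 1-based
inclusive and converted internally.  Every DMR is linked to exactly
one gene — the one whose TSS is nearest to the DMR interval (distance
0 when the TSS falls inside the span), with ties broken by
lexicographically smallest gene id.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "FEATURE_CLASSES",
    "REGULATORY_CLASSES",
    "read_features",
    "read_tss_table",
    "intersect_features",
    "nearest_tss",
    "link_nearest_tss",
    "filter_gene_ids",
    "restrict_to_regulatory",
]

FEATURE_CLASSES = frozenset({
    "promoter", "enhancer", "CTCF_site", "TF_binding", "open_chromatin",
    "CpG_island", "CpG_shore", "CpG_shelf",
})
#: classes counted as predicted gene-regulatory regions (CpG tracks are not)
REGULATORY_CLASSES = frozenset({
    "promoter", "enhancer", "CTCF_site", "TF_binding", "open_chromatin",
})


def read_features(
    bed_paths: Mapping[str, str | Path] | Sequence[str | Path],
    class_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read BED6 feature files into a validated, sorted feature table.

    ``bed_paths`` maps a feature class to its BED file (or is a list
    of paths whose class comes from ``class_map`` keyed by file stem).
    Returns columns (chrom, start, end, feature_class, source_label)
    with 0-based half-open coordinates.
    """
    if not isinstance(bed_paths, Mapping):
        if class_map is None:
            raise ValueError("class_map required when bed_paths is a list")
        bed_paths = {class_map[Path(p).stem]: p for p in bed_paths}
    frames = []
    for cls, path in bed_paths.items():
        if cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {cls!r}")
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             dtype={0: str})
        except pd.errors.EmptyDataError:
            continue
        if df.empty:
            continue
        df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
        df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
        bad = df["start"] >= df["end"]
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}, line {line}: start >= end")
        frames.append(pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "feature_class": cls,
            "source_label": df["name"] if "name" in df else cls,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "feature_class",
                                     "source_label"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start", "end"],
                           kind="mergesort").reset_index(drop=True)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS TSV (gene_id[, gene_symbol], chrom, tss, strand, biotype).

    A missing gene_symbol column is filled from gene_id.  Gene ids
    must be unique; tss is 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss", "strand", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = df["gene_id"]
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id entries")
    if (df["tss"] < 1).any():
        raise ValueError(f"{path}: tss positions must be >= 1")
    return df.reset_index(drop=True)


def _feature_trees(features: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for rec in features.itertuples():
        key = (rec.chrom, rec.feature_class)
        trees.setdefault(key, IntervalTree()).addi(int(rec.start), int(rec.end))
    return trees


def _dmr_hits_class(dmrs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Boolean DMR × feature-class hit matrix (overlap >= 1 bp)."""
    trees = _feature_trees(features)
    classes = sorted(features["feature_class"].unique())
    hits = pd.DataFrame(False, index=dmrs.index, columns=classes)
    for i, rec in zip(dmrs.index, dmrs.itertuples()):
        s0, e0 = int(rec.start) - 1, int(rec.end)  # 1-based incl -> 0-based half-open
        for cls in classes:
            tree = trees.get((rec.chrom, cls))
            if tree is not None and tree.overlap(s0, e0):
                hits.at[i, cls] = True
    return hits


def intersect_features(dmrs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Per-class DMR hit counts and percentages, split by direction.

    A DMR hits a class when it overlaps any feature of the class by at
    least 1 bp (a DMR overlapping several features of one class counts
    once); classes are non-exclusive.  Percentages are per-direction
    counts over the total DMRs of that direction.
    """
    hits = _dmr_hits_class(dmrs, features)
    rows = []
    for direction in ("hyper", "hypo"):
        sel = dmrs["direction"] == direction
        n_dir = int(sel.sum())
        for cls in hits.columns:
            count = int(hits.loc[sel.values, cls].sum()) if n_dir else 0
            rows.append({
                "direction": direction,
                "feature_class": cls,
                "count": count,
                "total": n_dir,
                "percent": 100.0 * count / n_dir if n_dir else float("nan"),
            })
    return pd.DataFrame(rows)


def nearest_tss(dmr, tss_table: pd.DataFrame) -> dict:
    """Link one DMR (mapping with chrom/start/end) to its nearest TSS.

    Distance is 0 when a TSS lies within the 1-based inclusive span,
    else the gap to the nearest DMR edge; ties go to the
    lexicographically smallest gene_id.  With no TSS on the DMR's
    chromosome the link is missing (gene_id None, infinite distance).
    """
    chrom = dmr["chrom"]
    start, end = int(dmr["start"]), int(dmr["end"])
    sub = tss_table[tss_table["chrom"] == chrom]
    if sub.empty:
        return {"chrom": chrom, "start": start, "end": end,
                "gene_id": None, "distance": float("inf"), "missing": True}
    tss = sub["tss"].to_numpy()
    dist = np.maximum.reduce([start - tss, tss - end, np.zeros_like(tss)])
    dmin = dist.min()
    candidates = sub.loc[dist == dmin, "gene_id"]
    return {"chrom": chrom, "start": start, "end": end,
            "gene_id": str(candidates.min()), "distance": int(dmin),
            "missing": False}


def link_nearest_tss(dmrs: pd.DataFrame, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS link for every DMR (one gene per DMR).

    Returns one row per DMR: (dmr_index, chrom, start, end, gene_id,
    distance, missing, in_regulatory_region=False placeholder).
    """
    rows = []
    for i, rec in zip(dmrs.index, dmrs.itertuples()):
        link = nearest_tss(
            {"chrom": rec.chrom, "start": rec.start, "end": rec.end}, tss_table)
        link["dmr_index"] = i
        rows.append(link)
    out = pd.DataFrame(rows, columns=["dmr_index", "chrom", "start", "end",
                                      "gene_id", "distance", "missing"])
    out["in_regulatory_region"] = False
    return out


_RIK_RE = re.compile(r"rik$", re.IGNORECASE)
_GM_RE = re.compile(r"^gm\d+", re.IGNORECASE)


def filter_gene_ids(
    links: pd.DataFrame,
    tss_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop links to Riken clones, Gm-predicted genes and pseudogenes.

    Symbols ending in "Rik", symbols of the form "Gm<digits>", and
    biotypes containing "pseudogene" are removed (case-insensitive).
    Symbol/biotype come from ``tss_table`` when given, else from the
    link table's own columns, else gene_id stands in for the symbol.
    Returns (kept_links, removal_log).
    """
    df = links.copy()
    if tss_table is not None:
        meta = tss_table.set_index("gene_id")[["gene_symbol", "biotype"]]
        df = df.join(meta, on="gene_id")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = df["gene_id"]
    if "biotype" not in df.columns:
        df["biotype"] = ""
    sym = df["gene_symbol"].fillna("").astype(str)
    bio = df["biotype"].fillna("").astype(str)
    is_rik = sym.str.contains(_RIK_RE)
    is_gm = sym.str.contains(_GM_RE)
    is_pseudo = bio.str.lower().str.contains("pseudogene")
    drop = is_rik | is_gm | is_pseudo | df["gene_id"].isna()
    reason = np.select(
        [df["gene_id"].isna(), is_rik, is_gm, is_pseudo],
        ["unlinked", "riken", "gm_predicted", "pseudogene"], default="",
    )
    log = df.loc[drop, ["gene_id", "gene_symbol", "biotype"]].copy()
    log["reason"] = reason[drop.to_numpy()]
    kept = links.loc[~drop.to_numpy()].reset_index(drop=True)
    return kept, log.reset_index(drop=True)


def restrict_to_regulatory(
    links: pd.DataFrame,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Keep links whose DMR overlaps a predicted regulatory feature.

    Only regulatory classes count (CpG island/shore/shelf tracks do
    not); overlap threshold is 1 bp.  Sets ``in_regulatory_region``
    on the surviving links.
    """
    reg = features[features["feature_class"].isin(REGULATORY_CLASSES)]
    trees: dict[str, IntervalTree] = {}
    for rec in reg.itertuples():
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            int(rec.start), int(rec.end))
    keep = []
    for rec in links.itertuples():
        tree = trees.get(rec.chrom)
        s0, e0 = int(rec.start) - 1, int(rec.end)
        keep.append(tree is not None and bool(tree.overlap(s0, e0)))
    out = links.loc[keep].copy()
    out["in_regulatory_region"] = True
    return out.reset_index(drop=True)
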