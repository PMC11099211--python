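"""Cross-cutting analyses: DEG set intersections, direction
concordance, DEG × DMR-linked-gene tables, and Fisher-exact gene-set
over-representation.

Enrichment follows the one-sided hypergeometric (Fisher exact)
over-representation convention with significance at
-log10(p) > 1.3 (p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "disjoint_intersections",
    "directional_concordance",
    "fisher_enrichment",
    "pathway_member_genes",
    "build_intersection_table",
    "NEG_LOG10_P_THRESHOLD",
]

NEG_LOG10_P_THRESHOLD = 1.3


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of gene ids."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(s) for name, s in self.sets.items()}
        self.universe = frozenset(self.universe)
        if not self.universe:
            raise ValueError("empty gene universe")
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe, "
                    f"e.g. {sorted(extra)[:3]}"
                )


def read_gmt(path: str | Path, universe: Iterable[str] | None = None
             ) -> GeneSetCollection:
    """Read GMT-like TSV: set_name <TAB> description <TAB> gene1 <TAB> …

    With no explicit universe, the union of all set members is used.
    """
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, genes")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r}")
        sets[name] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, "na", *sorted(members)])
        for name, members in collection.sets.items()
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def disjoint_intersections(
    named_sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty membership pattern of 2–8 named sets.

    Keys are sorted tuples of the set names an element belongs to
    (the disjoint regions of an UpSet plot); the counts sum to the
    size of the union.
    """
    if not isinstance(named_sets, Mapping):
        names = [n for n, _ in named_sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate set names")
        named_sets = dict(named_sets)
    sets = {name: set(v) for name, v in named_sets.items()}
    if not 2 <= len(sets) <= 8:
        raise ValueError("disjoint_intersections needs 2-8 sets")
    regions: dict[tuple[str, ...], int] = {}
    union = set().union(*sets.values())
    for g in union:
        key = tuple(sorted(name for name, s in sets.items() if g in s))
        regions[key] = regions.get(key, 0) + 1
    return regions


def directional_concordance(
    degs_a: pd.DataFrame,
    degs_b: pd.DataFrame,
) -> tuple[int, float]:
    """Shared significant genes and the fraction with the same sign.

    Both inputs are DEG tables (indexed by gene_id, with
    ``log2_fold_change`` and ``significant``).  Returns
    (n_shared, fraction_same_sign); the fraction is NaN when no gene
    is significant in both.
    """
    sig_a = degs_a[degs_a["significant"]]
    sig_b = degs_b[degs_b["significant"]]
    shared = sig_a.index.intersection(sig_b.index)
    if len(shared) == 0:
        return 0, float("nan")
    same = (np.sign(sig_a.loc[shared, "log2_fold_change"])
            == np.sign(sig_b.loc[shared, "log2_fold_change"]))
    return int(len(shared)), float(same.mean())


def fisher_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    threshold: float = NEG_LOG10_P_THRESHOLD,
) -> pd.DataFrame:
    """One-sided over-representation test of a query against each set.

    p is the hypergeometric upper tail P(X >= overlap) drawing
    ``|query|`` genes from the universe with ``|set|`` successes
    (equivalent to the one-sided Fisher exact test on the 2×2 table).
    Query genes outside the universe are dropped with a warning.
    Results are sorted by p; ``significant`` is
    ``-log10(p) > threshold``.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        import warnings

        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query &= collection.universe
    M = len(collection.universe)
    nq = len(query)
    rows = []
    for name, members in collection.sets.items():
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), nq))
        p = min(max(p, 5e-324), 1.0)
        nlp = -np.log10(p)
        rows.append({
            "set_name": name,
            "overlap": k,
            "query_size": nq,
            "set_size": len(members),
            "universe_size": M,
            "p_value": p,
            "neg_log10_p": nlp,
            "significant": bool(nlp > threshold),
        })
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "query_size",
                                      "set_size", "universe_size", "p_value",
                                      "neg_log10_p", "significant"])
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def pathway_member_genes(
    enrichment: pd.DataFrame,
    collection: GeneSetCollection,
    significant_only: bool = True,
) -> frozenset[str]:
    """Genes belonging to at least one (significant) enriched set."""
    if significant_only:
        names = enrichment.loc[enrichment["significant"], "set_name"]
    else:
        names = enrichment["set_name"]
    members: set[str] = set()
    for name in names:
        members |= collection.sets[name]
    return frozenset(members)


def build_intersection_table(
    deg_lists: Mapping[str, Iterable[str]],
    dmr_links_tss: Iterable[str],
    dmr_links_tss_reg: Iterable[str],
    pathway_genes: Iterable[str],
) -> pd.DataFrame:
    """Per-group DEG / DMR-linked-gene intersection counts.

    For each group: the DEG count, the intersection with TSS-linked
    DMR genes, the subset of that intersection belonging to enriched
    pathways, and the same two counts against the
    regulatory-restricted link set.  Pathway-restricted counts are
    never larger than their parents, and the regulatory-restricted
    links are a subset of the TSS links.
    """
    tss_genes = set(dmr_links_tss)
    reg_genes = set(dmr_links_tss_reg)
    pw = set(pathway_genes)
    rows = []
    for group, degs in deg_lists.items():
        degs = set(degs)
        tss_hit = degs & tss_genes
        reg_hit = degs & reg_genes
        rows.append({
            "group": group,
            "n_degs": len(degs),
            "n_deg_dmr_tss": len(tss_hit),
            "n_deg_dmr_tss_in_pathways": len(tss_hit & pw),
            "n_deg_dmr_tss_reg": len(reg_hit),
            "n_deg_dmr_tss_reg_in_pathways": len(reg_hit & pw),
        })
    return pd.DataFrame(rows).set_index("group")
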