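"""Synthetic study inputs with known planted truth.

Three generators emulate the inputs of a stop-exposure liver study:

* :func:`simulate_methylome` — RRBS-like CpG methylation call
  matrices.  Covered CpGs arrive in dense fragment-like clusters (the
  enzymatic enrichment of RRBS covers CpG-dense fragments); each
  fragment is island-like (low methylation) or open (high
  methylation); per-sample methylation propensities are Beta-
  distributed around the locus baseline (beta-binomial
  overdispersion) and read depth is negative-binomial.  Hyper- and
  hypomethylated DMRs can be planted as additive shifts of the
  treated-group propensity.
* :func:`simulate_annotation` — regulatory features, CpG
  island/shore/shelf tracks consistent with the methylome's island
  layout, and a TSS table including excludable identifiers (Riken
  "…Rik" suffixes, "Gm###" predictions, pseudogenes).
* :func:`simulate_counts` — negative-binomial probe-level counts for
  a targeted expression panel, with planted fold changes and
  "FFPE-like" degraded samples whose gene ranking is partially
  scrambled.

All generators are deterministic given their config (which carries
the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome import MethylationMatrix, write_cpg_calls

__all__ = [
    "MethylSimConfig",
    "ExprSimConfig",
    "TruthSet",
    "simulate_methylome",
    "simulate_annotation",
    "simulate_counts",
    "write_fixtures",
]


@dataclass(frozen=True)
class MethylSimConfig:
    """Configuration of the RRBS-like methylome generator.

    The defaults mirror the study arm the package targets: two groups
    of five biological replicates at ~30x mean CpG depth, with CpGs in
    fragment clusters of which a third are island-like.  Beta
    parameters are (alpha, beta) pairs; their sum is the concentration
    of locus baselines around the class mean.  ``sample_concentration``
    governs between-replicate variability of the per-sample
    methylation propensity (higher = tighter replicates).
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_cpgs: int = 20_000
    island_fraction: float = 0.3
    baseline_beta_params_island: tuple[float, float] = (5.0, 45.0)
    baseline_beta_params_open: tuple[float, float] = (40.0, 10.0)
    sample_concentration: float = 50.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    n_treat: int = 5
    n_control: int = 5
    n_dmrs_planted: int = 0
    dmr_width_cpgs: int = 5
    dmr_delta: float = 30.0
    dmr_direction_mix: float = 0.5
    lambda_n_sites: int = 200
    lambda_failure_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("island_fraction", "dmr_direction_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.dmr_width_cpgs < 3:
            raise ValueError("dmr_width_cpgs must be >= 3")
        if self.n_dmrs_planted > 0 and not 0.0 < self.dmr_delta <= 100.0:
            raise ValueError("dmr_delta must lie in (0, 100]")
        if self.n_chroms < 1 or self.n_cpgs < 1:
            raise ValueError("n_chroms and n_cpgs must be positive")


@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration of the targeted-panel count generator.

    Defaults emulate a liver-centric surrogate panel (3044 probes over
    2755 genes) with six animals per group; ``dispersion_trend``
    (a0, a1) sets gene dispersion a0 + a1/mean; degraded samples have
    ``degradation_rank_noise`` of their probe values scrambled, which
    is the property the downstream rank QC measures.
    """

    n_probes: int = 3044
    n_genes: int = 2755
    n_per_group: int = 6
    mean_log_expression_range: tuple[float, float] = (1.0, 7.5)
    dispersion_trend: tuple[float, float] = (0.05, 2.0)
    n_deg_planted: int = 100
    planted_log2fc: float = 2.0
    n_degraded_samples: int = 2
    degradation_rank_noise: float = 0.6
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    size_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes > self.n_probes:
            raise ValueError("n_genes must be <= n_probes")
        if self.n_deg_planted > 0 and (
            not np.isfinite(self.planted_log2fc) or self.planted_log2fc == 0
        ):
            raise ValueError("planted_log2fc must be finite and nonzero")
        if self.n_degraded_samples >= 2 * self.n_per_group:
            raise ValueError("n_degraded_samples must be < total samples")
        if not 0.0 <= self.degradation_rank_noise <= 1.0:
            raise ValueError("degradation_rank_noise must lie in [0, 1]")
        if self.n_deg_planted > self.n_genes:
            raise ValueError("n_deg_planted must be <= n_genes")


@dataclass
class TruthSet:
    """Planted ground truth of a simulation.

    ``planted_dmrs``: DataFrame (chrom, start, end, n_cpgs, direction,
    delta) with 1-based inclusive CpG spans.  ``planted_degs``:
    DataFrame (gene_id, log2fc).  ``degraded_sample_ids``: list.
    """

    planted_dmrs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "n_cpgs", "direction", "delta"]))
    planted_degs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "log2fc"]))
    degraded_sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Fragment layout (shared by the methylome and annotation generators)
# ---------------------------------------------------------------------------

def _fragment_layout(config: MethylSimConfig) -> pd.DataFrame:
    """Deterministic fragment layout: one row per CpG.

    Columns: chrom, pos (1-based), fragment_id, is_island.  The layout
    depends only on (config minus sample-level fields), so the
    annotation generator reproduces it exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    per_chrom = [config.n_cpgs // config.n_chroms] * config.n_chroms
    per_chrom[0] += config.n_cpgs - sum(per_chrom)
    rows = []
    frag_id = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        placed = 0
        pos = 1
        while placed < per_chrom[ci]:
            pos += int(rng.integers(400, 3000))  # inter-fragment gap
            k = min(3 + int(rng.poisson(5.0)), per_chrom[ci] - placed)
            is_island = bool(rng.random() < config.island_fraction)
            spacing = rng.integers(15, 80, size=k)
            for s in spacing:
                pos += int(s)
                if pos > config.chrom_length:
                    raise ValueError(
                        "chrom_length too small for n_cpgs at the simulated "
                        "fragment density"
                    )
                rows.append((chrom, pos, frag_id, is_island))
            placed += k
            frag_id += 1
    return pd.DataFrame(rows, columns=["chrom", "pos", "fragment_id", "is_island"])


def _place_dmrs(layout: pd.DataFrame, config: MethylSimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Choose non-overlapping planted DMRs on fragments.

    Hypermethylated DMRs go on island-like (low-baseline) fragments and
    hypomethylated ones on open (high-baseline) fragments, so the
    additive shift stays inside [0, 1].
    """
    n = config.n_dmrs_planted
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs",
                                     "direction", "delta", "member_rows"])
    n_hyper = int(round(n * config.dmr_direction_mix))
    sizes = layout.groupby("fragment_id").size()
    eligible = sizes[sizes >= config.dmr_width_cpgs].index.to_numpy()
    frag_island = layout.groupby("fragment_id")["is_island"].first()
    isl = np.array([f for f in eligible if frag_island[f]])
    opn = np.array([f for f in eligible if not frag_island[f]])
    if len(isl) < n_hyper or len(opn) < n - n_hyper:
        raise ValueError(
            "planted DMRs cannot be placed without overlap: not enough "
            f"eligible fragments of width >= {config.dmr_width_cpgs} CpGs "
            f"(need {n_hyper} island-like and {n - n_hyper} open)"
        )
    chosen_hyper = rng.choice(isl, size=n_hyper, replace=False)
    chosen_hypo = rng.choice(opn, size=n - n_hyper, replace=False)
    rows = []
    for frag, direction in [(f, "hyper") for f in chosen_hyper] + [
            (f, "hypo") for f in chosen_hypo]:
        mem = layout.index[layout["fragment_id"] == frag][: config.dmr_width_cpgs]
        sub = layout.loc[mem]
        rows.append({
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["pos"].min()),
            "end": int(sub["pos"].max()),
            "n_cpgs": len(mem),
            "direction": direction,
            "delta": config.dmr_delta,
            "member_rows": tuple(int(i) for i in mem),
        })
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return df


def simulate_methylome(config: MethylSimConfig) -> tuple[MethylationMatrix, TruthSet]:
    """Simulate a beta-binomial methylome with planted DMRs.

    Per CpG i: a locus baseline ``m_i`` is drawn from the island or
    open Beta prior of its fragment; per sample j the methylation
    propensity is ``p_ij ~ Beta`` with mean ``m_i`` (shifted by
    ±delta/100 for treated samples inside planted DMRs, clipped to
    [0.01, 0.99]) and concentration ``sample_concentration``; coverage
    is NB(mean, dispersion) and methylated reads are
    Binomial(coverage, p_ij).  An unmethylated spike-in (lambda) is
    simulated alongside with the stated conversion-failure rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    layout = _fragment_layout(config)
    dmrs = _place_dmrs(layout, config, rng)

    n_sites = len(layout)
    samples = ([f"treat_{i + 1}" for i in range(config.n_treat)]
               + [f"ctrl_{i + 1}" for i in range(config.n_control)])
    groups = pd.Series(
        ["treated"] * config.n_treat + ["control"] * config.n_control,
        index=samples,
    )

    a_isl, b_isl = config.baseline_beta_params_island
    a_opn, b_opn = config.baseline_beta_params_open
    is_island = layout["is_island"].to_numpy()
    baseline = np.where(
        is_island,
        rng.beta(a_isl, b_isl, size=n_sites),
        rng.beta(a_opn, b_opn, size=n_sites),
    )

    shift = np.zeros(n_sites)
    for rec in dmrs.itertuples():
        sgn = 1.0 if rec.direction == "hyper" else -1.0
        shift[list(rec.member_rows)] = sgn * rec.delta / 100.0

    n_samples = len(samples)
    treated_mask = (groups.values == "treated")
    mean = np.tile(baseline[:, None], (1, n_samples))
    mean[:, treated_mask] += shift[:, None]
    mean = np.clip(mean, 0.01, 0.99)

    c = config.sample_concentration
    p = rng.beta(mean * c, (1.0 - mean) * c)
    size = config.coverage_dispersion
    nb_p = size / (size + config.coverage_mean)
    coverage = rng.negative_binomial(size, nb_p, size=(n_sites, n_samples))
    meth = rng.binomial(coverage, p)

    idx = pd.MultiIndex.from_arrays(
        [layout["chrom"], layout["pos"].astype(int)], names=["chrom", "pos"]
    )
    meth_df = pd.DataFrame(meth, index=idx, columns=samples)
    total_df = pd.DataFrame(coverage, index=idx, columns=samples)

    lam_cov = rng.negative_binomial(
        size, nb_p, size=(config.lambda_n_sites, n_samples))
    lam_meth = rng.binomial(lam_cov, config.lambda_failure_rate)
    lam_idx = pd.MultiIndex.from_arrays(
        [np.repeat("lambda", config.lambda_n_sites),
         np.arange(1, config.lambda_n_sites + 1) * 50],
        names=["chrom", "pos"],
    )
    lambda_counts = (
        pd.DataFrame(lam_meth, index=lam_idx, columns=samples),
        pd.DataFrame(lam_cov, index=lam_idx, columns=samples),
    )

    matrix = MethylationMatrix(meth_df, total_df, groups, lambda_counts)
    truth = TruthSet(planted_dmrs=dmrs.drop(columns=["member_rows"]))
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------

_FEATURE_CLASSES = ("promoter", "enhancer", "CTCF_site",
                    "CpG_island", "CpG_shore", "CpG_shelf")

SHORE_BP = 2_000
SHELF_BP = 2_000  # shelves extend a further 2 kb beyond the shores


def _island_flanks(start: int, end: int) -> tuple[tuple[int, int], ...]:
    """Shores (±2 kb) and shelves (2–4 kb) flanking a 0-based island."""
    shores = ((max(0, start - SHORE_BP), start), (end, end + SHORE_BP))
    shelves = ((max(0, start - SHORE_BP - SHELF_BP), max(0, start - SHORE_BP)),
               (end + SHORE_BP, end + SHORE_BP + SHELF_BP))
    return shores + shelves


def simulate_annotation(
    config: MethylSimConfig,
    tss_density: float = 10.0,
    fraction_excludable: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate feature BED intervals and a TSS table.

    ``tss_density`` is genes per Mbp.  CpG islands are the island-like
    fragments of the methylome layout (so annotation and methylome
    agree); each island is flanked by ±2 kb shores and 2–4 kb shelves.
    ``fraction_excludable`` of genes get identifiers matching the
    standard exclusion patterns ("…Rik" suffix, "Gm###" prefix,
    pseudogene biotype), placed deterministically (exact count).

    Returns (features, tss): features have 0-based half-open
    (chrom, start, end, feature_class, source_label); the TSS table
    has (gene_id, gene_symbol, chrom, tss, strand, biotype) with a
    1-based tss.
    """
    if tss_density <= 0:
        raise ValueError("tss_density must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    layout = _fragment_layout(config)

    feats: list[tuple[str, int, int, str, str]] = []
    for (chrom, frag), sub in layout.groupby(["chrom", "fragment_id"], sort=True):
        if not sub["is_island"].iloc[0]:
            continue
        start0 = int(sub["pos"].min()) - 1     # 1-based CpG -> 0-based interval
        end0 = int(sub["pos"].max())
        feats.append((chrom, start0, end0, "CpG_island", "sim"))
        (sh1, sh2, shl1, shl2) = _island_flanks(start0, end0)
        for s, e in (sh1, sh2):
            if e > s:
                feats.append((chrom, s, e, "CpG_shore", "sim"))
        for s, e in (shl1, shl2):
            if e > s:
                feats.append((chrom, s, e, "CpG_shelf", "sim"))

    genome_mbp = config.n_chroms * config.chrom_length / 1e6
    n_genes = max(1, int(round(tss_density * genome_mbp)))
    chrom_of = rng.integers(0, config.n_chroms, size=n_genes)
    tss_pos = rng.integers(1, config.chrom_length + 1, size=n_genes)
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")

    n_excl = int(round(fraction_excludable * n_genes))
    excl_rows = rng.choice(n_genes, size=n_excl, replace=False)
    symbols = [f"Sim{i + 1:05d}" for i in range(n_genes)]
    biotypes = ["protein_coding"] * n_genes
    for j, row in enumerate(excl_rows):
        kind = j % 3
        if kind == 0:
            symbols[row] = f"{1700000 + row:07d}A{j % 24:02d}Rik"
        elif kind == 1:
            symbols[row] = f"Gm{10000 + row}"
        else:
            biotypes[row] = "processed_pseudogene"

    tss = pd.DataFrame({
        "gene_id": [f"SGENE{i + 1:05d}" for i in range(n_genes)],
        "gene_symbol": symbols,
        "chrom": [f"chr{c + 1}" for c in chrom_of],
        "tss": tss_pos,
        "strand": strand,
        "biotype": biotypes,
    }).sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)

    # promoters around each TSS (strand-aware: -1 kb .. +200 bp)
    for rec in tss.itertuples():
        t0 = rec.tss - 1
        if rec.strand == "+":
            s, e = max(0, t0 - 1000), t0 + 200
        else:
            s, e = max(0, t0 - 200), t0 + 1000
        feats.append((rec.chrom, s, e, "promoter", "sim"))

    # enhancers and CTCF sites scattered uniformly
    for cls, n_feat, width in (("enhancer", int(2 * genome_mbp), 800),
                               ("CTCF_site", int(4 * genome_mbp), 200)):
        chroms = rng.integers(0, config.n_chroms, size=n_feat)
        starts = rng.integers(0, config.chrom_length - width, size=n_feat)
        for c, s in zip(chroms, starts):
            feats.append((f"chr{c + 1}", int(s), int(s) + width, cls, "sim"))

    features = pd.DataFrame(
        feats, columns=["chrom", "start", "end", "feature_class", "source_label"]
    ).sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return features, tss


# ---------------------------------------------------------------------------
# Expression counts generator
# ---------------------------------------------------------------------------

def _degrade_inplace(values: np.ndarray, noise: float,
                     perm: np.ndarray) -> np.ndarray:
    """Scramble a fraction of a sample's probe values.

    ``perm`` is a fixed random ordering of probe indices; the first
    ``round(noise * n)`` positions of it are disrupted by rotating
    their values half-way, so a larger noise level disrupts a
    superset of the positions a smaller one does (rank QC then
    degrades monotonically in ``noise``).
    """
    n = len(values)
    k = int(round(noise * n))
    if k < 2:
        return values
    idx = perm[:k]
    values[idx] = np.roll(values[idx], k // 2)
    return values


def simulate_counts(config: ExprSimConfig):
    """Simulate NB probe counts with planted DEGs and degraded samples.

    Returns ``(counts, probe_map, sample_info, truth)``: a probe ×
    sample integer DataFrame, a probe→gene Series, a sample sheet with
    group labels, and the :class:`TruthSet`.  Treated-group means of
    planted DEG probes are scaled by ``2**planted_log2fc``; degraded
    samples (drawn from either group) have a fraction of their probe
    values scrambled after counting.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    n_probes, n_genes = config.n_probes, config.n_genes

    gene_ids = [f"EG{i + 1:05d}" for i in range(n_genes)]
    probe_gene = np.concatenate([
        np.arange(n_genes),
        rng.integers(0, n_genes, size=n_probes - n_genes),
    ])
    probe_ids = [f"P{i + 1:05d}" for i in range(n_probes)]
    probe_map = pd.Series([gene_ids[g] for g in probe_gene], index=probe_ids,
                          name="gene_id")

    lo, hi = config.mean_log_expression_range
    probe_mean = np.exp(rng.uniform(lo, hi, size=n_probes))
    a0, a1 = config.dispersion_trend
    dispersion = a0 + a1 / probe_mean

    deg_rows = rng.choice(n_genes, size=config.n_deg_planted, replace=False)
    sign = np.where(rng.random(config.n_deg_planted) < 0.5, 1.0, -1.0)
    gene_l2fc = np.zeros(n_genes)
    gene_l2fc[deg_rows] = sign * config.planted_log2fc
    probe_fc = 2.0 ** gene_l2fc[probe_gene]

    n = config.n_per_group
    samples = [f"T{i + 1}" for i in range(n)] + [f"C{i + 1}" for i in range(n)]
    group = ["treated"] * n + ["control"] * n
    if config.size_factors is not None:
        if len(config.size_factors) != 2 * n:
            raise ValueError("size_factors must have one entry per sample")
        sf = np.asarray(config.size_factors, dtype=float)
    else:
        sf = np.exp(rng.uniform(np.log(config.size_factor_range[0]),
                                np.log(config.size_factor_range[1]),
                                size=2 * n))

    mean = probe_mean[:, None] * sf[None, :]
    mean[:, :n] *= probe_fc[:, None]
    size = 1.0 / np.maximum(dispersion, 1e-8)
    nb_p = size[:, None] / (size[:, None] + mean)
    counts = rng.negative_binomial(size[:, None], nb_p)

    degraded = sorted(
        rng.choice(samples, size=config.n_degraded_samples, replace=False).tolist()
    )
    for s in degraded:
        j = samples.index(s)
        perm = rng.permutation(n_probes)
        counts[:, j] = _degrade_inplace(counts[:, j].copy(),
                                        config.degradation_rank_noise, perm)

    counts_df = pd.DataFrame(counts, index=probe_ids, columns=samples)
    sample_info = pd.DataFrame({"sample": samples, "group": group,
                                "timepoint": ["t1"] * 2 * n}).set_index("sample")
    truth = TruthSet(
        planted_degs=pd.DataFrame({
            "gene_id": [gene_ids[g] for g in deg_rows],
            "log2fc": sign * config.planted_log2fc,
        }),
        degraded_sample_ids=degraded,
    )
    truth.true_size_factors = pd.Series(sf, index=samples)  # extra diagnostics
    truth.gene_means = pd.Series(
        np.bincount(probe_gene, weights=probe_mean, minlength=n_genes),
        index=gene_ids,
    )
    return counts_df, probe_map, sample_info, truth


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixtures(
    outdir: str | Path,
    methylome: tuple[MethylationMatrix, TruthSet] | None = None,
    annotation: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    counts=None,
) -> pd.DataFrame:
    """Write simulated inputs to disk; returns a file manifest.

    Writes Bismark-coverage files (one per sample), per-class BED
    files, the TSS TSV, the counts CSV with probe-map and sample-sheet
    sidecars, and a truth JSON.  The manifest lists every file with
    its row count.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    manifest: list[tuple[str, int]] = []
    truth_blob: dict = {}

    if methylome is not None:
        matrix, truth = methylome
        cov_dir = outdir / "coverage"
        written = write_cpg_calls(matrix, cov_dir)
        for sample, path in written.items():
            n_rows = int((matrix.total[sample] > 0).sum())
            manifest.append((str(path.relative_to(outdir)), n_rows))
        groups_path = outdir / "groups.tsv"
        matrix.groups.rename("group").rename_axis("sample").to_csv(
            groups_path, sep="\t")
        manifest.append(("groups.tsv", len(matrix.groups)))
        truth_blob["planted_dmrs"] = truth.planted_dmrs.to_dict(orient="records")

    if annotation is not None:
        features, tss = annotation
        for cls, sub in features.groupby("feature_class"):
            path = outdir / f"features_{cls}.bed"
            bed = pd.DataFrame({
                "chrom": sub["chrom"], "start": sub["start"], "end": sub["end"],
                "name": cls, "score": 0, "strand": ".",
            })
            bed.to_csv(path, sep="\t", header=False, index=False)
            manifest.append((path.name, len(sub)))
        tss_path = outdir / "tss.tsv"
        tss.to_csv(tss_path, sep="\t", index=False)
        manifest.append(("tss.tsv", len(tss)))

    if counts is not None:
        counts_df, probe_map, sample_info, truth = counts
        counts_path = outdir / "counts.csv"
        counts_df.rename_axis("probe_id").to_csv(counts_path)
        manifest.append(("counts.csv", len(counts_df)))
        pm_path = outdir / "probe_map.tsv"
        probe_map.rename_axis("probe_id").to_csv(pm_path, sep="\t")
        manifest.append(("probe_map.tsv", len(probe_map)))
        ss_path = outdir / "samples.tsv"
        sample_info.to_csv(ss_path, sep="\t")
        manifest.append(("samples.tsv", len(sample_info)))
        truth_blob["planted_degs"] = truth.planted_degs.to_dict(orient="records")
        truth_blob["degraded_sample_ids"] = list(truth.degraded_sample_ids)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth_blob, indent=2, default=str))
    manifest.append(("truth.json", len(truth_blob)))

    return pd.DataFrame(manifest, columns=["path", "rows"])
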