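"""RRBS differentially-methylated-region (DMR) calling.

The caller consumes per-sample CpG methylation call tables (Bismark
coverage dialect), applies coverage and SNP-blacklist filters, screens
CpGs for a between-group methylation difference, clusters differential
CpGs into candidate regions, summarises each region by its
coverage-weighted methylation level (sum of methylated reads over sum
of total reads), and tests regions with a two-group pooled-variance
Student's t-test on the per-sample weighted levels.

Coordinates: CpG positions and DMR spans are 1-based inclusive
(Bismark convention); BED blacklists are 0-based half-open and are
converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DmrConfig",
    "MethylationMatrix",
    "CandidateRegion",
    "read_cpg_calls",
    "write_cpg_calls",
    "filter_sites",
    "conversion_rate",
    "site_methylation",
    "methylation_fractions",
    "detect_differential_cpgs",
    "cluster_into_regions",
    "weighted_region_methylation",
    "test_region",
    "evaluate_candidate_regions",
    "call_dmrs",
    "summarize_direction",
]

GROUPS = ("control", "treated")


@dataclass(frozen=True)
class DmrConfig:
    """Thresholds of the DMR-calling chain.

    min_reads
        Minimum total reads for a per-sample CpG observation to be
        used; shallower observations are masked (default 10 reads).
    min_samples_covered_per_group
        Minimum surviving observations per group for a CpG (and, at
        the region stage, for the region) to be testable.
    cpg_delta_threshold
        Absolute between-group mean-methylation difference, in
        percentage points, for a CpG to be called differential.  A
        threshold of 0 disables the differential screen: every
        testable CpG becomes a candidate member and the same-sign
        clustering constraint is waived (the sign of an unthresholded
        difference is noise); this mode yields selection-free
        candidate regions for calibration studies.
    max_gap
        Maximum distance in bp between consecutive member CpGs.
    min_cpgs
        Minimum CpGs per region (at least 3).
    alpha
        Region-level significance threshold for the Student's t-test.
        Raw p-values; no multiplicity correction is applied.
    site_filter_mode
        "observation" masks only the shallow observation and keeps
        the site for other samples; "site" drops the whole site when
        any observation is shallow.
    """

    min_reads: int = 10
    min_samples_covered_per_group: int = 3
    cpg_delta_threshold: float = 10.0
    max_gap: int = 250
    min_cpgs: int = 3
    alpha: float = 0.05
    site_filter_mode: str = "observation"

    def __post_init__(self) -> None:
        if self.min_cpgs < 3:
            raise ValueError("min_cpgs must be >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cpg_delta_threshold < 0:
            raise ValueError("cpg_delta_threshold must be >= 0")
        if self.site_filter_mode not in ("observation", "site"):
            raise ValueError("site_filter_mode must be 'observation' or 'site'")


@dataclass
class MethylationMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``meth`` and ``total`` are integer DataFrames indexed by
    ``(chrom, pos)`` (1-based CpG position) with one column per
    sample; an observation with ``total == 0`` is uncovered/masked.
    ``groups`` maps each sample id to "control" or "treated".
    ``lambda_counts`` optionally holds the unmethylated spike-in
    (lambda phage) sites as a ``(meth, total)`` pair of DataFrames.
    """

    meth: pd.DataFrame
    total: pd.DataFrame
    groups: pd.Series
    lambda_counts: tuple[pd.DataFrame, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.total.index):
            raise ValueError("meth and total must share a site index")
        if list(self.meth.columns) != list(self.total.columns):
            raise ValueError("meth and total must share sample columns")
        if self.meth.index.has_duplicates:
            raise ValueError("duplicate CpG sites in matrix")
        if not self.meth.index.is_monotonic_increasing:
            order = self.meth.index.sortlevel()[1]
            self.meth = self.meth.iloc[order]
            self.total = self.total.iloc[order]
        missing = set(self.meth.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.meth.values > self.total.values).any():
            raise ValueError("methylated counts exceed total counts")
        if (self.meth.values < 0).any() or (self.total.values < 0).any():
            raise ValueError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_sites(self) -> int:
        return len(self.meth)

    def sample_ids(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.meth.copy(), self.total.copy(), self.groups.copy(),
            None if self.lambda_counts is None
            else (self.lambda_counts[0].copy(), self.lambda_counts[1].copy()),
        )


@dataclass(frozen=True)
class CandidateRegion:
    """A clustered run of (differential) CpGs awaiting the region test."""

    chrom: str
    start: int  # 1-based position of the first member CpG
    end: int    # 1-based position of the last member CpG
    member_pos: tuple[int, ...]

    @property
    def n_cpgs(self) -> int:
        return len(self.member_pos)


# ---------------------------------------------------------------------------
# I/O — Bismark coverage dialect
# ---------------------------------------------------------------------------

_COV_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]


def _read_one_coverage(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_COV_COLUMNS,
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed coverage file: {exc}") from exc
    if df.empty:
        return df.assign(pos=pd.Series(dtype=int))
    for col in ("start", "end", "count_meth", "count_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}, line {line}: non-integer value in column {col!r}")
        df[col] = vals.astype(int)
    mism = df["start"] != df["end"]
    if mism.any():
        line = int(mism.idxmax()) + 1
        raise ValueError(f"{path}, line {line}: start != end for a CpG record")
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    df["pos"] = df["start"]
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        line = int(dup.idxmax()) + 1
        raise ValueError(f"{path}, line {line}: duplicate CpG site within one file")
    return df


def read_cpg_calls(
    paths: Mapping[str, str | Path],
    groups: Mapping[str, str],
) -> MethylationMatrix:
    """Read per-sample Bismark-coverage files into a union site matrix.

    ``paths`` maps sample id to file path; ``groups`` maps sample id
    to "control"/"treated".  Sites absent from a sample carry
    ``total == 0`` for it (uncovered), never an imputed value.
    """
    meth_cols: dict[str, pd.Series] = {}
    total_cols: dict[str, pd.Series] = {}
    for sample, path in paths.items():
        df = _read_one_coverage(Path(path))
        idx = pd.MultiIndex.from_arrays(
            [df["chrom"], df["pos"]], names=["chrom", "pos"]
        )
        meth_cols[sample] = pd.Series(df["count_meth"].values, index=idx)
        total_cols[sample] = pd.Series(
            (df["count_meth"] + df["count_unmeth"]).values, index=idx
        )
    meth = pd.DataFrame(meth_cols).astype(float).fillna(0).astype(int).sort_index()
    total = pd.DataFrame(total_cols).astype(float).fillna(0).astype(int).sort_index()
    meth = meth[list(paths)]
    total = total[list(paths)]
    return MethylationMatrix(meth, total, pd.Series(dict(groups)))


def write_cpg_calls(m: MethylationMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write one Bismark-coverage file per sample; returns sample → path.

    Only covered observations (total > 0) are emitted, matching the
    dialect; re-reading the files reproduces the matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    chroms = m.meth.index.get_level_values("chrom")
    pos = m.meth.index.get_level_values("pos")
    for sample in m.samples:
        tot = m.total[sample].values
        cov = tot > 0
        met = m.meth[sample].values[cov]
        tot = tot[cov]
        df = pd.DataFrame({
            "chrom": chroms[cov],
            "start": pos[cov],
            "end": pos[cov],
            "meth_pct": 100.0 * met / tot,
            "count_meth": met,
            "count_unmeth": tot - met,
        })
        path = outdir / f"{sample}.cov"
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
        written[sample] = path
    return written


# ---------------------------------------------------------------------------
# Filtering and per-site statistics
# ---------------------------------------------------------------------------

def _blacklist_mask(index: pd.MultiIndex, blacklist) -> np.ndarray:
    """Boolean mask of sites overlapping 0-based half-open intervals."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    if hasattr(blacklist, "itertuples"):
        rows = ((r.chrom, int(r.start), int(r.end)) for r in blacklist.itertuples())
    else:
        rows = ((c, int(s), int(e)) for c, s, e in blacklist)
    for chrom, start, end in rows:
        trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
    chroms = index.get_level_values("chrom")
    pos = index.get_level_values("pos")
    hit = np.zeros(len(index), dtype=bool)
    for chrom, tree in trees.items():
        sel = np.flatnonzero(chroms == chrom)
        for i in sel:
            # 1-based CpG position p occupies 0-based [p-1, p)
            if tree.overlaps(int(pos[i]) - 1):
                hit[i] = True
    return hit


def filter_sites(
    m: MethylationMatrix,
    cfg: DmrConfig,
    blacklist=None,
) -> MethylationMatrix:
    """Apply read-depth masking, SNP-blacklist removal, and group-coverage pruning.

    Observations with fewer than ``cfg.min_reads`` total reads are
    masked (set uncovered); sites overlapping the blacklist (0-based
    half-open intervals) are removed entirely; sites left with fewer
    than ``cfg.min_samples_covered_per_group`` covered observations in
    either group are removed.  An empty result is legal.
    """
    meth_arr = m.meth.to_numpy().copy()
    total_arr = m.total.to_numpy().copy()
    index = m.meth.index

    if cfg.site_filter_mode == "site":
        shallow = total_arr < cfg.min_reads
        covered = total_arr > 0
        keep_site = ~(shallow & covered).any(axis=1)
        meth_arr, total_arr = meth_arr[keep_site], total_arr[keep_site]
        index = index[keep_site]
    shallow = total_arr < cfg.min_reads
    meth_arr[shallow] = 0
    total_arr[shallow] = 0
    meth = pd.DataFrame(meth_arr, index=index, columns=m.meth.columns)
    total = pd.DataFrame(total_arr, index=index, columns=m.meth.columns)

    if blacklist is not None and len(blacklist) > 0:
        hit = _blacklist_mask(meth.index, blacklist)
        meth, total = meth.loc[~hit], total.loc[~hit]

    covered = total.values > 0
    keep = np.ones(len(meth), dtype=bool)
    for group in GROUPS:
        cols = [meth.columns.get_loc(s) for s in m.samples if m.groups[s] == group]
        if cols:
            keep &= covered[:, cols].sum(axis=1) >= cfg.min_samples_covered_per_group
    return MethylationMatrix(meth.loc[keep], total.loc[keep], m.groups.copy(),
                             m.lambda_counts)


def conversion_rate(lambda_meth, lambda_total) -> float:
    """Bisulfite conversion rate from the unmethylated spike-in genome.

    Returns ``1 − Σ methylated / Σ total`` over all lambda sites and
    samples; every methylated call on the fully unmethylated spike-in
    is a conversion failure.
    """
    tot = float(np.asarray(lambda_total, dtype=float).sum())
    if tot <= 0:
        raise ValueError("conversion rate undefined: zero total spike-in reads")
    met = float(np.asarray(lambda_meth, dtype=float).sum())
    return 1.0 - met / tot


def site_methylation(meth_reads: int, total_reads: int) -> float:
    """Methylation fraction of one observation; NaN when uncovered."""
    if total_reads <= 0:
        return float("nan")
    return meth_reads / total_reads


def methylation_fractions(m: MethylationMatrix) -> pd.DataFrame:
    """Per-site per-sample methylation fractions; NaN where uncovered."""
    total = m.total.values.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, m.meth.values / total, np.nan)
    return pd.DataFrame(frac, index=m.meth.index, columns=m.meth.columns)


# ---------------------------------------------------------------------------
# Differential CpGs and clustering
# ---------------------------------------------------------------------------

def detect_differential_cpgs(
    m: MethylationMatrix,
    cfg: DmrConfig,
    treat_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Screen CpGs for a between-group mean-methylation difference.

    Group means are unweighted means of per-sample methylation
    fractions over covered samples, on the percentage scale.  A site
    is emitted iff both groups have at least
    ``cfg.min_samples_covered_per_group`` covered samples and
    ``|mean_treat − mean_control| ≥ cfg.cpg_delta_threshold``
    (percentage points).  Columns: chrom, pos, mean_treat,
    mean_control, delta, n_treat_covered, n_control_covered.
    """
    treat_ids = list(treat_ids) if treat_ids is not None else m.sample_ids("treated")
    control_ids = (list(control_ids) if control_ids is not None
                   else m.sample_ids("control"))
    frac = methylation_fractions(m)
    ft = frac[treat_ids].values
    fc = frac[control_ids].values
    n_t = np.sum(~np.isnan(ft), axis=1)
    n_c = np.sum(~np.isnan(fc), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_t = np.where(n_t > 0, 100.0 * np.nansum(ft, axis=1) / n_t, np.nan)
        mean_c = np.where(n_c > 0, 100.0 * np.nansum(fc, axis=1) / n_c, np.nan)
        delta = mean_t - mean_c
    min_n = cfg.min_samples_covered_per_group
    emit = (n_t >= min_n) & (n_c >= min_n) & (np.abs(delta) >= cfg.cpg_delta_threshold)
    out = pd.DataFrame({
        "chrom": m.meth.index.get_level_values("chrom")[emit],
        "pos": m.meth.index.get_level_values("pos")[emit].astype(int),
        "mean_treat": mean_t[emit],
        "mean_control": mean_c[emit],
        "delta": delta[emit],
        "n_treat_covered": n_t[emit],
        "n_control_covered": n_c[emit],
    })
    return out.reset_index(drop=True)


def cluster_into_regions(diff: pd.DataFrame, cfg: DmrConfig) -> list[CandidateRegion]:
    """Merge consecutive differential CpGs into candidate regions.

    Consecutive CpGs on one chromosome with the same sign of delta
    and inter-CpG distance ≤ ``cfg.max_gap`` are chained; chains with
    fewer than ``cfg.min_cpgs`` members are discarded.  When
    ``cfg.cpg_delta_threshold == 0`` the differential screen is off
    and the same-sign constraint is waived (see :class:`DmrConfig`).
    """
    if diff.empty:
        return []
    regions: list[CandidateRegion] = []
    use_sign = cfg.cpg_delta_threshold > 0
    for chrom, sub in diff.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        sign = np.sign(sub["delta"].to_numpy())
        gap_break = np.diff(pos) > cfg.max_gap
        if use_sign:
            brk = gap_break | (sign[1:] != sign[:-1])
        else:
            brk = gap_break
        chain = np.concatenate([[0], np.cumsum(brk)])
        for _, members in pd.Series(pos).groupby(chain):
            mp = tuple(int(p) for p in members)
            if len(mp) >= cfg.min_cpgs:
                regions.append(CandidateRegion(str(chrom), mp[0], mp[-1], mp))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


# ---------------------------------------------------------------------------
# Region statistics and testing
# ---------------------------------------------------------------------------

def weighted_region_methylation(
    m: MethylationMatrix,
    region: CandidateRegion,
    sample: str | None = None,
):
    """Coverage-weighted methylation level of a region.

    Per sample, ``Σ methylated / Σ total`` over **all** CpGs of the
    matrix lying within the region span (CpGs weighted by their read
    depth) — not only the differential member CpGs that seeded the
    region.  Including the non-differential CpGs inside the span
    keeps the region statistic from being computed purely on sites
    pre-selected for a group difference.  Returns a float for one
    sample or a Series over all samples; NaN when no spanned CpG is
    covered.
    """
    lo, hi = m.meth.index.slice_locs(
        (region.chrom, region.start), (region.chrom, region.end))
    tot = m.total.values[lo:hi].sum(axis=0).astype(float)
    met = m.meth.values[lo:hi].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        wm = pd.Series(np.where(tot > 0, met / tot, np.nan), index=m.meth.columns)
    if sample is not None:
        return float(wm[sample])
    return wm


def _pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided pooled-variance (Student's) t-test.

    Returns (t, p, degenerate).  Zero within-group variance in both
    groups: equal means → p = 1; unequal means → p = 0 flagged
    degenerate (the limit of the statistic).
    """
    nx, ny = len(x), len(y)
    vx = np.var(x, ddof=1) if nx > 1 else 0.0
    vy = np.var(y, ddof=1) if ny > 1 else 0.0
    if vx == 0.0 and vy == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), False


def test_region(
    m: MethylationMatrix,
    region: CandidateRegion,
    treat_ids: Sequence[str],
    control_ids: Sequence[str],
    cfg: DmrConfig,
) -> dict | None:
    """Student's t-test on per-sample weighted region methylation.

    Returns a region record (dict) with the p-value regardless of
    significance, or None when a group has fewer than 2 covered
    samples.  The record's ``significant`` field applies the
    ``p < cfg.alpha`` rule; delta and direction come from the group
    means of the weighted levels (fractions).
    """
    wm = weighted_region_methylation(m, region)
    xt = wm[list(treat_ids)].dropna().to_numpy()
    xc = wm[list(control_ids)].dropna().to_numpy()
    if len(xt) < 2 or len(xc) < 2:
        return None
    t, p, degenerate = _pooled_t_test(xt, xc)
    delta = float(np.mean(xt) - np.mean(xc))
    # region-level effect-size gate: the region's weighted-methylation
    # difference must itself meet the differential threshold, otherwise a
    # region is reported "differentially methylated" on a smaller change
    # than the per-CpG screen demands (and select-then-test inflation
    # would let diluted-noise regions through on p-value alone)
    meets_delta = abs(delta) * 100.0 >= cfg.cpg_delta_threshold
    rec = {
        "chrom": region.chrom,
        "start": region.start,
        "end": region.end,
        "n_cpgs": region.n_cpgs,
        "mean_treat": float(np.mean(xt)),
        "mean_control": float(np.mean(xc)),
        "delta": delta,
        "t_stat": t,
        "p_value": p,
        "degenerate": degenerate,
        "direction": "hyper" if delta > 0 else "hypo",
        "significant": bool(p < cfg.alpha and meets_delta),
    }
    for s in m.samples:
        rec[f"wm_{s}"] = float(wm[s])
    return rec


def evaluate_candidate_regions(
    m: MethylationMatrix,
    treat_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
    cfg: DmrConfig = DmrConfig(),
    blacklist=None,
) -> pd.DataFrame:
    """Full chain up to and including the region test, keeping every
    tested candidate region with its p-value (no significance filter).

    ``call_dmrs`` is this composition followed by the ``p < alpha``
    filter; exposing the unfiltered table supports calibration
    studies and diagnostic output.
    """
    treat_ids = list(treat_ids) if treat_ids is not None else m.sample_ids("treated")
    control_ids = (list(control_ids) if control_ids is not None
                   else m.sample_ids("control"))
    for name, ids in (("treated", treat_ids), ("control", control_ids)):
        if len(ids) < cfg.min_samples_covered_per_group:
            raise ValueError(
                f"group {name!r} has {len(ids)} samples, fewer than "
                f"min_samples_covered_per_group={cfg.min_samples_covered_per_group}"
            )
    filtered = filter_sites(m, cfg, blacklist)
    diff = detect_differential_cpgs(filtered, cfg, treat_ids, control_ids)
    regions = cluster_into_regions(diff, cfg)
    records = []
    for region in regions:
        rec = test_region(filtered, region, treat_ids, control_ids, cfg)
        if rec is not None:
            records.append(rec)
    if not records:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "n_cpgs", "mean_treat", "mean_control",
            "delta", "t_stat", "p_value", "degenerate", "direction", "significant",
        ])
    out = pd.DataFrame(records)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def call_dmrs(
    m: MethylationMatrix,
    treat_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
    cfg: DmrConfig = DmrConfig(),
    blacklist=None,
) -> pd.DataFrame:
    """Call DMRs: filter sites, screen CpGs, cluster, test regions.

    Returns the regions with ``p < cfg.alpha``, sorted by
    (chrom, start).  Raw per-region p-values — no multiple-testing
    correction is applied across regions.
    """
    tested = evaluate_candidate_regions(m, treat_ids, control_ids, cfg, blacklist)
    dmrs = tested.loc[tested["significant"].astype(bool)]
    dmrs = dmrs.drop(columns=["significant"])
    return dmrs.reset_index(drop=True)


def summarize_direction(dmrs: pd.DataFrame) -> tuple[float, float]:
    """Fractions of hyper- and hypomethylated DMRs; (nan, nan) if empty."""
    if len(dmrs) == 0:
        return (float("nan"), float("nan"))
    frac_hyper = float((dmrs["direction"] == "hyper").mean())
    return (frac_hyper, 1.0 - frac_hyper)


def write_dmr_tables(dmrs: pd.DataFrame, prefix: str | Path) -> tuple[Path, Path]:
    """Write a DMR table as BED6+ (0-based half-open) and as TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".dmrs.tsv")
    bed = prefix.with_suffix(".dmrs.bed")
    dmrs.to_csv(tsv, sep="\t", index=False)
    if len(dmrs):
        bed_df = pd.DataFrame({
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,   # 1-based inclusive -> 0-based half-open
            "end": dmrs["end"],
            "name": [f"dmr_{i}" for i in range(len(dmrs))],
            "score": 0,
            "strand": ".",
            "n_cpgs": dmrs["n_cpgs"],
            "delta": dmrs["delta"],
            "p_value": dmrs["p_value"],
            "direction": dmrs["direction"],
        })
    else:
        bed_df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score",
                                       "strand", "n_cpgs", "delta", "p_value",
                                       "direction"])
    bed_df.to_csv(bed, sep="\t", index=False, header=False)
    return bed, tsv
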