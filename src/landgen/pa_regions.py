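"""Presence/absence regions from binned read coverage.

A bin is a P/A bin when every sample of at least one group maps zero
reads while at least one other group is covered (mean per-sample count at
or above a threshold). Adjacent bins with identical group-presence
patterns merge into regions; regions feed Jaccard distances, NJ trees and
TE-enrichment contrasts. All interval logic is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import nj_with_bootstrap, nj_tree, TreeNode


@dataclass
class BinCoverage:
    """Fixed-size genome bins with per-sample read counts."""

    bins: pd.DataFrame          # columns: chrom, start, end (0-based half-open)
    counts: np.ndarray          # (n_bins, n_samples) int
    samples: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.counts.shape != (len(self.bins), len(self.samples)):
            raise ValueError("counts shape does not match bins x samples")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts)
            if np.any(ends[order][:-1] > starts[order][1:]):
                raise ValueError(f"overlapping bins on {chrom}")

    @property
    def bin_size(self) -> int:
        sizes = (self.bins["end"] - self.bins["start"]).unique()
        return int(sizes[0])


@dataclass
class PARegionSet:
    """Merged presence/absence regions and their group-presence patterns."""

    regions: pd.DataFrame        # columns: chrom, start, end
    group_presence: pd.DataFrame  # groups x regions binary

    def __post_init__(self) -> None:
        gp = self.group_presence.to_numpy()
        if gp.size:
            per_region = gp.sum(axis=0)
            if np.any(per_region == 0) or np.any(per_region == gp.shape[0]):
                raise ValueError(
                    "each region needs >= 1 absent and >= 1 present group"
                )

    @property
    def lengths(self) -> np.ndarray:
        return (self.regions["end"] - self.regions["start"]).to_numpy()

    def summary(self) -> dict:
        ln = self.lengths
        return {
            "n_regions": len(ln),
            "mean_length": float(ln.mean()) if len(ln) else np.nan,
            "sd_length": float(ln.std(ddof=1)) if len(ln) > 1 else np.nan,
            "min_length": int(ln.min()) if len(ln) else 0,
            "max_length": int(ln.max()) if len(ln) else 0,
        }


@dataclass
class TEMask:
    """Merged repeat-mask intervals (0-based half-open)."""

    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def masked_bp(self, chrom: str, start: int, end: int) -> int:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if sub.empty:
            return 0
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        overlap = np.minimum(e, end) - np.maximum(s, start)
        return int(np.clip(overlap, 0, None).sum())


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent half-open intervals per chromosome."""
    if intervals.empty:
        return intervals.reset_index(drop=True)
    out = []
    for chrom, sub in intervals.sort_values(["chrom", "start"]).groupby(
        "chrom", sort=True
    ):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def call_pa_bins(
    cov: BinCoverage,
    groups: pd.Series,
    min_presence_mean: float = 1.0,
) -> pd.DataFrame:
    """Flag P/A bins and report per-bin group presence.

    Returns the bin table extended with ``is_pa`` and one boolean presence
    column per group (True = any read in that group). A bin qualifies iff
    >= 1 group has all-zero counts and >= 1 other group has mean per-sample
    count >= ``min_presence_mean``.
    """
    labels = groups.reindex(cov.samples)
    if labels.isna().any():
        missing = [s for s, g in zip(cov.samples, labels) if pd.isna(g)]
        raise ValueError(f"samples without group assignment: {missing}")
    names = sorted(labels.unique())
    lab = labels.to_numpy()

    presence = {}
    means = {}
    for name in names:
        cols = cov.counts[:, lab == name]
        if cols.shape[1] == 0:
            raise ValueError(f"group {name!r} has no samples")
        presence[name] = cols.sum(axis=1) > 0
        means[name] = cols.mean(axis=1)

    pres = np.column_stack([presence[n] for n in names])
    strong = np.column_stack([means[n] >= min_presence_mean for n in names])
    n_present = pres.sum(axis=1)
    is_pa = (n_present >= 1) & (n_present <= len(names) - 1) & (
        (strong & pres).any(axis=1)
    )

    out = cov.bins.copy().reset_index(drop=True)
    out["is_pa"] = is_pa
    for k, name in enumerate(names):
        out[f"present_{name}"] = pres[:, k]
    return out


def merge_pa_regions(pa_bins: pd.DataFrame) -> PARegionSet:
    """Merge adjacent P/A bins with identical group-presence patterns."""
    pres_cols = [c for c in pa_bins.columns if c.startswith("present_")]
    groups = [c[len("present_"):] for c in pres_cols]
    sub = pa_bins[pa_bins["is_pa"]].sort_values(["chrom", "start"])

    regions = []
    patterns = []
    prev = None
    for row in sub.itertuples(index=False):
        pattern = tuple(getattr(row, c) for c in pres_cols)
        if (
            prev is not None
            and row.chrom == prev["chrom"]
            and row.start == prev["end"]
            and pattern == prev["pattern"]
        ):
            prev["end"] = row.end
        else:
            if prev is not None:
                regions.append((prev["chrom"], prev["start"], prev["end"]))
                patterns.append(prev["pattern"])
            prev = {"chrom": row.chrom, "start": row.start, "end": row.end,
                    "pattern": pattern}
    if prev is not None:
        regions.append((prev["chrom"], prev["start"], prev["end"]))
        patterns.append(prev["pattern"])

    reg_df = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    names = [f"{c}:{s}-{e}" for c, s, e in regions]
    gp = pd.DataFrame(
        np.array(patterns, dtype=int).T if patterns else
        np.zeros((len(groups), 0), int),
        index=groups,
        columns=names,
    )
    return PARegionSet(regions=reg_df, group_presence=gp)


def split_regions_to_bins(pa: PARegionSet, bin_size: int) -> pd.DataFrame:
    """Re-split regions into their constituent bins (round-trip check)."""
    rows = []
    for (chrom, start, end), (_, pattern) in zip(
        pa.regions.itertuples(index=False), pa.group_presence.items()
    ):
        for s in range(start, end, bin_size):
            rows.append((chrom, s, s + bin_size, *pattern.to_numpy()))
    cols = ["chrom", "start", "end"] + [
        f"present_{g}" for g in pa.group_presence.index
    ]
    df = pd.DataFrame(rows, columns=cols)
    for c in cols[3:]:
        df[c] = df[c].astype(bool)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def jaccard_distance(group_presence: pd.DataFrame) -> pd.DataFrame:
    """1 - |intersection| / |union| of presence sets; joint absences ignored."""
    x = group_presence.to_numpy(bool)
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.sum(x[i] | x[j])
            if union == 0:
                warnings.warn(
                    "two all-absent groups: Jaccard distance defined as 0"
                )
                d = 0.0
            else:
                d = 1.0 - np.sum(x[i] & x[j]) / union
            out[i, j] = out[j, i] = d
    idx = group_presence.index
    return pd.DataFrame(out, index=idx, columns=idx)


def te_enrichment(
    pa: PARegionSet,
    mask: TEMask,
    genome_bins: pd.DataFrame,
    seed: int = 0,
) -> dict:
    """Masked-bp fractions for the whole genome, the P/A bins, and an
    equally sized random control of non-P/A bins (uniform, no replacement,
    seeded)."""
    def fraction(bins: pd.DataFrame) -> float:
        total = int((bins["end"] - bins["start"]).sum())
        if total == 0:
            return 0.0
        masked = sum(
            mask.masked_bp(c, s, e)
            for c, s, e in bins[["chrom", "start", "end"]].itertuples(index=False)
        )
        return masked / total

    pa_bins = split_regions_to_bins(pa, bin_size=_infer_bin_size(genome_bins))[
        ["chrom", "start", "end"]
    ]
    key = set(map(tuple, pa_bins.to_numpy()))
    all_bins = genome_bins[["chrom", "start", "end"]].reset_index(drop=True)
    is_pa = all_bins.apply(tuple, axis=1).isin(key).to_numpy()
    non_pa = all_bins[~is_pa]
    if len(non_pa) < len(pa_bins):
        raise ValueError("fewer non-P/A bins than P/A bins")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(non_pa), size=len(pa_bins), replace=False)
    control = non_pa.iloc[np.sort(pick)]
    return {
        "genome_fraction": fraction(all_bins),
        "pa_fraction": fraction(pa_bins),
        "control_fraction": fraction(control),
    }


def _infer_bin_size(bins: pd.DataFrame) -> int:
    return int((bins["end"] - bins["start"]).iloc[0])


def nj_from_pa(
    pa: PARegionSet, n_bootstrap: int = 0, seed: int = 0
) -> tuple[TreeNode, dict]:
    """NJ tree over groups from Jaccard distances on region presence, with
    bootstrap over regions (column resampling) for split supports."""
    gp = pa.group_presence
    if gp.shape[0] < 3:
        raise ValueError("need at least 3 groups for a tree")
    dist = jaccard_distance(gp)
    if not n_bootstrap:
        return nj_tree(dist), {}
    labels = list(gp.index)

    def dist_fn(cols: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(cols, index=labels)
        return jaccard_distance(df)

    return nj_with_bootstrap(
        dist, column_matrix=gp.to_numpy(), dist_fn=dist_fn,
        n_reps=n_bootstrap, seed=seed,
    )
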