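"""Seeded synthetic input bundles with the statistical structure the
analysis expects: a selfing population in clades and local groups along an
environmental transect, injected environment-associated loci, high-Fst
outlier loci, group-consistent zero-coverage regions enriched for TE
intervals, and truth tables for every injected feature.

Allele frequencies follow hierarchical Balding-Nichols draws
(clade -> group); coverage is negative-binomial per covered bin with
exact zeros in absence bins (presence bins are kept strictly positive so
noiseless recovery is well-defined).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneSet
from .geo_env import SampleSheet, env_pca
from .pa_regions import BinCoverage, TEMask
from .popgen import GenotypeMatrix


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    n_groups: int = 9
    samples_per_group: int = 10
    n_loci: int = 500
    selfing_rate: float = 0.99
    n_clades: int = 2
    fst_between_clades: float = 0.2
    fst_within_clade: float = 0.03
    transect_length_km: float = 1000.0
    env_noise_sd: float = 0.3
    n_eas: int = 0
    eas_effect: float = 3.0
    n_outliers: int = 0
    outlier_fst: float = 0.8
    genome_length_bp: int = 1_000_000
    bin_size_bp: int = 1000
    n_chroms: int = 2
    n_pa_regions: int = 0
    pa_env_driven: bool = False
    pa_te_enrichment: float = 3.0
    te_background_density: float = 0.15
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.0
    ld_block_span: int = 1
    seed: int = 0

    def validate(self) -> None:
        counts = [
            "n_groups", "samples_per_group", "n_loci", "n_clades", "n_eas",
            "n_outliers", "n_pa_regions", "genome_length_bp", "bin_size_bp",
            "n_chroms", "ld_block_span",
        ]
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        fractions = [
            "selfing_rate", "fst_between_clades", "fst_within_clade",
            "outlier_fst", "missing_rate", "te_background_density",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_eas + self.n_outliers > self.n_loci:
            raise ConfigError("n_eas + n_outliers must be <= n_loci")
        if self.n_clades > self.n_groups:
            raise ConfigError("n_clades must be <= n_groups")
        if self.n_groups > 0 and self.n_clades < 1:
            raise ConfigError("n_clades must be >= 1")
        if self.bin_size_bp > 0 and self.genome_length_bp % self.bin_size_bp:
            raise ConfigError("genome_length_bp must be a multiple of bin_size_bp")


@dataclass
class DatasetBundle:
    config: SimConfig
    sample_sheet: SampleSheet
    env_table: pd.DataFrame
    genotypes: GenotypeMatrix
    coverage: BinCoverage
    te_mask: TEMask
    gene_models: GeneSet
    eas_truth: pd.DataFrame
    outlier_truth: pd.DataFrame
    pa_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        from . import io_pipeline as io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sample_sheet.table.to_csv(
            outdir / "samples.tsv", sep="\t", index=False
        )
        self.env_table.to_csv(outdir / "environment.tsv", sep="\t")
        io.write_genotypes_tsv(self.genotypes, outdir / "genotypes.tsv")
        io.write_vcf(self.genotypes, outdir / "genotypes.vcf")
        io.write_coverage(self.coverage, outdir / "coverage.tsv")
        io.write_bed(self.te_mask.intervals, outdir / "te_mask.bed")
        io.write_gff3(self.gene_models, outdir / "genes.gff3")
        self.eas_truth.to_csv(outdir / "truth_eas.tsv", sep="\t", index=False)
        self.outlier_truth.to_csv(
            outdir / "truth_outliers.tsv", sep="\t", index=False
        )
        self.pa_truth.to_csv(outdir / "truth_pa.tsv", sep="\t", index=False)


_ENV_VARS = ["altitude"] + [f"bio{i}" for i in range(1, 20)]


def _chrom_sizes(config: SimConfig) -> dict[str, int]:
    n_bins = config.genome_length_bp // config.bin_size_bp
    per = n_bins // config.n_chroms
    sizes = {}
    for i in range(config.n_chroms):
        nb = per + (1 if i < n_bins % config.n_chroms else 0)
        sizes[f"chr{i + 1}"] = nb * config.bin_size_bp
    return sizes


def _make_geography(config: SimConfig, rng: np.random.Generator):
    """Groups on a west-east transect, samples jittered around each point."""
    g = config.n_groups
    t = np.linspace(0.0, 1.0, g) if g > 1 else np.array([0.5])
    lat0 = 39.8
    km_per_deg_lon = 111.32 * np.cos(np.radians(lat0))
    lons = 26.5 + t * config.transect_length_km / km_per_deg_lon
    lats = np.full(g, lat0) + rng.normal(0, 0.05, size=g)
    alts = 100.0 + 900.0 * t + rng.normal(0, 10, size=g)
    names = [f"G{i + 1}" for i in range(g)]
    rows = []
    for gi, name in enumerate(names):
        for s in range(config.samples_per_group):
            rows.append(
                (
                    f"{name}_s{s + 1}",
                    name,
                    round(lats[gi] + rng.normal(0, 1e-3), 6),
                    round(np.clip(lons[gi] + rng.normal(0, 1e-3), -180, 180), 6),
                    round(alts[gi], 1),
                )
            )
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample", "group", "lat", "lon", "altitude"])
    )
    return sheet, names, t, alts


def _make_environment(config, rng, names, t, alts) -> pd.DataFrame:
    """19 BioClim-like variables plus altitude, driven by the transect
    gradient so environmental PC1 is monotone along it."""
    data = {"altitude": np.round(alts, 1)}
    for i in range(1, 20):
        slope = rng.uniform(1.0, 3.0) * (1 if rng.random() < 0.5 else -1)
        base = rng.uniform(-5, 5)
        data[f"bio{i}"] = np.round(
            base + slope * t + rng.normal(0, config.env_noise_sd, size=len(t)), 4
        )
    return pd.DataFrame(data, index=pd.Index(names, name="location"))


def _balding_nichols(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    if fst <= 0:
        return p_anc.copy()
    theta = (1.0 - fst) / fst
    a = np.clip(theta * p_anc, 1e-6, None)
    b = np.clip(theta * (1.0 - p_anc), 1e-6, None)
    return rng.beta(a, b)


def _group_frequencies(config: SimConfig, rng, pc1_z: np.ndarray):
    """Per-group allele frequencies plus truth tables of injected loci."""
    g, L = config.n_groups, config.n_loci
    clade_of = np.arange(g) % config.n_clades

    p_anc = rng.uniform(0.1, 0.9, size=L)
    # divergence corrected so realized pairwise Weir-Cockerham theta between
    # clades tracks the requested value (theta ~ F / (1 - F/2) otherwise)
    f_clade = config.fst_between_clades / (1.0 + config.fst_between_clades / 2.0)
    clade_p = np.stack(
        [_balding_nichols(rng, p_anc, f_clade) for _ in range(config.n_clades)]
    )
    freqs = np.stack(
        [
            _balding_nichols(rng, clade_p[clade_of[gi]], config.fst_within_clade)
            for gi in range(g)
        ]
    )  # (groups, loci)

    special = rng.choice(L, size=config.n_eas + config.n_outliers, replace=False)
    eas_idx = np.sort(special[: config.n_eas])
    out_idx = np.sort(special[config.n_eas:])

    eas_rows = []
    from scipy.special import expit

    for k in eas_idx:
        sign = 1 if rng.random() < 0.5 else -1
        freqs[:, k] = expit(sign * config.eas_effect * pc1_z)
        eas_rows.append((int(k), sign))

    out_rows = []
    half_sep = np.sqrt(min(config.outlier_fst, 0.96)) / 2.0
    for k in out_idx:
        lo, hi = 0.5 - half_sep, 0.5 + half_sep
        freqs[:, k] = np.where(clade_of % 2 == 0, lo, hi)
        out_rows.append((int(k), lo, hi))

    return freqs, eas_idx, out_idx, eas_rows, out_rows


def _draw_genotypes(config: SimConfig, rng, freqs: np.ndarray) -> np.ndarray:
    """Diploid codes with selfing-equilibrium inbreeding F = s / (2 - s)."""
    g, L = freqs.shape
    n = g * config.samples_per_group
    f_is = config.selfing_rate / (2.0 - config.selfing_rate)
    codes = np.empty((n, L), dtype=np.int8)
    span = max(config.ld_block_span, 1)
    row = 0
    for gi in range(g):
        p = freqs[gi]
        for _ in range(config.samples_per_group):
            if span > 1:
                # draw one genotype per planted haplotype block, copy within
                block_ids = np.arange(L) // span
                n_blocks = block_ids[-1] + 1
                p_block = p[np.minimum(np.arange(n_blocks) * span, L - 1)]
                ibd = rng.random(n_blocks) < f_is
                a1 = rng.random(n_blocks) < p_block
                a2 = np.where(ibd, a1, rng.random(n_blocks) < p_block)
                geno_block = a1.astype(np.int8) + a2.astype(np.int8)
                geno = geno_block[block_ids]
                flip = rng.random(L) < 0.02   # sparse intra-block discordance
                re_a1 = rng.random(L) < p
                re_ibd = rng.random(L) < f_is
                re_a2 = np.where(re_ibd, re_a1, rng.random(L) < p)
                geno = np.where(flip, re_a1.astype(np.int8) + re_a2, geno)
            else:
                ibd = rng.random(L) < f_is
                a1 = rng.random(L) < p
                a2 = np.where(ibd, a1, rng.random(L) < p)
                geno = a1.astype(np.int8) + a2.astype(np.int8)
            codes[row] = geno
            row += 1
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = -1
    return codes


def _locus_positions(config: SimConfig, rng, sizes: dict[str, int]):
    chroms, positions = [], []
    total = sum(sizes.values())
    per_chrom = {
        c: max(1, int(round(config.n_loci * s / total))) for c, s in sizes.items()
    }
    # adjust rounding drift on the last chromosome
    drift = config.n_loci - sum(per_chrom.values())
    last = list(sizes)[-1]
    per_chrom[last] = max(1, per_chrom[last] + drift)
    for c, k in per_chrom.items():
        pos = np.sort(rng.choice(np.arange(1, sizes[c] + 1), size=k, replace=False))
        chroms.extend([c] * k)
        positions.extend(pos.tolist())
    return np.array(chroms, dtype=object), np.array(positions, dtype=np.int64)


def _make_coverage(config: SimConfig, rng, sizes, group_names, sheet):
    """Binned counts with injected group-consistent zero-coverage regions."""
    bin_rows = []
    for c, size in sizes.items():
        for s in range(0, size, config.bin_size_bp):
            bin_rows.append((c, s, s + config.bin_size_bp))
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end"])
    n_bins = len(bins)
    samples = sheet.samples
    labels = sheet.groups.reindex(samples).to_numpy()

    # choose region start bins, keeping a one-bin gap so regions stay distinct
    region_len = rng.integers(1, 4, size=config.n_pa_regions)
    chosen: list[tuple[int, int]] = []
    occupied = np.zeros(n_bins, dtype=bool)
    tries = 0
    k = 0
    while k < config.n_pa_regions and tries < 100 * max(config.n_pa_regions, 1):
        tries += 1
        ln = int(region_len[k])
        start = int(rng.integers(0, n_bins - ln))
        lo, hi = max(0, start - 1), min(n_bins, start + ln + 1)
        chrom0 = bins["chrom"].iloc[start]
        if bins["chrom"].iloc[start + ln - 1] != chrom0:
            continue
        if occupied[lo:hi].any():
            continue
        occupied[start : start + ln] = True
        chosen.append((start, ln))
        k += 1
    if k < config.n_pa_regions:
        raise ConfigError(
            "n_pa_regions too large for the genome/bin configuration"
        )
    chosen.sort()

    # strictly positive counts in covered bins: 1 + NB(mean-1, dispersion)
    mu = max(config.mean_depth - 1.0, 0.1)
    r = config.depth_dispersion
    p_nb = r / (r + mu)
    counts = 1 + rng.negative_binomial(r, p_nb, size=(n_bins, len(samples)))

    pa_rows = []
    for start, ln in chosen:
        if config.pa_env_driven:
            # absence tracks the transect: one side of a random cut point
            cut = int(rng.integers(1, config.n_groups))
            side = rng.random() < 0.5
            absent = list(range(cut)) if side else list(
                range(cut, config.n_groups)
            )
        else:
            n_absent = int(rng.integers(1, config.n_groups))
            absent = sorted(
                rng.choice(config.n_groups, size=n_absent, replace=False).tolist()
            )
        absent_names = [group_names[i] for i in absent]
        absent_mask = np.isin(labels, absent_names)
        counts[start : start + ln][:, absent_mask] = 0
        pa_rows.append(
            (
                bins["chrom"].iloc[start],
                int(bins["start"].iloc[start]),
                int(bins["end"].iloc[start + ln - 1]),
                ",".join(absent_names),
            )
        )
    pa_truth = pd.DataFrame(pa_rows, columns=["chrom", "start", "end", "absent_groups"])
    pa_truth = pa_truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    cov = BinCoverage(bins=bins, counts=counts, samples=samples)
    return cov, pa_truth


def _make_te_mask(config: SimConfig, rng, sizes, pa_truth) -> TEMask:
    rows = []
    for c, size in sizes.items():
        target_bp = config.te_background_density * size
        covered = 0.0
        while covered < target_bp:
            ln = int(rng.integers(100, 500))
            s = int(rng.integers(0, max(size - ln, 1)))
            rows.append((c, s, s + ln))
            covered += ln
    # densify inside injected P/A regions
    extra = config.te_background_density * (config.pa_te_enrichment - 1.0)
    for row in pa_truth.itertuples(index=False):
        span = row.end - row.start
        covered = 0.0
        while covered < extra * span:
            ln = int(rng.integers(50, 200))
            s = int(rng.integers(row.start, max(row.end - ln, row.start + 1)))
            rows.append((row.chrom, s, min(s + ln, row.end)))
            covered += ln
    return TEMask(intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _make_genes(config: SimConfig, rng, sizes) -> GeneSet:
    rows = []
    idx = 0
    for c, size in sizes.items():
        pos = 1
        while pos + 2500 < size:
            gap = int(rng.integers(1000, 4000))
            start = pos + gap
            length = int(rng.integers(800, 2500))
            end = min(start + length, size)
            if end - start < 200:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            idx += 1
            rows.append((f"gene{idx:05d}", c, start, end, strand))
            pos = end
    return GeneSet(
        genes=pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        )
    )


def simulate_dataset(config: SimConfig) -> DatasetBundle:
    """Generate a complete, seeded input bundle (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = _chrom_sizes(config)

    sheet, group_names, t, alts = _make_geography(config, rng)
    env = _make_environment(config, rng, group_names, t, alts)

    pcs = env_pca(env, k=3)
    pc1 = pcs.scores["PC1"].to_numpy()
    # orient so PC1 increases along the transect, then standardize
    if np.corrcoef(pc1, t)[0, 1] < 0:
        pc1 = -pc1
    pc1_z = (pc1 - pc1.mean()) / pc1.std()

    freqs, eas_idx, out_idx, eas_rows, out_rows = _group_frequencies(
        config, rng, pc1_z
    )
    codes = _draw_genotypes(config, rng, freqs)
    chrom, pos = _locus_positions(config, rng, sizes)
    ref = np.array(["A"] * config.n_loci, dtype=object)
    alt = np.array(["T"] * config.n_loci, dtype=object)
    genotypes = GenotypeMatrix(
        samples=sheet.samples,
        codes=codes,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        groups=sheet.groups,
    )

    eas_truth = pd.DataFrame(
        [
            (int(k), str(genotypes.chrom[k]), int(genotypes.pos[k]), sign)
            for (k, sign) in eas_rows
        ],
        columns=["locus", "chrom", "pos", "slope_sign"],
    )
    outlier_truth = pd.DataFrame(
        [
            (int(k), str(genotypes.chrom[k]), int(genotypes.pos[k]), lo, hi)
            for (k, lo, hi) in out_rows
        ],
        columns=["locus", "chrom", "pos", "freq_low", "freq_high"],
    )

    coverage, pa_truth = _make_coverage(config, rng, sizes, group_names, sheet)
    te_mask = _make_te_mask(config, rng, sizes, pa_truth)
    genes = _make_genes(config, rng, sizes)

    return DatasetBundle(
        config=config,
        sample_sheet=sheet,
        env_table=env,
        genotypes=genotypes,
        coverage=coverage,
        te_mask=te_mask,
        gene_models=genes,
        eas_truth=eas_truth,
        outlier_truth=outlier_truth,
        pa_truth=pa_truth,
    )
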