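"""Readers/writers for the standard formats, run configuration, and the
stage-chaining pipeline driver.

Coordinate dialects: BED and the coverage table are 0-based half-open;
VCF and GFF3 are 1-based. Genotypes are never imputed at the IO boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import env_association as assoc
from . import fst_outliers as outliers
from . import geo_env
from . import ld_blocks as ldb
from . import ordination
from . import pa_regions as pa
from . import popgen

logger = logging.getLogger("landgen")


def _stage_logger(stage: str) -> logging.Logger:
    lg = logging.getLogger(f"landgen.{stage}")
    if not logging.getLogger("landgen").handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        logging.getLogger("landgen").addHandler(h)
        logging.getLogger("landgen").setLevel(logging.INFO)
    return lg


# ---------------------------------------------------------------------------
# Genotypes


def read_genotypes(path: str | Path) -> popgen.GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV (codes 0/1/2/NA)."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_genotypes_tsv(path)


def read_vcf(path: str | Path) -> popgen.GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multi-allelic records are an error."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, cols = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} "
                f"({v.REF}->{','.join(v.ALT)})"
            )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(v.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cols.append(col.astype(np.int8))
    codes = (
        np.column_stack(cols)
        if cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return popgen.GenotypeMatrix(
        samples=samples,
        codes=codes,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def read_genotypes_tsv(path: str | Path) -> popgen.GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    codes = df[samples].to_numpy(float)
    codes = np.where(np.isnan(codes), -1, codes).astype(np.int8).T
    return popgen.GenotypeMatrix(
        samples=samples,
        codes=codes,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
    )


def write_genotypes_tsv(g: popgen.GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"chrom": g.chrom, "pos": g.pos, "ref": g.ref, "alt": g.alt})
    for i, s in enumerate(g.samples):
        df[s] = ["NA" if v == -1 else int(v) for v in g.codes[i]]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(g: popgen.GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields."""
    lines = ["##fileformat=VCFv4.2"]
    chrom_str = g.chrom.astype(str)
    for chrom in pd.unique(chrom_str):
        length = int(g.pos[chrom_str == chrom].max()) + 10000
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.samples)
    )
    for k in range(g.n_loci):
        gts = "\t".join(_GT_STRINGS[int(v)] for v in g.codes[:, k])
        lines.append(
            f"{g.chrom[k]}\t{g.pos[k]}\t.\t{g.ref[k]}\t{g.alt[k]}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def filter_loci(
    g: popgen.GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.80,
) -> popgen.GenotypeMatrix:
    """Keep loci with call rate >= call_rate_min and MAF >= maf_min
    (both computed over non-missing calls); order preserved."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    obs = g.codes != popgen.MISSING
    call_rate = obs.mean(axis=0)
    p = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1 - p)
    keep = (call_rate >= call_rate_min) & (maf >= maf_min) & ~np.isnan(maf)
    if not keep.any():
        warnings.warn("no loci pass the filters")
    return g.subset_loci(keep)


# ---------------------------------------------------------------------------
# Other formats


def read_sample_sheet(path: str | Path) -> geo_env.SampleSheet:
    return geo_env.SampleSheet(pd.read_csv(path, sep="\t"))


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_coverage(path: str | Path) -> pa.BinCoverage:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["chrom", "start", "end"]
    samples = [c for c in df.columns if c not in meta]
    return pa.BinCoverage(
        bins=df[meta].copy(),
        counts=df[samples].to_numpy(np.int64),
        samples=samples,
    )


def write_coverage(cov: pa.BinCoverage, path: str | Path) -> None:
    df = cov.bins.copy()
    for i, s in enumerate(cov.samples):
        df[s] = cov.counts[:, i]
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_gff3(genes: ann.GeneSet, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for row in genes.genes.itertuples(index=False):
        lines.append(
            f"{row.chrom}\tlandgen\tgene\t{row.start}\t{row.end}\t.\t"
            f"{row.strand}\t.\tID={row.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_newick(tree: popgen.TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Run configuration


_ALL_STAGES = [
    "filter", "envpca", "popgen", "ldblocks", "assoc", "outliers",
    "annotate", "pascan", "cca", "report",
]


@dataclass
class RunConfig:
    """Resolved run parameters; defaults mirror the published analysis."""

    genotypes: str = ""
    samples: str = ""
    environment: str = ""
    coverage: str = ""
    te_mask: str = ""
    genes: str = ""
    outdir: str = "results"

    maf_min: float = 0.05
    call_rate_min: float = 0.80
    bin_size: int = 1000
    min_presence_mean: float = 1.0
    n_env_pcs: int = 3
    n_genotype_pcs: int = 5
    n_latent_factors: int = 5
    n_clusters: int = 5
    ld_window: int = 500
    dprime_strong_upper: float = 0.98
    dprime_strong_lower: float = 0.7
    dprime_recomb_upper: float = 0.9
    min_strong_fraction: float = 0.95
    alpha_target: float = 0.1
    outlier_fdr: float = 0.05
    outlier_prior_odds: float = 10.0
    mcmc_burn: int = 1000
    mcmc_iter: int = 10000
    mcmc_thin: int = 10
    n_permutations: int = 999
    n_bootstrap: int = 100
    upstream_bp: int = 5000
    seed: int = 1

    stages: dict = field(default_factory=lambda: {s: True for s in _ALL_STAGES})

    def stage_seed(self, stage: str) -> int:
        return self.seed + 1000 * (_ALL_STAGES.index(stage) + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = {s: cfg.stages.get(s, True) for s in _ALL_STAGES}
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# Pipeline driver


def run_pipeline(config: RunConfig) -> Path:
    """Run the enabled stages in order and write a markdown report.

    Returns the output directory. Raises on the first stage failure after
    logging the stage name and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    state: dict = {}

    def stage(name):
        def deco(fn):
            lg = _stage_logger(name)
            if not config.stages.get(name, True):
                lg.info("stage disabled, skipping")
                return
            missing = [d for d in getattr(fn, "_needs", []) if d not in state]
            if missing:
                lg.warning("skipping: required upstream results missing: %s",
                           missing)
                return
            try:
                lg.info("running")
                fn(lg)
            except Exception as exc:
                lg.error("stage failed: %s", exc)
                raise
        return deco

    def needs(*deps):
        def mark(fn):
            fn._needs = deps
            return fn
        return mark

    sheet = read_sample_sheet(config.samples)
    state["sheet"] = sheet

    @stage("filter")
    def _filter(lg):
        g = read_genotypes(config.genotypes)
        g.groups = sheet.groups
        n0 = g.n_loci
        g = filter_loci(g, config.maf_min, config.call_rate_min)
        lg.info("retained %d of %d loci", g.n_loci, n0)
        write_genotypes_tsv(g, out / "genotypes_filtered.tsv")
        state["genotypes"] = g

    @stage("envpca")
    def _envpca(lg):
        env = read_env_table(config.environment)
        pcs = geo_env.env_pca(env, k=config.n_env_pcs)
        pcs.scores.to_csv(out / "env_pc_scores.tsv", sep="\t")
        pcs.loadings.to_csv(out / "env_pc_loadings.tsv", sep="\t")
        pd.Series(
            pcs.variance_fractions,
            index=pcs.scores.columns, name="variance_fraction",
        ).to_csv(out / "env_pc_fractions.tsv", sep="\t")
        gd = geo_env.distance_matrix_km(sheet.group_coordinates())
        gd.to_csv(out / "geographic_distance_km.tsv", sep="\t")
        state["env_pcs"] = pcs
        state["geo_dist"] = gd

    @stage("popgen")
    @needs("genotypes")
    def _popgen(lg):
        g = state["genotypes"]
        fst = popgen.pairwise_fst(g)
        fst.to_csv(out / "pairwise_fst.tsv", sep="\t")
        kin = popgen.vanraden_kinship(g)
        kin.values.to_csv(out / "kinship.tsv", sep="\t")
        pdist = popgen.p_distance(g)
        pdist.to_csv(out / "p_distance.tsv", sep="\t")
        tree, supports = popgen.nj_with_bootstrap(
            pdist,
            column_matrix=g.codes,
            dist_fn=lambda m: popgen.p_distance(
                dataclasses.replace(g, codes=m)
            ),
            n_reps=config.n_bootstrap,
            seed=config.stage_seed("popgen"),
        )
        write_newick(tree, out / "nj_samples.nwk")
        scores = popgen.genotype_pca(g, n_pcs=config.n_genotype_pcs)
        scores.to_csv(out / "genotype_pcs.tsv", sep="\t")
        clusters = popgen.assign_clusters(
            scores, k=min(config.n_clusters, len(scores) - 1),
            seed=config.stage_seed("popgen"),
        )
        clusters.to_csv(out / "clusters.tsv", sep="\t")
        state.update(fst=fst, kinship=kin, geno_pcs=scores)
        if "geo_dist" in state:
            common = [x for x in state["geo_dist"].index if x in fst.index]
            rho, pval = geo_env.matrix_spearman(
                fst.loc[common, common],
                state["geo_dist"].loc[common, common],
                n_perm=config.n_permutations,
                seed=config.stage_seed("popgen"),
            )
            state["mantel"] = (rho, pval)
            lg.info("fst~distance spearman rho=%.4f p=%.4f", rho, pval)

    @stage("ldblocks")
    @needs("genotypes")
    def _ldblocks(lg):
        g = state["genotypes"]
        part = ldb.gabriel_blocks(
            g,
            window=config.ld_window,
            strong=(config.dprime_strong_upper, config.dprime_strong_lower),
            recomb_upper=config.dprime_recomb_upper,
            min_strong_fraction=config.min_strong_fraction,
        )
        thr = ldb.ld_bonferroni(part, config.alpha_target)
        rows = [
            (g.chrom[s], int(s), int(e), e - s + 1) for s, e in part.blocks
        ]
        pd.DataFrame(rows, columns=["chrom", "start_locus", "end_locus", "size"]
                     ).to_csv(out / "ld_blocks.tsv", sep="\t", index=False)
        (out / "ld_threshold.json").write_text(json.dumps({
            "n_blocks": len(part.blocks),
            "n_singletons": len(part.singletons),
            "n_independent_tests": part.n_independent_tests,
            "alpha_target": config.alpha_target,
            "threshold": thr,
        }, indent=2))
        lg.info("%d blocks, %d singletons, threshold %.3g",
                len(part.blocks), len(part.singletons), thr)
        state["partition"] = part
        state["threshold"] = thr

    @stage("assoc")
    @needs("genotypes", "env_pcs", "kinship", "geno_pcs", "threshold")
    def _assoc(lg):
        g = state["genotypes"]
        pcs = state["env_pcs"]
        thr = state["threshold"]
        frames = {"mlm": [], "lfmm": []}
        for pc_name in pcs.scores.columns:
            response = pcs.scores[pc_name]
            r1 = assoc.mlm_assoc(
                g, response, state["kinship"], Q=state["geno_pcs"],
                pc_name=pc_name,
            )
            r2 = assoc.lfmm_assoc(
                g, response, L=config.n_latent_factors, pc_name=pc_name
            )
            frames["mlm"].append(r1.significant(thr))
            frames["lfmm"].append(r2.significant(thr))
        mlm_all = pd.concat(frames["mlm"], ignore_index=True)
        lfmm_all = pd.concat(frames["lfmm"], ignore_index=True)
        mlm_all.to_csv(out / "assoc_mlm.tsv", sep="\t", index=False)
        lfmm_all.to_csv(out / "assoc_lfmm.tsv", sep="\t", index=False)
        eas_mlm = mlm_all[mlm_all["flag"]]
        eas_lfmm = lfmm_all[lfmm_all["flag"]]
        inter = assoc.intersect_methods(eas_mlm, eas_lfmm, per_pc=True)
        inter.to_csv(out / "assoc_intersection.tsv", sep="\t", index=False)
        lg.info("EAS: mlm=%d lfmm=%d joint=%d",
                eas_mlm["locus"].nunique(), eas_lfmm["locus"].nunique(),
                inter["locus"].nunique())
        state["eas_mlm"] = eas_mlm
        state["eas_lfmm"] = eas_lfmm
        state["eas_joint"] = inter

    @stage("outliers")
    @needs("genotypes")
    def _outliers(lg):
        g = state["genotypes"]
        alt, tot, names = outliers.allele_counts(g)
        res = outliers.bayes_fst_scan(
            (alt, tot),
            n_burn=config.mcmc_burn,
            n_iter=config.mcmc_iter,
            thin=config.mcmc_thin,
            prior_odds=config.outlier_prior_odds,
            fdr=config.outlier_fdr,
            seed=config.stage_seed("outliers"),
        )
        tbl = res.table.copy()
        tbl["chrom"] = g.chrom[tbl["locus"]]
        tbl["pos"] = g.pos[tbl["locus"]]
        tbl.to_csv(out / "outliers.tsv", sep="\t", index=False)
        summ = outliers.summarize_scan(res, g.n_loci)
        (out / "outlier_summary.json").write_text(json.dumps(summ, indent=2))
        lg.info("%d outliers (%.1f%%)", summ["n_outliers"], summ["percent"])
        state["outliers"] = tbl[tbl["flag"]]
        state["outlier_summary"] = summ

    @stage("annotate")
    @needs("genotypes")
    def _annotate(lg):
        genes = ann.read_gff3_genes(config.genes)
        per_method: dict[str, pd.DataFrame] = {}
        sources = {
            "mlm": state.get("eas_mlm"),
            "lfmm": state.get("eas_lfmm"),
            "outliers": state.get("outliers"),
        }
        summaries = []
        for method, df in sources.items():
            if df is None or df.empty:
                continue
            loci = df[["chrom", "pos"]].drop_duplicates()
            classified = ann.classify_positions(
                loci, genes, upstream_bp=config.upstream_bp
            )
            per_method[method] = classified
            counts = classified["class"].value_counts().to_dict()
            summary = ann.position_summary(counts)
            summary.insert(0, "method", method)
            summaries.append(summary)
            classified.to_csv(
                out / f"classified_{method}.tsv", sep="\t", index=False
            )
        if summaries:
            pd.concat(summaries, ignore_index=True).to_csv(
                out / "position_summary.tsv", sep="\t", index=False
            )
        if per_method:
            lists, inter = ann.gene_lists(per_method)
            inter.to_csv(out / "gene_intersections.tsv", sep="\t", index=False)
            state["gene_lists"] = lists
            state["gene_intersections"] = inter
        state["position_summaries"] = summaries

    @stage("pascan")
    def _pascan(lg):
        cov = read_coverage(config.coverage)
        bins = pa.call_pa_bins(
            cov, sheet.groups, min_presence_mean=config.min_presence_mean
        )
        regions = pa.merge_pa_regions(bins)
        lg.info("%d P/A bins in %d regions",
                int(bins["is_pa"].sum()), len(regions.regions))
        regions.regions.to_csv(out / "pa_regions.bed", sep="\t",
                               index=False, header=False)
        regions.group_presence.to_csv(out / "pa_group_presence.tsv", sep="\t")
        mask = pa.TEMask(intervals=read_bed(config.te_mask))
        enrich = pa.te_enrichment(
            regions, mask, cov.bins, seed=config.stage_seed("pascan")
        )
        (out / "te_enrichment.json").write_text(json.dumps(enrich, indent=2))
        if regions.group_presence.shape[0] >= 3 and len(regions.regions) >= 2:
            tree, _ = pa.nj_from_pa(
                regions, n_bootstrap=config.n_bootstrap,
                seed=config.stage_seed("pascan"),
            )
            write_newick(tree, out / "nj_groups_pa.nwk")
        state["pa_regions"] = regions
        state["te_enrichment"] = enrich

    @stage("cca")
    @needs("pa_regions", "env_pcs")
    def _cca(lg):
        regions = state["pa_regions"]
        pcs = state["env_pcs"]
        presence = regions.group_presence
        constraints = pcs.scores.reindex(presence.index)
        p, fit = ordination.cca_permutation(
            presence, constraints,
            n_perm=config.n_permutations,
            seed=config.stage_seed("cca"),
        )
        (out / "cca_summary.json").write_text(json.dumps({
            "total_inertia": fit.total_inertia,
            "constrained_fraction": fit.constrained_fraction,
            "constrained_eigenvalues": list(map(float,
                                                fit.constrained_eigenvalues)),
            "permutation_p": p,
        }, indent=2))
        fit.site_scores.to_csv(out / "cca_sites.tsv", sep="\t")
        fit.object_scores.to_csv(out / "cca_objects.tsv", sep="\t")
        fit.constraint_vectors.to_csv(out / "cca_vectors.tsv", sep="\t")
        lg.info("constrained fraction %.3f, p=%.4f", fit.constrained_fraction, p)
        state["cca"] = fit

    @stage("report")
    def _report(lg):
        write_report(state, out / "report.md")

    return out


def _df_md(df: pd.DataFrame, floatfmt: str = "%.4g") -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: floatfmt % v)
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "---|" * len(df.columns)
    rows = ["| " + " | ".join(str(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def write_report(state: dict, path: Path) -> None:
    """Markdown report with the five summary tables."""
    parts = ["# Landscape genomics report", ""]

    parts.append("## Table 1. Geographic distance and pairwise Fst")
    if "fst" in state and "geo_dist" in state:
        parts.append("### Fst (Weir-Cockerham theta)")
        parts.append(_df_md(state["fst"].reset_index()))
        parts.append("### Distance (km)")
        parts.append(_df_md(state["geo_dist"].reset_index()))
        if "mantel" in state:
            rho, p = state["mantel"]
            parts.append(f"\nFst vs distance: Spearman rho={rho:.4f}, p={p:.4f}")
    else:
        parts.append("_not computed_")

    parts.append("\n## Table 2. TE enrichment of P/A regions")
    if "te_enrichment" in state:
        enr = state["te_enrichment"]
        parts.append(_df_md(pd.DataFrame([
            ("whole genome", enr["genome_fraction"]),
            ("P/A bins", enr["pa_fraction"]),
            ("matched non-P/A bins", enr["control_fraction"]),
        ], columns=["set", "masked_fraction"])))
    else:
        parts.append("_not computed_")

    parts.append("\n## Table 3. Association and outlier counts")
    rows = []
    for key, label in (("eas_mlm", "MLM EAS"), ("eas_lfmm", "LFMM EAS")):
        if key in state:
            rows.append((label, int(state[key]["locus"].nunique())))
    if "eas_joint" in state:
        rows.append(("joint EAS", int(state["eas_joint"]["locus"].nunique())))
    if "outlier_summary" in state:
        s = state["outlier_summary"]
        rows.append((f"outliers ({s['percent']}% of loci)", s["n_outliers"]))
    parts.append(_df_md(pd.DataFrame(rows, columns=["set", "count"]))
                 if rows else "_not computed_")

    parts.append("\n## Table 4. Positional enrichment")
    if state.get("position_summaries"):
        parts.append(_df_md(pd.concat(state["position_summaries"],
                                      ignore_index=True)))
    else:
        parts.append("_not computed_")

    parts.append("\n## Table 5. Constrained ordination (CCA)")
    if "cca" in state:
        fit = state["cca"]
        parts.append(_df_md(pd.DataFrame([
            ("total inertia", fit.total_inertia),
            ("constrained fraction", fit.constrained_fraction),
            ("permutation p", fit.permutation_p),
        ], columns=["quantity", "value"])))
    else:
        parts.append("_not computed_")

    path.write_text("\n".join(parts) + "\n")
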