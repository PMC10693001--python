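"""End-to-end driver: consensus -> merge -> filters -> popgen -> phenotypes -> GWAS.

``run_all`` executes the stages in dependency order over a directory of
inputs (the layout written by the synthetic profile or equivalent real
data), writes per-stage outputs plus JSON summaries into the output
directory, and finishes with a run manifest (package/library versions,
seed, config hash) and a consolidated ``report.json``.

Input directory layout::

    chroms.tsv              chromosome name/length table
    calls/<indiv>/<caller>.vcf   per-individual per-caller SV calls
    repeats.bed             repeat track (BED4, class labels)
    genes.gff3              gene annotation
    birds.csv, tracks.csv   phenotype table and daily positions
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import migrasv
from migrasv import gwas as gwas_mod
from migrasv import landscape as landscape_mod
from migrasv import phenotypes as pheno_mod
from migrasv import popgen as popgen_mod
from migrasv.io import (
    GenomeLayout,
    read_bed_repeats,
    read_gff_genes,
    read_phenotype_table,
    read_sv_vcf,
    write_sv_vcf,
)
from migrasv.svmerge import (
    consensus_individual,
    filter_n_runs,
    maf_filter,
    merge_cohort,
)

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger("migrasv")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their documented defaults."""

    # consensus / merge
    max_dist: int = 1000
    min_callers: int = 2
    min_support_individuals: int = 4
    min_size: int = 50
    max_n_run: int = 10
    min_maf: float = 0.05
    # landscape
    window: int = 200_000
    # popgen
    pbs_groups: tuple[str, str, str] = ("NW", "SW", "SE")
    pbs_quantile: float = 0.95
    pca_exclude_chroms: tuple[str, ...] = ()
    # gwas
    gwas_traits: tuple[str, ...] = ("direction",)
    burn_in: int = 3000
    steps: int = 12000
    thin: int = 10
    n_chains: int = 2
    run_pgs: bool = False
    pgs_folds: int = 4
    # global
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pbs_groups", "pca_exclude_chroms", "gwas_traits"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def sha256(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def run_all(config: PipelineConfig, input_dir: str | Path, output_dir: str | Path) -> dict:
    """Run the full chain; returns (and writes) the consolidated report."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    if not logger.handlers:
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    config.to_yaml(output_dir / "config.yaml")
    report: dict = {"stages": {}}
    t_start = time.time()

    def stage(name: str):
        logger.info("stage %s", name)
        return time.time()

    def done(name: str, t0: float, **summary) -> None:
        summary["seconds"] = round(time.time() - t0, 2)
        report["stages"][name] = summary
        _write_json(output_dir / f"stage_{name}.json", summary)

    # ----- inputs -----
    t0 = stage("inputs")
    layout_path = input_dir / "chroms.tsv"
    if not layout_path.exists():
        raise FileNotFoundError(f"missing input: {layout_path}")
    layout = GenomeLayout.from_table(layout_path)
    calls_dir = input_dir / "calls"
    if not calls_dir.is_dir():
        raise FileNotFoundError(f"missing input directory: {calls_dir}")
    individuals = sorted(p.name for p in calls_dir.iterdir() if p.is_dir())
    done("inputs", t0, n_chromosomes=len(layout.names), n_individuals=len(individuals))

    # ----- per-individual consensus -----
    t0 = stage("consensus")
    consensus = {}
    n_raw = n_consensus = 0
    for ind in individuals:
        callsets = {}
        for vcf_path in sorted((calls_dir / ind).glob("*.vcf")):
            try:
                callsets[vcf_path.stem] = read_sv_vcf(vcf_path, caller_label=vcf_path.stem)
            except Exception as exc:
                raise RuntimeError(f"failed to read {vcf_path}: {exc}") from exc
        n_raw += sum(len(v) for v in callsets.values())
        calls = consensus_individual(
            callsets, max_dist=config.max_dist, min_size=config.min_size
        )
        consensus[ind] = filter_n_runs(calls, max_run=config.max_n_run)
    n_consensus = sum(len(v) for v in consensus.values())
    done("consensus", t0, n_raw_calls=n_raw, n_consensus_calls=n_consensus)

    # ----- cohort merge + MAF filter -----
    t0 = stage("merge")
    merged = merge_cohort(
        consensus,
        max_dist=config.max_dist,
        min_support_individuals=config.min_support_individuals,
        min_size=config.min_size,
        chrom_order=layout.names,
    )
    filtered = maf_filter(merged, min_maf=config.min_maf)
    write_sv_vcf(filtered.loci, layout, output_dir / "merged.vcf", sample="cohort")
    locus_table = pd.DataFrame(
        {
            "id": [r.id for r in filtered.loci],
            "chrom": [r.chrom for r in filtered.loci],
            "start": [r.start for r in filtered.loci],
            "end": [r.end for r in filtered.loci],
            "svtype": [r.svtype for r in filtered.loci],
            "length": [r.length for r in filtered.loci],
            "maf": filtered.maf,
        }
    )
    locus_table.to_csv(output_dir / "loci.tsv", sep="\t", index=False)
    done(
        "merge", t0,
        n_merged_loci=merged.n_loci,
        n_after_maf=filtered.n_loci,
    )

    # ----- landscape -----
    t0 = stage("landscape")
    density = landscape_mod.window_density(filtered.loci, layout, window=config.window)
    density.to_csv(output_dir / "window_density.tsv", sep="\t", index=False)
    sizes = landscape_mod.size_spectrum(filtered.loci)
    summary: dict = {"size_spectrum": sizes.summary.to_dict(orient="records")}
    repeats_path = input_dir / "repeats.bed"
    if repeats_path.exists():
        repeats = read_bed_repeats(repeats_path, layout)
        overlap = landscape_mod.repeat_overlap(filtered.loci, repeats)
        summary["repeat_overlap"] = {
            "fraction_overlapping": overlap.fraction_overlapping,
            "class_shares": overlap.class_shares,
        }
    done("landscape", t0, **summary)

    # ----- phenotypes -----
    t0 = stage("phenotypes")
    birds = read_phenotype_table(input_dir / "birds.csv", input_dir / "tracks.csv")
    pheno = pheno_mod.derive_phenotypes(birds)
    pheno.to_csv(output_dir / "phenotypes.csv", index=False)
    groups = dict(zip(pheno["bird_id"], pheno["group"]))
    done("phenotypes", t0, n_birds=len(pheno),
         group_counts=pheno["group"].value_counts().to_dict())

    # ----- popgen -----
    t0 = stage("popgen")
    afs = popgen_mod.folded_afs(merged, popgen_mod.svtype_categories(merged.loci))
    afs_summary = {
        cat: {"n_polymorphic": a.n_polymorphic, "n_monomorphic": a.n_monomorphic_excluded}
        for cat, a in afs.items()
    }
    tajima = popgen_mod.tajimas_d(merged)
    col_of = {name: i for i, name in enumerate(filtered.individuals)}
    group_cols = {
        g: [col_of[b] for b in filtered.individuals if groups.get(b) == g]
        for g in config.pbs_groups
    }
    missing_groups = [g for g, cols in group_cols.items() if len(cols) < 2]
    popgen_summary: dict = {"afs": afs_summary, "tajimas_d": tajima}
    if not missing_groups:
        counts = popgen_mod.allele_counts(filtered, group_cols)
        fst_pairs = {}
        pair_list = [(a, b) for i, a in enumerate(config.pbs_groups)
                     for b in config.pbs_groups[i + 1:]]
        for a, b in pair_list:
            num, den, _ = popgen_mod.hudson_fst(counts[a], counts[b])
            fst_pairs[f"{a}-{b}"] = popgen_mod.fst_genomewide(num, den)
        pbs_result = popgen_mod.pbs(counts)
        pbs_result.frame().to_csv(output_dir / "pbs.tsv", sep="\t", index=False)
        outlier_ids = {}
        for g, values in pbs_result.pbs.items():
            mask = popgen_mod.pbs_outlier_loci(values, config.pbs_quantile)
            outlier_ids[g] = [filtered.loci[int(i)].id
                              for i in pbs_result.locus_index[mask]]
        genes_path = input_dir / "genes.gff3"
        outlier_genes = {}
        if genes_path.exists():
            genes = read_gff_genes(genes_path, layout)
            outlier_genes = popgen_mod.pbs_outlier_genes(
                pbs_result, filtered.loci, genes, config.pbs_quantile
            )
        popgen_summary.update(
            fst_genomewide=fst_pairs,
            pbs_outliers={g: ids for g, ids in outlier_ids.items()},
            pbs_outlier_genes={g: v for g, v in outlier_genes.items()},
            pbs_n_dropped=pbs_result.n_dropped_undefined,
        )
    else:
        popgen_summary["pbs_skipped_missing_groups"] = missing_groups
    pca_res = popgen_mod.pca(filtered, exclude_chroms=set(config.pca_exclude_chroms))
    popgen_summary["pca_top_eigenvalues"] = pca_res.eigenvalues[:5].tolist()
    done("popgen", t0, **popgen_summary)

    # ----- GWAS -----
    t0 = stage("gwas")
    pheno_indexed = pheno.set_index("bird_id").loc[filtered.individuals]
    K = gwas_mod.kinship(filtered)
    gwas_summary = {}
    for ti, trait_name in enumerate(config.gwas_traits):
        if trait_name not in pheno_indexed.columns:
            raise ValueError(f"trait {trait_name!r} not found in phenotype table")
        raw = pheno_indexed[trait_name].to_numpy(dtype=float)
        ok = np.isfinite(raw)
        sub = filtered.subset_individuals(np.flatnonzero(ok).tolist())
        prepared = gwas_mod.prepare_trait(raw[ok], pheno_indexed["sex"].to_numpy()[ok])
        cfg = gwas_mod.BSLMMConfig(
            burn_in=config.burn_in, steps=config.steps, thin=config.thin,
            n_chains=config.n_chains, seed=int(config.seed + 97 * (ti + 1)),
        )
        fit = gwas_mod.bslmm_fit(prepared, sub, K=K[np.ix_(ok.nonzero()[0], ok.nonzero()[0])],
                                 config=cfg)
        per_variant = pd.DataFrame(
            {
                "id": [r.id for r in filtered.loci],
                "pip": fit.pip,
                "beta_bar": fit.beta_bar,
            }
        ).sort_values("pip", ascending=False)
        per_variant.to_csv(output_dir / f"gwas_{trait_name}.tsv", sep="\t", index=False)
        entry = {
            "pve_mean": fit.pve_mean,
            "pve_sd": fit.pve_sd,
            "top_pip": per_variant.head(5)[["id", "pip"]].to_dict(orient="records"),
        }
        if config.run_pgs:
            pgs = gwas_mod.pgs_crossval(
                prepared, sub, K=K[np.ix_(ok.nonzero()[0], ok.nonzero()[0])],
                config=cfg, n_folds=config.pgs_folds, seed=config.seed,
            )
            entry["pgs_r"] = pgs.r
            entry["pgs_p"] = pgs.p_value
        gwas_summary[trait_name] = entry
    done("gwas", t0, **gwas_summary)

    # ----- manifest + report -----
    manifest = {
        "migrasv_version": migrasv.__version__,
        "numpy_version": np.__version__,
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "total_seconds": round(time.time() - t_start, 2),
    }
    _write_json(output_dir / "manifest.json", manifest)
    report["manifest"] = manifest
    _write_json(output_dir / "report.json", report)
    logger.info("pipeline complete in %.1fs", time.time() - t_start)
    return report
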