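"""End-to-end orchestration: filter -> prune -> clones -> ancestry -> DAPC
-> diversity -> FST/outliers/genes -> tree -> LD decay, with the
introgression test run on the unpruned filtered matrix.

The dual-track design matters: population-structure and diversity stages
consume the clone-pruned (non-clonal) subset, while the ABBA-BABA stage
uses the full filtered sample set. One master seed fans out to per-stage
seeds through ``SeedSequence`` so any stage can be reproduced in
isolation. Every run writes per-stage TSVs and a JSON manifest recording
parameters, seeds, input hashes and stage counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, clones, differentiation, diversity, introgression
from . import ld_decay, phylo, qc_filter
from .io_core import (AridpopError, GenotypeMatrix, SampleMeta, read_gff3_genes,
                      read_vcf, write_vcf)

STAGE_ORDER = ["filter", "prune", "clones", "ancestry", "dapc", "diversity",
               "fst", "tree", "lddecay", "dstat"]


class StageError(AridpopError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    out_dir: str
    gff3: str | None = None
    seed: int = 0
    filter: qc_filter.FilterConfig = field(default_factory=qc_filter.FilterConfig)
    prune: qc_filter.PruneConfig = field(default_factory=qc_filter.PruneConfig)
    clone_threshold: float = 0.95
    k_min: int = 1
    k_max: int = 10
    k_replicates: int = 20
    dapc_n_pca: int = 40
    dapc_n_da: int = 3
    fst_window: int = 50_000
    fst_step: int = 10_000
    fst_top_quantile: float = 0.99
    fst_pad: int = 2_500
    dstat_quartets: list[tuple] = field(default_factory=list)
    dstat_block_bp: int = 1_000_000
    tree_bootstraps: int = 1000
    ld_max_dist_bp: int = 300_000
    ld_bin_bp: int = 100
    ld_spline_df: int = 8


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns (and writes) the manifest dict.

    A stage failure raises :class:`StageError` naming the stage after
    writing the partial manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {"vcf": cfg.vcf, "vcf_sha256": _sha256(cfg.vcf)},
        "seed": cfg.seed,
        "parameters": {
            "filter": vars(cfg.filter), "prune": vars(cfg.prune),
            "clone_threshold": cfg.clone_threshold,
            "K_range": [cfg.k_min, cfg.k_max], "K_replicates": cfg.k_replicates,
            "fst_window": cfg.fst_window, "fst_step": cfg.fst_step,
            "fst_top_quantile": cfg.fst_top_quantile, "fst_pad": cfg.fst_pad,
            "tree_bootstraps": cfg.tree_bootstraps,
            "ld_max_dist_bp": cfg.ld_max_dist_bp,
        },
        "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in STAGE_ORDER},
        "counts": {},
    }
    if cfg.gff3:
        manifest["inputs"]["gff3"] = cfg.gff3
        manifest["inputs"]["gff3_sha256"] = _sha256(cfg.gff3)

    def fail(stage: str, e: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise StageError(stage, e) from e

    counts = manifest["counts"]
    # ------------------------------------------------------------ filtering
    try:
        gm = read_vcf(cfg.vcf)
        counts["raw_sites"] = gm.n_sites
        counts["raw_samples"] = gm.n_samples
        report = qc_filter.FilterReport()
        if gm.depth is not None and gm.genoqual is not None:
            gm = qc_filter.mask_genotypes(gm, cfg.filter)
        gm = qc_filter.filter_sites(gm, cfg.filter, report)
        gm, dropped = qc_filter.filter_samples(gm, cfg.filter, report)
        counts["filtered_sites"] = gm.n_sites
        counts["filtered_samples"] = gm.n_samples
        pd.DataFrame(report.to_rows(), columns=["rule", "count"]).to_csv(
            out / "filter_report.tsv", sep="\t", index=False)
        write_vcf(gm, out / "filtered.vcf")
    except AridpopError as e:
        fail("filter", e)

    # -------------------------------------------------------------- pruning
    try:
        keep = qc_filter.ld_prune(gm, cfg.prune)
        pruned = gm.subset_sites(keep)
        counts["pruned_sites"] = pruned.n_sites
        write_vcf(pruned, out / "pruned.vcf")
    except AridpopError as e:
        fail("prune", e)

    # --------------------------------------------------------------- clones
    try:
        rel = clones.pairwise_relatedness(pruned)
        groups = clones.clone_groups(rel, cfg.clone_threshold)
        fmiss = pruned.sample_missing_rate()
        meta = [SampleMeta(sample_id=s, f_miss=float(f))
                for s, f in zip(pruned.sample_ids, fmiss)]
        retained = clones.select_representatives(groups, meta)
        nonclonal = pruned.subset_samples(retained)
        counts["clone_groups_multi"] = sum(1 for g in groups.groups if len(g) > 1)
        counts["nonclonal_samples"] = len(retained)
        rel.pairs.to_csv(out / "relatedness.tsv", sep="\t", index=False)
        pd.DataFrame({
            "sample_id": [m.sample_id for m in meta],
            "f_miss": [m.f_miss for m in meta],
            "clonal_status": [m.clonal_status for m in meta],
        }).to_csv(out / "clones.tsv", sep="\t", index=False)
    except AridpopError as e:
        fail("clones", e)

    # ------------------------------------------------------------- ancestry
    try:
        seed = manifest["stage_seeds"]["ancestry"]
        table, best_k = ancestry.select_K(
            nonclonal, range(cfg.k_min, cfg.k_max + 1),
            replicates=cfg.k_replicates, seed=seed)
        table.to_csv(out / "cross_entropy.tsv", sep="\t", index=False)
        best_row = table[table["K"] == best_k].sort_values("cross_entropy").iloc[0]
        X = ancestry.encode_indicator(nonclonal)
        res = ancestry.snmf_fit(X, best_k, seed=int(best_row["seed"]))
        labels, admixed = ancestry.assign_clusters(res.Q)
        counts["best_K"] = best_k
        qdf = pd.DataFrame(res.Q, columns=[f"Q{k + 1}" for k in range(best_k)])
        qdf.insert(0, "sample_id", nonclonal.sample_ids)
        qdf["cluster"] = labels
        qdf["admixed"] = admixed
        qdf.to_csv(out / "ancestry_Q.tsv", sep="\t", index=False)
    except AridpopError as e:
        fail("ancestry", e)

    # ----------------------------------------------------------------- dapc
    try:
        if best_k >= 2:
            dapc = ancestry.dapc_fit(nonclonal, labels, cfg.dapc_n_pca,
                                     cfg.dapc_n_da)
            post = pd.DataFrame(
                dapc.posteriors,
                columns=[f"post{k + 1}" for k in range(dapc.posteriors.shape[1])])
            post.insert(0, "sample_id", nonclonal.sample_ids)
            post.to_csv(out / "dapc_posteriors.tsv", sep="\t", index=False)
            concord = float(np.mean(
                np.unique(labels)[np.argmax(dapc.posteriors, axis=1)] == labels))
            counts["dapc_concordance"] = concord
    except AridpopError as e:
        fail("dapc", e)

    # ------------------------------------------------------------ diversity
    try:
        if best_k >= 2:
            div = diversity.diversity_table(nonclonal, labels)
            div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    except AridpopError as e:
        fail("diversity", e)

    # ---------------------------------------------------------------- fst
    try:
        if best_k >= 2:
            fst_mat = differentiation.pairwise_fst(nonclonal, labels)
            fst_mat.to_csv(out / "pairwise_fst.tsv", sep="\t")
            genes = read_gff3_genes(cfg.gff3) if cfg.gff3 else []
            uniq = np.unique(labels)
            outlier_rows = []
            for i, g1 in enumerate(uniq):
                for g2 in uniq[i + 1:]:
                    comps = differentiation.wc_components(
                        nonclonal.dosage, labels, (g1, g2))
                    windows = differentiation.windowed_fst(
                        comps, nonclonal.sites, cfg.fst_window, cfg.fst_step)
                    if not windows:
                        continue
                    outl = differentiation.outliers_and_genes(
                        windows, nonclonal.sites, genes,
                        cfg.fst_top_quantile, cfg.fst_pad)
                    outlier_rows.append((g1, g2, outl.threshold_fst,
                                         len(outl.snp_indices), len(outl.genes)))
            pd.DataFrame(outlier_rows, columns=[
                "group_a", "group_b", "threshold_fst", "outlier_snps",
                "outlier_genes"]).to_csv(out / "fst_outliers.tsv", sep="\t",
                                         index=False)
    except AridpopError as e:
        fail("fst", e)

    # ----------------------------------------------------------------- tree
    try:
        tree = phylo.bootstrap_support(nonclonal, cfg.tree_bootstraps,
                                       manifest["stage_seeds"]["tree"])
        phylo.write_newick(tree, out / "tree.nwk")
    except AridpopError as e:
        fail("tree", e)

    # -------------------------------------------------------------- lddecay
    try:
        if best_k >= 2:
            ld = ld_decay.group_ld_curves(nonclonal, labels,
                                          cfg.ld_max_dist_bp, cfg.ld_bin_bp,
                                          cfg.ld_spline_df)
            ld.to_csv(out / "ld_half_decay.tsv", sep="\t", index=False)
    except AridpopError as e:
        fail("lddecay", e)

    # ---------------------------------------------------------------- dstat
    try:
        if cfg.dstat_quartets:
            # introgression runs on the unpruned filtered set, full samples
            group_map: dict[str, list[str]] = {}
            for s, lab in zip(nonclonal.sample_ids, labels):
                group_map.setdefault(str(lab), []).append(s)
            rows = []
            for quartet in cfg.dstat_quartets:
                quartet = tuple(str(x) for x in quartet)
                res = introgression.d_statistic(
                    gm.subset_samples([s for q in quartet for s in group_map[q]]),
                    group_map, quartet, cfg.dstat_block_bp,
                    manifest["stage_seeds"]["dstat"])
                rows.append(res.as_row())
            pd.DataFrame(rows).to_csv(out / "dstat.tsv", sep="\t", index=False)
    except (AridpopError, KeyError) as e:
        fail("dstat", e)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
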