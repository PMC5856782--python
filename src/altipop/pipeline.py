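"""End-to-end pipeline: simulate -> SNP stats -> diversity -> differentiation
-> structure -> expression -> ABC -> meta-analysis, driven by one config and
one seed, with a content-hash manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import differentiation, diversity, expression, meta, structure, variants
from ._rng import stage_seed  # noqa: F401 (re-exported for stage seeding)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("altipop.pipeline")

ALL_STAGES = [
    "simulate", "snpstats", "diversity", "differentiation",
    "structure", "expression", "abc", "meta",
]

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]


@dataclass
class RunConfig:
    """Pipeline run settings: output dir, global seed, stage toggles, parameters."""

    out_dir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulation: Dict = field(default_factory=dict)
    abc_n_sims: int = 5000
    abc_tolerance: float = 0.01
    n_permutations: int = 999
    outlier_quantile: float = 0.99
    lsbl_threshold: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Run the enabled stages; returns the manifest {relative path: sha256}.

    A stage failure aborts the run with the stage named; outputs written so
    far are retained next to a FAILED marker.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: List[str] = []

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> str:
        path = os.path.join(config.out_dir, name)
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        outputs.append(name)
        return path

    def save_text(text: str, name: str) -> str:
        path = os.path.join(config.out_dir, name)
        with open(path, "w") as fh:
            fh.write(text)
        outputs.append(name)
        return path

    enabled = [s for s in ALL_STAGES if s in config.stages]
    state: Dict = {}
    current = None
    try:
        for stage in enabled:
            current = stage
            logger.info("[%s] starting", stage)
            _STAGE_FUNCS[stage](config, state, save_df, save_text)
            logger.info("[%s] done", stage)
    except Exception:
        save_text(f"stage {current} failed\n", "FAILED")
        logger.exception("pipeline aborted at stage %s", current)
        raise
    manifest = {name: _sha256(os.path.join(config.out_dir, name)) for name in outputs}
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump({"seed": config.seed, "stages": enabled, "files": manifest}, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _need_data(config: RunConfig, state: Dict) -> None:
    if "table" not in state:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        (state["table"], state["annotation"], state["design"],
         state["counts"], state["lengths"], state["truth"]) = simulate_dataset(sim)
        state["sim_config"] = sim


def _stage_simulate(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    table, ann, design = state["table"], state["annotation"], state["design"]
    vcf_path = os.path.join(config.out_dir, "variants.vcf")
    contig_lengths = dict(zip(ann.table.transcript_id, ann.table.length))
    variants.write_vcf(table, vcf_path, contig_lengths)
    ann.to_tsv(os.path.join(config.out_dir, "annotation.tsv"))
    ann.write_fasta(os.path.join(config.out_dir, "reference.fasta"))
    design.to_tsv(os.path.join(config.out_dir, "populations.tsv"))
    counts = state["counts"].copy()
    counts.insert(0, "length", state["lengths"])
    counts.to_csv(os.path.join(config.out_dir, "counts.tsv"), sep="\t")
    state["truth"].to_csv(os.path.join(config.out_dir, "de_truth.tsv"), sep="\t", index=False)
    for name in ["variants.vcf", "annotation.tsv", "reference.fasta", "populations.tsv",
                 "counts.tsv", "de_truth.tsv"]:
        save_text(open(os.path.join(config.out_dir, name)).read(), name)


def _stage_snpstats(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    table, ann, design = state["table"], state["annotation"], state["design"]
    save_df(variants.snp_density(table, design, ann), "snp_density.tsv")
    save_df(variants.snp_density(table, design, ann, per_sample=True), "snp_density_per_sample.tsv")
    save_df(variants.spectrum_counts(table, design).reset_index(), "spectrum.tsv")
    venn = variants.private_shared_sets(table, design)
    save_text(json.dumps(venn, indent=2, sort_keys=True) + "\n", "venn_counts.json")
    save_df(variants.coding_effect_table(table, ann, design), "coding_effects.tsv")


def _stage_diversity(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    tab = diversity.diversity_table(state["table"], state["annotation"], state["design"])
    state["diversity"] = tab
    save_df(tab, "diversity.tsv")
    bins = {}
    for lab in state["design"].labels:
        sub = tab[(tab.population == lab) & (tab.unit_id != "genome")]
        try:
            bins[lab] = diversity.d_threshold_bins(sub.tajima_d)
        except ValueError:
            bins[lab] = None
    save_text(json.dumps(bins, indent=2, sort_keys=True) + "\n", "tajima_d_bins.json")


def _stage_differentiation(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    table, design = state["table"], state["design"]
    diff = differentiation.differentiation_table(table, design)
    state["differentiation"] = diff
    save_df(diff, "differentiation.tsv")
    fst_tab = differentiation.pairwise_fst_table(table, design)
    high = design.labels[-1]
    pairs_with_high = [f"fst_{a}-{b}" for a in design.labels for b in design.labels
                       if f"fst_{a}-{b}" in diff.columns and high in (a, b)]
    genes = diff[diff.unit_id != "genome"]
    fst_stat = genes[pairs_with_high].mean(axis=1)
    fst_rank = pd.DataFrame({"unit_id": genes.unit_id, "stat": fst_stat})
    fst_out = differentiation.outlier_genes(fst_rank, "stat", config.outlier_quantile)
    gst_out = differentiation.outlier_genes(genes[["unit_id", "gst"]], "gst", config.outlier_quantile)
    lsbl_sel, n_max = differentiation.select_by_lsbl(
        genes[["unit_id", f"lsbl_{high}"]].rename(columns={}), high, config.lsbl_threshold
    ) if f"lsbl_{high}" in genes.columns else (set(), 0)
    save_text("\n".join(sorted(fst_out)) + "\n", "outliers_fst.txt")
    save_text("\n".join(sorted(gst_out)) + "\n", "outliers_gst.txt")
    save_text("\n".join(sorted(fst_out & gst_out)) + "\n", "outliers_shared.txt")
    save_text("\n".join(sorted(lsbl_sel)) + "\n", f"lsbl_candidates_{high}.txt")
    state["outliers"] = dict(fst=fst_out, gst=gst_out, lsbl=lsbl_sel, lsbl_n_max=n_max)


def _stage_structure(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    table, design = state["table"], state["design"]
    dm = structure.distance_matrix(table)
    save_df(dm.to_dataframe(), "distances.tsv", index=True)
    tree, raw_edges = structure.neighbor_joining(dm)
    save_text(tree.to_newick() + "\n", "nj_tree.nwk")
    save_df(raw_edges, "nj_raw_branch_lengths.tsv")
    pca = structure.genotype_pca(table)
    state["pca"] = pca
    save_df(pca.scores_frame(), "pca_scores.tsv", index=True)
    save_df(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pca.variance_fractions))],
                          "variance_fraction": pca.variance_fractions}), "pca_variance.tsv")
    high = design.labels[-1]
    grouping = {lab: ("high" if lab == high else "low") for lab in design.labels}
    labels = [design.assignment[s] for s in pca.samples]
    stat, p = structure.permutation_test_separation(
        pca.scores, labels, grouping, n_perm=config.n_permutations,
        seed=config.seed,
    )
    state["perm_p"] = p
    save_text(json.dumps({"statistic": stat, "p_value": p, "n_perm": config.n_permutations}) + "\n",
              "permutation_test.json")


def _stage_expression(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    design = state["design"]
    expr = expression.ExpressionMatrix(state["counts"], state["lengths"])
    state["expr"] = expr
    save_df(expr.rpkm().round(4), "rpkm.tsv", index=True)
    labs = design.labels
    pairs = [(labs[i], labs[j]) for i in range(len(labs)) for j in range(i + 1, len(labs))]
    deg_state = {}
    for lo, hi in pairs:
        de = expression.pairwise_de(expr, design, (lo, hi))
        deg_state[f"{lo}-{hi}"] = de
        save_df(de.reset_index(), f"deg_{lo}_{hi}.tsv")
        save_df(expression.volcano_table(de).reset_index(), f"volcano_{lo}_{hi}.tsv")
    state["deg"] = deg_state
    de_genes = set()
    for de in deg_state.values():
        de_genes |= set(de.index[de.call != "ns"])
    if len(de_genes) >= 2:
        _, names, nwk = expression.cluster_samples(expr.rpkm(), sorted(de_genes))
        save_text(nwk + "\n", "expression_dendrogram.nwk")


def _stage_abc(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    table, ann, design = state["table"], state["annotation"], state["design"]
    idx = design.indices(table)
    lengths = ann.table.set_index("transcript_id").length
    per_gene = {}
    for lab in design.labels:
        seg = table.segregating_mask(idx[lab])
        counts = pd.Series(0, index=lengths.index)
        vc = pd.Series(table.transcript_id[seg]).value_counts()
        counts.loc[vc.index] = vc.values
        per_gene[lab] = counts
    per_gene = pd.DataFrame(per_gene)
    observed, names = abc_mod.observed_density_summaries(per_gene, lengths)
    rpkm_mean = expression.ExpressionMatrix(state["counts"], state["lengths"]).rpkm().mean(axis=1)
    model = abc_mod.SnpDensityAbcModel(
        observed, lengths.to_numpy(), rpkm_mean.reindex(lengths.index).to_numpy(),
        pop_labels=design.labels,
    )
    model.config = abc_mod.ABCConfig(
        priors=model.config.priors, n_sims=config.abc_n_sims,
        tolerance_quantile=config.abc_tolerance, seed=config.seed,
    )
    res = model.fit()
    state["abc"] = res
    res.to_tsv(os.path.join(config.out_dir, "abc_posterior.tsv"))
    save_text(open(os.path.join(config.out_dir, "abc_posterior.tsv")).read(), "abc_posterior.tsv")
    prob, flag = res.bifurcation_test()
    save_text(json.dumps({
        "summary": json.loads(res.summary().to_json()),
        "bifurcation_probability": prob, "bifurcation_flag": bool(flag),
    }, indent=2) + "\n", "abc_report.json")


def _stage_meta(config, state, save_df, save_text) -> None:
    _need_data(config, state)
    table, ann, design = state["table"], state["annotation"], state["design"]
    mb = ann.total_covered_bp() / 1e6
    lengths = ann.table.set_index("transcript_id").length
    site_meas: Dict[str, List[np.ndarray]] = {}
    for lab in design.labels:
        vecs = []
        for s in design.samples_for(lab):
            col = table.genotypes[:, table.sample_index([s])[0]]
            carrier = (col == 1) | (col == 2)
            dens = pd.Series(table.transcript_id[carrier]).value_counts()
            per_gene = pd.Series(0.0, index=lengths.index)
            per_gene.loc[dens.index] = dens.values
            vecs.append((per_gene / lengths * 1e6).to_numpy())
        site_meas[lab] = vecs
    partition = meta.randomize_studies(site_meas, n_per_site=9, seed=config.seed)
    altitudes = {"L": 2846.0, "M": 3282.0, "H": 3714.0}
    rows = []
    results = {}
    high = design.labels[-1]
    for site in design.labels:
        if site == design.labels[0]:
            continue
        effects = meta.pseudo_study_effects(partition, site, design.labels[0])
        fit = meta.RandomEffectsMeta(effects).fit()
        results[f"{site}-vs-{design.labels[0]}"] = json.loads(fit.summary().to_json())
        for e in effects:
            rows.append(dict(study=e.study, g=e.g, var_g=e.var_g,
                             moderator=altitudes.get(site, float("nan"))))
    save_df(pd.DataFrame(rows), "meta_effects.tsv")
    save_text(json.dumps(results, indent=2) + "\n", "meta_results.json")
    state["meta"] = results


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "snpstats": _stage_snpstats,
    "diversity": _stage_diversity,
    "differentiation": _stage_differentiation,
    "structure": _stage_structure,
    "expression": _stage_expression,
    "abc": _stage_abc,
    "meta": _stage_meta,
}
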