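"""End-to-end pipeline: simulate → GRM/PCA → adjust → GREML → validate →
SNP effects → AWM → PCIT → prioritize → report.

Each stage writes its artefacts under the output directory and records them
(with SHA-256 hashes) in a run manifest, so a rerun with the same config and
seed reproduces identical hashes for all deterministic stages and any stage
can be resumed from the persisted artefacts of the previous ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import adjust_phenotypes, reml_covariates
from .awm import build_awm, export_network, map_snp_to_genes, pcit
from .config import SimConfig
from .greml import genomic_correlation_across_breeds, run_all_bivariates
from .grm import GRM, compute_grm, compute_pca
from .prioritize import cluster_profiles, family_enrichment, rank_and_select
from .simulate import make_dataset, read_dataset, write_dataset
from .snp_effects import (backsolve_snp_effects, pleiotropy_chi2,
                          standardize_and_test)
from .validate import anova_metrics, run_validation, summarize_validation

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError", "STAGES"]

STAGES = ("simulate", "grm", "adjust", "greml", "validate", "snpfx", "awm",
          "pcit", "prioritize", "report")

_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; completed artefacts are left on disk."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


class _Run:
    """Holds the in-memory artefacts and the manifest while stages run."""

    def __init__(self, cfg: dict, outdir: Path, resume: bool):
        self.cfg = cfg
        self.out = outdir
        self.resume = resume
        self.ctx: dict = {}
        self.manifest = {
            "config": cfg,
            "seed": cfg.get("seed", 0),
            "versions": {"fertnet": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
            "stages": [],
        }

    def record(self, name: str, outputs: list[Path], elapsed: float,
               resumed: bool) -> None:
        self.manifest["stages"].append({
            "name": name,
            "outputs": {str(p.relative_to(self.out)): _sha256(p)
                        for p in outputs},
            "elapsed_s": round(elapsed, 3),
            "resumed": resumed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _sim_config(cfg: dict) -> SimConfig:
    overrides = dict(cfg.get("simulate", {}))
    overrides.setdefault("seed", cfg.get("seed", 0))
    return SimConfig.from_dict(overrides)


# --------------------------------------------------------------------- stages

def _stage_simulate(run: _Run):
    out = run.out / "data"
    scfg = _sim_config(run.cfg)
    if run.resume and (out / "config.yaml").exists():
        ds = read_dataset(out)
        if ds.config.to_dict() == scfg.to_dict():
            run.ctx["ds"] = ds
            return [p for p in sorted(out.iterdir())], True
    ds = make_dataset(scfg)
    write_dataset(ds, out)
    run.ctx["ds"] = ds
    return [p for p in sorted(out.iterdir())], False


def _stage_grm(run: _Run):
    ds = run.ctx["ds"]
    grm_path = run.out / "grm.tsv"
    meta_path = run.out / "grm_meta.json"
    pca_path = run.out / "pca.tsv"
    if run.resume and grm_path.exists() and meta_path.exists() \
            and pca_path.exists():
        mat = pd.read_csv(grm_path, sep="\t", index_col=0)
        meta = json.loads(meta_path.read_text())
        grm = GRM(animal_ids=mat.index.to_numpy(dtype=object),
                  values=mat.to_numpy(),
                  denom=meta["denom"],
                  freqs=np.asarray(meta["freqs"]),
                  snp_ids=np.asarray(meta["snp_ids"], dtype=object))
        pca = pd.read_csv(pca_path, sep="\t", index_col=0)
        run.ctx.update(grm=grm, pca=pca)
        return [grm_path, meta_path, pca_path], True
    grm = compute_grm(ds.genotypes)
    pca = compute_pca(ds.genotypes, k=2, grm=grm)
    pd.DataFrame(grm.values, index=grm.animal_ids,
                 columns=grm.animal_ids).to_csv(
        grm_path, sep="\t", float_format=_FLOAT)
    meta_path.write_text(json.dumps({
        "denom": grm.denom,
        "freqs": [float(f) for f in grm.freqs],
        "snp_ids": [str(s) for s in grm.snp_ids]}))
    pca.to_csv(pca_path, sep="\t", float_format=_FLOAT)
    run.ctx.update(grm=grm, pca=pca)
    return [grm_path, meta_path, pca_path], False


def _stage_adjust(run: _Run):
    ds, pca = run.ctx["ds"], run.ctx["pca"]
    path = run.out / "adjusted_phenotypes.tsv"
    adj = adjust_phenotypes(ds.phenotypes, pca,
                            traits=list(ds.config.traits))
    adj.values.to_csv(path, sep="\t", float_format=_FLOAT)
    (run.out / "adjust_summaries.json").write_text(json.dumps(
        {t: {"r2": s["r2"], "n": s["n"]} for t, s in adj.summaries.items()},
        indent=2))
    breed_labels = pd.Series(ds.genotypes.breed_labels,
                             index=ds.genotypes.animal_ids)
    run.ctx["adj"] = adj
    run.ctx["fixed"] = reml_covariates(breed_labels, pca)
    return [path, run.out / "adjust_summaries.json"], False


def _stage_greml(run: _Run):
    adj, grm = run.ctx["adj"], run.ctx["grm"]
    gcfg = dict(run.cfg.get("greml", {}))
    traits = gcfg.get("traits") or list(adj.values.columns)
    fits, summary, gebv_w = run_all_bivariates(adj, grm, traits=traits,
                                               fixed=run.ctx.get("fixed"))
    paths = [run.out / "greml_summary.tsv", run.out / "gebv_whole.tsv",
             run.out / "greml_fits.tsv"]
    summary.to_csv(paths[0], sep="\t", float_format=_FLOAT)
    gebv_w.to_csv(paths[1], sep="\t", float_format=_FLOAT)
    rows = []
    for (a, b), fit in fits.items():
        rows.append({
            "trait_a": a, "trait_b": b,
            "vg_a": fit.Vg[0, 0], "vg_b": fit.Vg[1, 1],
            "vg_ab": fit.Vg[0, 1],
            "ve_a": fit.Ve[0, 0], "ve_b": fit.Ve[1, 1],
            "ve_ab": fit.Ve[0, 1],
            "h2_a": fit.h2[0], "h2_b": fit.h2[1],
            "rg": fit.rg, "re": fit.re, "loglik": fit.loglik,
            "converged": fit.converged, "n_iter": fit.n_iter,
        })
    pd.DataFrame(rows).to_csv(paths[2], sep="\t", index=False,
                              float_format=_FLOAT)
    run.ctx.update(fits=fits, greml_summary=summary, gebv_w=gebv_w)

    if gcfg.get("across_breed"):
        ds = run.ctx["ds"]
        breed_labels = pd.Series(ds.genotypes.breed_labels,
                                 index=ds.genotypes.animal_ids)
        breeds = list(dict.fromkeys(breed_labels))
        ab_traits = gcfg.get("across_breed_traits") or traits
        rows = []
        for trait in ab_traits:
            for i in range(len(breeds)):
                for j in range(i + 1, len(breeds)):
                    try:
                        est = genomic_correlation_across_breeds(
                            trait, breeds[i], breeds[j], adj, grm,
                            breed_labels)
                        rows.append({
                            "trait": trait, "breed_1": breeds[i],
                            "breed_2": breeds[j],
                            "rg_across": est.rg_across,
                            "converged": est.converged})
                    except ValueError as exc:
                        logger.warning("across-breed %s %s/%s skipped: %s",
                                       trait, breeds[i], breeds[j], exc)
        ab_path = run.out / "across_breed_rg.tsv"
        pd.DataFrame(rows).to_csv(ab_path, sep="\t", index=False,
                                  float_format=_FLOAT)
        paths.append(ab_path)
    return paths, False


def _stage_validate(run: _Run):
    adj, grm, ds = run.ctx["adj"], run.ctx["grm"], run.ctx["ds"]
    vcfg = dict(run.cfg.get("validate", {}))
    schemes = vcfg.get("schemes", [1, 2])
    k = int(vcfg.get("k", 5))
    breed_labels = pd.Series(ds.genotypes.breed_labels,
                             index=ds.genotypes.animal_ids)
    paths = []
    all_results = {}
    for scheme in schemes:
        res = run_validation(adj, grm, breed_labels, scheme=scheme, k=k,
                             seed=int(run.cfg.get("seed", 0)),
                             fixed=run.ctx.get("fixed"))
        p = run.out / f"validation_scheme{scheme}.tsv"
        res.to_csv(p, sep="\t", index=False, float_format=_FLOAT)
        paths.append(p)
        summ = summarize_validation(res)
        ps = run.out / f"validation_summary_scheme{scheme}.tsv"
        summ.to_csv(ps, sep="\t", float_format=_FLOAT)
        paths.append(ps)
        anova = anova_metrics(res)
        pa = run.out / f"validation_anova_scheme{scheme}.json"
        pa.write_text(json.dumps(anova, indent=2))
        paths.append(pa)
        all_results[scheme] = res
    run.ctx["validation"] = all_results
    return paths, False


def _stage_snpfx(run: _Run):
    ds, grm, gebv_w = run.ctx["ds"], run.ctx["grm"], run.ctx["gebv_w"]
    scfg = dict(run.cfg.get("snpfx", {}))
    lam = float(scfg.get("lambda", 0.85))
    alpha = float(scfg.get("alpha", 0.01))
    raw = backsolve_snp_effects(ds.genotypes, grm, gebv_w, lam=lam)
    effects = standardize_and_test(raw, alpha=alpha)
    pleiotropy_chi2(effects)
    path = run.out / "snp_effects.tsv"
    out = effects.z.copy()
    out["n_assoc"] = effects.n_assoc
    out["chi2"] = effects.chi2
    out["chi2_p"] = effects.chi2_p
    out.to_csv(path, sep="\t", float_format=_FLOAT)
    run.ctx["effects"] = effects
    return [path], False


def _stage_awm(run: _Run):
    ds, effects = run.ctx["ds"], run.ctx["effects"]
    acfg = dict(run.cfg.get("awm", {}))
    window = int(acfg.get("window", 10000))
    assignments = map_snp_to_genes(ds.genotypes.snp_map, ds.gene_map,
                                   window=window)
    awm = build_awm(effects, assignments, ds.genotypes.snp_map,
                    key_trait=acfg.get("key_trait", "PNS"),
                    alpha=float(acfg.get("alpha", 0.01)))
    path = run.out / "awm.tsv"
    awm.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT)
    run.ctx.update(awm=awm, assignments=assignments)
    return [path], False


def _stage_pcit(run: _Run):
    net = pcit(run.ctx["awm"])
    paths = export_network(net, run.out, prefix="network")
    run.ctx["net"] = net
    return list(paths.values()), False


def _stage_prioritize(run: _Run):
    ds, awm, net, effects = (run.ctx["ds"], run.ctx["awm"], run.ctx["net"],
                             run.ctx["effects"])
    pcfg = dict(run.cfg.get("prioritize", {}))
    top_k = int(pcfg.get("top_k", 10))
    tf_set = set(ds.gene_map.loc[ds.gene_map["tf_flag"].astype(bool),
                                 "gene_id"])
    chi2_gene = pd.Series(
        effects.chi2.reindex(awm.table["snp_id"]).to_numpy(),
        index=awm.table["gene_id"])
    expr = ds.sperm_expr.set_index("gene_id")["abundance"]
    ranks = rank_and_select(net, chi2_gene, expr, tf_set, top_k=top_k)
    paths = [run.out / "tf_ranks.tsv", run.out / "enrichment.json"]
    ranks.to_csv(paths[0], sep="\t", index=False, float_format=_FLOAT)

    fam_label = ds.config.family_label
    family = set(ds.gene_map.loc[ds.gene_map["family"] == fam_label,
                                 "gene_id"])
    enr_p = family_enrichment(set(awm.gene_ids), family, len(ds.gene_map))
    paths[1].write_text(json.dumps({
        "family": fam_label, "family_size": len(family),
        "awm_size": len(awm.gene_ids),
        "captured": len(set(awm.gene_ids) & family),
        "genome_size": len(ds.gene_map),
        "p_value": enr_p}, indent=2))

    selected = ranks.loc[ranks["selected"], "gene_id"].tolist()
    if len(selected) >= 2:
        prof = awm.values.loc[selected]
        clus = cluster_profiles(prof)
        pc = run.out / "profile_clusters.json"
        pc.write_text(json.dumps({
            "row_order": clus.row_order, "col_order": clus.col_order,
            "row_clusters": {k: int(v)
                             for k, v in clus.row_clusters.items()},
            "col_clusters": {k: int(v)
                             for k, v in clus.col_clusters.items()},
        }, indent=2))
        paths.append(pc)
    run.ctx["ranks"] = ranks
    return paths, False


def _stage_report(run: _Run):
    lines = ["pipeline summary", "================"]
    ds = run.ctx["ds"]
    lines.append(f"animals: {ds.genotypes.n_animals}  "
                 f"snps: {ds.genotypes.m_snps}  "
                 f"breeds: {len(set(ds.genotypes.breed_labels))}")
    if "greml_summary" in run.ctx:
        h2 = np.diag(run.ctx["greml_summary"].to_numpy())
        lines.append("mean bivariate h2 per trait: "
                     + ", ".join(f"{t}={v:.2f}" for t, v in
                                 zip(run.ctx["greml_summary"].index, h2)))
    if "net" in run.ctx:
        lines.append(f"network: {len(run.ctx['net'].nodes)} genes, "
                     f"{run.ctx['net'].n_edges} edges")
    if "ranks" in run.ctx:
        sel = int(run.ctx["ranks"]["selected"].sum())
        lines.append(f"selected TFs (any top-10 criterion): {sel}")
    path = run.out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return [path], False


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "grm": _stage_grm,
    "adjust": _stage_adjust,
    "greml": _stage_greml,
    "validate": _stage_validate,
    "snpfx": _stage_snpfx,
    "awm": _stage_awm,
    "pcit": _stage_pcit,
    "prioritize": _stage_prioritize,
    "report": _stage_report,
}


def run_pipeline(
    config,
    outdir=None,
    seed: int | None = None,
    upto: str | None = None,
    resume: bool = True,
) -> Path:
    """Run the pipeline (optionally up to a named stage); returns the output
    directory containing all artefacts and ``manifest.json``.

    ``config`` is a YAML path or a dict; ``seed``/``outdir`` override the
    config's values.  On a stage failure a :class:`PipelineError` naming the
    stage is raised and the completed artefacts remain on disk.
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir or cfg.get("outdir", "fertnet_run"))
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    run = _Run(cfg, out, resume)
    stages = STAGES[:STAGES.index(upto) + 1] if upto else STAGES
    for name in stages:
        t0 = time.time()
        try:
            outputs, resumed = _STAGE_FUNCS[name](run)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        run.record(name, outputs, time.time() - t0, resumed)
        logger.info("stage %-10s done (%.1fs)%s", name, time.time() - t0,
                    " [resumed]" if resumed else "")
    return out
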