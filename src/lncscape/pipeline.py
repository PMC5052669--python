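"""End-to-end landscape run: filter -> SSEA (two contrasts) -> clustering
and labelling -> intersection -> binding/induction annotation ->
prioritization -> concept associations -> survival, from one declarative
config, with a machine-readable manifest and bit-reproducible outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import intervals as iv_mod
from . import landscape as ls_mod
from . import ssea as ssea_mod
from .expression import ExpressionMatrix, expression_filter, log2_fold_over_reference, read_matrix
from .survival import ExpressionStratifiedKM, read_survival

__all__ = ["RunConfig", "run_landscape", "write_report", "STAGES"]

STAGES = ["filter", "ssea_cancer", "ssea_er", "cluster", "intersect",
          "prioritize", "associate", "survival"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration for one landscape run.

    All thresholds default to the landscape's printed operating points:
    FDR < 1e-5 at percentile 0.975, expression filter 1 FPKM at the 0.95
    quantile, top-150 correlation signatures, the methods network preset,
    and 10/1 FPKM survival cuts.
    """
    matrix_path: str = ""
    models_path: str = ""
    annotations_path: str = ""
    peaks_path: str | None = None
    induction_path: str | None = None
    concepts_path: str | None = None
    survival_path: str | None = None
    outdir: str = "landscape_run"
    seed: int = 0
    n_permutations: int = 1000
    fdr_cutoff: float = 1e-5
    percentile_q: float = 0.975
    filter_q: float = 0.95
    filter_min_fpkm: float = 1.0
    n_clusters: int = 3
    n_top_candidates: int = 10
    signature_n: int = 150
    network_preset: str = "methods"
    survival_high_cut: float = 10.0
    survival_low_cut: float = 1.0
    target_id: str | None = None
    log2fc_pseudocount: float = 0.1
    promoter_mode: str = "symmetric"
    promoter_upstream_bp: int = 5000
    promoter_downstream_bp: int = 5000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key {sorted(unknown)[0]!r}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("matrix_path", "models_path", "annotations_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError("validate", f"{name} missing or does not exist: {p!r}")
        for name in ("peaks_path", "induction_path", "concepts_path", "survival_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{name} does not exist: {p!r}")
        if self.network_preset not in ("methods", "figure"):
            raise PipelineError("validate", f"unknown network preset {self.network_preset!r}")


def _stage_seed(seed: int, stage: str) -> int:
    # recorded fan-out: global seed plus the stage's fixed index
    return (seed * 1009 + STAGES.index(stage)) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    models = pd.read_csv(config.models_path, sep="\t", dtype={"transcript_id": str}
                         ).set_index("transcript_id")
    ann = pd.read_csv(config.annotations_path, sep="\t", dtype={"sample_id": str}
                      ).set_index("sample_id")
    for col in ("cohort", "er_status", "pam50"):
        if col not in ann.columns:
            raise PipelineError("validate", f"annotation column {col!r} missing")
    matrix = read_matrix(config.matrix_path,
                         transcripts=models[["length_bp", "biotype"]], samples=ann)
    return matrix, models, ann


def run_landscape(config: RunConfig) -> Path:
    """Execute the full landscape pipeline; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": [], "outputs": {}}

    def record(stage: str, outputs: dict, **info):
        entry = {"stage": stage, "seed": _stage_seed(config.seed, stage), **info}
        entry["outputs"] = {}
        for key, path in outputs.items():
            entry["outputs"][key] = {"path": str(path), "sha256": _sha256(Path(path))}
            manifest["outputs"][key] = str(path)
        manifest["stages"].append(entry)

    matrix, models, ann = _load_inputs(config)
    counts = matrix if matrix.unit == "counts" else None
    fpkm = matrix.to_fpkm() if matrix.unit == "counts" else matrix

    # stage: expression filter (lncRNAs only enter the DE landscape)
    try:
        kept = expression_filter(fpkm, q=config.filter_q, min_fpkm=config.filter_min_fpkm)
        lnc = [t for t in kept
               if matrix.transcripts is not None
               and matrix.transcripts.loc[t, "biotype"] == "lncRNA"]
        if not lnc:
            raise ValueError("no lncRNA transcript passes the expression filter")
        path = outdir / "filtered_transcripts.tsv"
        pd.DataFrame({"transcript_id": lnc}).to_csv(path, sep="\t", index=False)
        record("filter", {"filtered_transcripts": path},
               n_kept=len(kept), n_lncrna=len(lnc))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # stage: SSEA contrasts
    def run_contrast(stage: str, sub_matrix, sub_fpkm, set_name, member_mask):
        try:
            sset = ssea_mod.SampleSet(set_name,
                                      sub_matrix.sample_ids[member_mask])
            params = ssea_mod.SseaParams(n_permutations=config.n_permutations,
                                         seed=_stage_seed(config.seed, stage))
            res = ssea_mod.SSEA(sub_matrix, sset, params,
                                percentile_q=config.percentile_q,
                                percentile_matrix=sub_fpkm,
                                fdr_cutoff=config.fdr_cutoff,
                                min_percentile_value=config.filter_min_fpkm).fit()
            path = outdir / f"{stage}.tsv"
            res.write(path)
            record(stage, {stage: path}, sample_set=set_name,
                   n_significant=int(res.table["significant"].sum()))
            return res
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    lnc_counts = (counts or matrix).subset(transcript_ids=lnc)
    lnc_fpkm = fpkm.subset(transcript_ids=lnc)
    tumor_mask = (ann["cohort"] == "tumor").to_numpy()
    res_cancer = run_contrast("ssea_cancer", lnc_counts, lnc_fpkm,
                              "tumor_vs_normal", tumor_mask)

    tumor_ids = list(ann.index[tumor_mask])
    er_ann = ann.loc[tumor_ids]
    er_mask = (er_ann["er_status"] == "positive").to_numpy()
    res_er = run_contrast("ssea_er", lnc_counts.subset(sample_ids=tumor_ids),
                          lnc_fpkm.subset(sample_ids=tumor_ids),
                          "er_pos_vs_neg", er_mask)

    # stage: clustering and labelling of the cancer-DE lncRNAs
    try:
        de_cancer = res_cancer.significant_ids()
        normals = list(ann.index[ann["cohort"] == "normal"])
        cluster_outputs = {}
        labels_map: dict = {}
        if len(de_cancer) >= 2 and normals:
            log2fc = log2_fold_over_reference(fpkm.subset(transcript_ids=de_cancer),
                                              normals, config.log2fc_pseudocount)
            tr_clust = ls_mod.hierarchical_cluster(log2fc, axis="rows")
            k = min(config.n_clusters, len(de_cancer))
            tr_labels = tr_clust.cut(k)
            labels_map = ls_mod.label_lncrna_clusters(log2fc, tr_labels, ann)
            sm_clust = ls_mod.hierarchical_cluster(
                log2fc[[s for s in log2fc.columns if s in set(tumor_ids)]],
                axis="columns")
            out = pd.DataFrame({"cluster": tr_labels,
                                "category": tr_labels.map(labels_map)})
            path = outdir / "lncrna_clusters.tsv"
            out.rename_axis("transcript_id").to_csv(path, sep="\t")
            nwk_t = outdir / "dendrogram_transcripts.nwk"
            nwk_t.write_text(tr_clust.newick() + "\n", encoding="utf-8")
            nwk_s = outdir / "dendrogram_samples.nwk"
            nwk_s.write_text(sm_clust.newick() + "\n", encoding="utf-8")
            cluster_outputs = {"lncrna_clusters": path,
                               "dendrogram_transcripts": nwk_t,
                               "dendrogram_samples": nwk_s}
        record("cluster", cluster_outputs, n_de_cancer=len(de_cancer),
               labels={str(k): v for k, v in labels_map.items()})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc

    # stage: intersection of the up-regulated DE sets
    try:
        up_cancer = res_cancer.significant_ids("+")
        up_er = res_er.significant_ids("+")
        both, venn = ls_mod.intersect_de_sets(up_cancer, up_er)
        path = outdir / "intersection.tsv"
        pd.DataFrame({"transcript_id": both}).to_csv(path, sep="\t", index=False)
        record("intersect", {"intersection": path}, venn=venn)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("intersect", str(exc)) from exc

    # stage: binding flags, induction folds and candidate prioritization
    try:
        tmodels = [iv_mod.TranscriptModel(str(t), r["chrom"], int(r["tss"]),
                                          str(r["strand"]), int(r["length_bp"]))
                   for t, r in models.iterrows()]
        if config.peaks_path:
            peaks = iv_mod.read_bed(config.peaks_path)
            flags = iv_mod.promoter_binding_flags(
                tmodels, peaks, mode=config.promoter_mode,
                upstream_bp=config.promoter_upstream_bp,
                downstream_bp=config.promoter_downstream_bp)
            binding = flags.to_frame("chip")
        else:
            binding = pd.DataFrame({"chip": pd.Series(False, index=models.index)})
        if config.induction_path:
            ind = pd.read_csv(config.induction_path, sep="\t",
                              dtype={"transcript_id": str}).set_index("transcript_id")
            folds = (ind["fold"] if "fold" in ind.columns
                     else ind["estrogen"] / ind["vehicle"])
        else:
            folds = pd.Series(dtype=float)
        bpath = outdir / "binding_flags.tsv"
        binding.rename_axis("transcript_id").to_csv(bpath, sep="\t")
        cand = ls_mod.prioritize_candidates(both, fpkm, binding, folds,
                                            n_top=config.n_top_candidates)
        path = outdir / "candidates.tsv"
        cand.to_csv(path, sep="\t", index=False)
        record("prioritize", {"binding_flags": bpath, "candidates": path},
               n_bound=int(binding.any(axis=1).sum()), n_candidates=len(cand))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("prioritize", str(exc)) from exc

    # stage: guilt-by-association network for the top candidate
    try:
        target = config.target_id or (cand["transcript_id"].iloc[0] if len(cand) else None)
        assoc_outputs = {}
        n_edges = 0
        if target is not None and config.concepts_path:
            er_pos = set(ann.index[(ann["cohort"] == "tumor") &
                                   (ann["er_status"] == "positive")])
            ranked = assoc_mod.spearman_correlations(fpkm, target,
                                                     sample_filter=lambda s: s in er_pos)
            pos_sig, neg_sig = assoc_mod.top_signatures(ranked, n=config.signature_n,
                                                        name=target)
            concepts = assoc_mod.read_gmt(config.concepts_path)
            # universe = genes measured in the matrix (ranked); concept sets
            # are truncated to it so every test shares one gene space
            universe = set(ranked["gene_id"])
            assocs = []
            for cname in sorted(concepts):
                genes = tuple(g for g in concepts[cname] if g in universe)
                if not genes:
                    continue
                cset = assoc_mod.GeneSignature(cname, genes, "unsigned", "library")
                for sig in (pos_sig, neg_sig):
                    assocs.append(assoc_mod.fisher_overlap(sig, cset, universe))
            preset = (assoc_mod.METHODS_PRESET if config.network_preset == "methods"
                      else assoc_mod.FIGURE_PRESET)
            nodes, edges = assoc_mod.concept_network(assocs, preset)
            n_edges = len(edges)
            apath = outdir / "associations.tsv"
            pd.DataFrame([dataclasses.asdict(a) for a in assocs]).to_csv(
                apath, sep="\t", index=False)
            npath, epath = outdir / "network_nodes.tsv", outdir / "network_edges.tsv"
            nodes.to_csv(npath, sep="\t", index=False)
            edges.to_csv(epath, sep="\t", index=False)
            assoc_outputs = {"associations": apath, "network_nodes": npath,
                             "network_edges": epath}
        record("associate", assoc_outputs, target=target, n_edges=n_edges)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("associate", str(exc)) from exc

    # stage: expression-stratified survival for the target
    try:
        surv_outputs = {}
        surv_info: dict = {}
        if target is not None and config.survival_path:
            surv = read_survival(config.survival_path)
            km = ExpressionStratifiedKM(fpkm.values.loc[target], surv[["time", "event"]],
                                        high_cut=config.survival_high_cut,
                                        low_cut=config.survival_low_cut).fit()
            path = outdir / "survival_test.tsv"
            pd.DataFrame([{"target": target, "chi2": km.chi2, "p": km.p_value}]
                         ).to_csv(path, sep="\t", index=False)
            cpath = outdir / "km_curves.tsv"
            pd.concat({g: c for g, c in km.curves.items()},
                      names=["group"]).reset_index(level=0).to_csv(
                cpath, sep="\t", index=False)
            surv_outputs = {"survival_test": path, "km_curves": cpath}
            surv_info = {"chi2": km.chi2, "p": km.p_value}
        record("survival", surv_outputs, target=target, **surv_info)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return outdir


def write_report(run_dir) -> Path:
    """Summarize a completed run: DE counts, Venn counts, candidate table,
    network edge count and the survival test."""
    run_dir = Path(run_dir)
    mpath = run_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}; run incomplete")
    manifest = json.loads(mpath.read_text(encoding="utf-8"))
    stages = {s["stage"]: s for s in manifest["stages"]}
    missing = [s for s in STAGES if s not in stages]
    if missing:
        raise ValueError(f"run incomplete: stage {missing[0]!r} missing")
    lines = ["# Landscape run report", ""]
    lines.append(f"- transcripts passing expression filter (lncRNA): "
                 f"{stages['filter']['n_lncrna']}")
    lines.append(f"- DE lncRNAs, cancer vs normal: "
                 f"{stages['ssea_cancer']['n_significant']}")
    lines.append(f"- DE lncRNAs, ER+ vs ER-: {stages['ssea_er']['n_significant']}")
    venn = stages["intersect"]["venn"]
    lines.append(f"- up-regulated intersection: {venn['both']} "
                 f"(cancer only {venn['a_only']}, ER only {venn['b_only']})")
    labels = stages["cluster"].get("labels", {})
    if labels:
        lines.append(f"- lncRNA cluster categories: "
                     f"{', '.join(f'{k}:{v}' for k, v in sorted(labels.items()))}")
    lines.append(f"- concept network edges: {stages['associate']['n_edges']}")
    if "p" in stages["survival"]:
        lines.append(f"- survival log-rank p for {stages['survival']['target']}: "
                     f"{stages['survival']['p']:.4g}")
    cpath = run_dir / "candidates.tsv"
    if cpath.exists():
        cand = pd.read_csv(cpath, sep="\t")
        lines.append("")
        lines.append("## Top candidates")
        lines.append("")
        lines.append(cand.to_string(index=False) if len(cand)
                     else "(intersection empty; no candidates)")
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return report
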