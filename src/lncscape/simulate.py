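"""Synthetic breast-cohort generator with known planted truth.

Every downstream stage of the landscape analysis is exercised against
cohorts generated here: negative-binomial RNA-seq counts with
library-size variation, planted PAM50 subtype blocks, planted
cancer-vs-normal and ER-status differential lncRNAs (with an overlapping
"both" subset), planted ER-bound promoters, a planted estrogen-induction
experiment, concept libraries with exact overlap counts, and survival
times with a planted hazard ratio.

Count model
-----------
``counts[g, s] ~ NB(mean = baseline_g * fold(g, s) * lib_s / median(lib),
dispersion)`` with a gamma-Poisson parameterization: dispersion ``a`` is
the per-transcript overdispersion (variance ``m + a m^2``); ``a = 0``
degenerates to Poisson. Library sizes are log-uniform over the configured
range; baselines are log-normal, rescaled so expected sample totals match
the middle of the library-size range; a configurable fraction of lncRNAs
is set near zero to exercise the expression filter.

Planted expression patterns
---------------------------
* subtype markers: up ``fold_change``-fold in tumors of one subtype;
* cancer-DE lncRNAs, three patterns: ``up`` (all tumors), ``down`` (all
  tumors), ``luminal`` (LumA/LumB tumors only);
* ER-DE lncRNAs: up in ER-positive (modelled as down in ER-negative
  tumors so they are ER-specific, not cancer-wide) or up in ER-negative
  ("basal" pattern);
* an overlap subset carries both the cancer (luminal pattern) and the
  ER-positive effect; its first member is the designated best candidate —
  highest baseline, ER-bound promoter, strong planted induction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GeneSignature, write_gmt
from .expression import ExpressionMatrix, write_matrix
from .intervals import GenomicInterval, TranscriptModel, write_bed
from .survival import group_by_expression, write_survival

__all__ = [
    "CohortConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_concept_library",
    "simulate_chip_peaks",
    "simulate_induction",
    "simulate_survival",
    "transcript_models",
    "prepare_landscape_run",
    "write_cohort",
    "DEFAULT_SUBTYPE_PROPORTIONS",
    "DEFAULT_CONCEPT_PLAN",
]

DEFAULT_SUBTYPE_PROPORTIONS = {
    "LumA": 0.35, "LumB": 0.20, "Her2": 0.15, "Basal": 0.25, "Normal": 0.05,
}

# Planted overlap counts (signature size 150, concept size 150): large
# counts pass the network presets by a wide margin, small ones fail.
DEFAULT_CONCEPT_PLAN = {
    "concept_pass_a": 30, "concept_pass_b": 20, "concept_pass_c": 12,
    "concept_border": 5, "concept_weak": 2, "concept_null": 0,
}

_CHROMS = tuple(f"chr{i}" for i in range(1, 11))
_TSS_SPACING = 300_000


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""
    n_tumor: int = 150
    n_normal: int = 50
    er_pos_fraction: float = 0.75
    subtype_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS))
    n_transcripts: int = 1000
    lncrna_fraction: float = 0.5
    n_de_cancer: int = 60
    n_de_er: int = 40
    fold_change: float = 4.0
    nb_dispersion: float = 0.2
    library_size_range: tuple = (5e5, 2e6)
    transcript_length_range: tuple = (500, 5000)
    seed: int = 0
    # secondary structure knobs (defaults are the study conditions)
    de_cancer_pattern_fractions: tuple = (0.4, 0.3, 0.3)  # up, down, luminal
    n_de_overlap: int = 10
    n_subtype_markers: int = 25
    lncrna_silent_fraction: float = 0.2
    er_prob_luminal: float = 0.95
    survival_hr: float = 3.0
    concept_overlap_plan: dict = field(default_factory=lambda: dict(DEFAULT_CONCEPT_PLAN))

    def validate(self) -> None:
        if self.n_tumor + self.n_normal <= 0:
            raise ConfigError("cohort has zero samples")
        if self.n_transcripts <= 0:
            raise ConfigError("cohort has zero transcripts")
        tot = sum(self.subtype_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"subtype proportions sum to {tot}, not 1")
        if not 0 <= self.er_pos_fraction <= 1:
            raise ConfigError("er_pos_fraction must be in [0, 1]")
        if self.fold_change <= 0:
            raise ConfigError("fold_change must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        for name in ("library_size_range", "transcript_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ConfigError(f"{name} must satisfy 0 < min <= max")
        n_lnc = int(round(self.n_transcripts * self.lncrna_fraction))
        if self.n_de_cancer > n_lnc or self.n_de_er > n_lnc:
            raise ConfigError("n_de_* exceeds number of lncRNA transcripts")
        if abs(sum(self.de_cancer_pattern_fractions) - 1.0) > 1e-9:
            raise ConfigError("de_cancer_pattern_fractions must sum to 1")
        n_lum = int(round(self.n_de_cancer * self.de_cancer_pattern_fractions[2]))
        if self.n_de_overlap > min(n_lum, self.n_de_er) and self.n_de_cancer > 0:
            raise ConfigError("n_de_overlap exceeds the luminal-pattern or ER-DE count")


@dataclass
class SimTruth:
    """Planted ground truth for one generated cohort."""
    de_cancer_ids: dict = field(default_factory=dict)   # id -> '+' / '-'
    de_er_ids: dict = field(default_factory=dict)       # id -> '+' / '-'
    cancer_pattern: dict = field(default_factory=dict)  # id -> up/down/luminal
    subtype_marker_ids: dict = field(default_factory=dict)
    bound_promoter_ids: set = field(default_factory=set)
    induced_ids: dict = field(default_factory=dict)     # id -> true fold
    concept_overlap_plan: dict = field(default_factory=dict)
    survival_hr: float = 1.0
    best_candidate_id: str | None = None
    target_correlated_ids: tuple | None = None

    def validate(self, transcript_ids) -> None:
        known = set(transcript_ids)
        for name, ids in (("de_cancer_ids", self.de_cancer_ids),
                          ("de_er_ids", self.de_er_ids),
                          ("induced_ids", self.induced_ids)):
            unknown = set(ids) - known
            if unknown:
                raise ConfigError(f"{name}: unknown id {sorted(unknown)[0]!r}")
        for d in (self.de_cancer_ids, self.de_er_ids):
            bad = {v for v in d.values()} - {"+", "-"}
            if bad:
                raise ConfigError(f"invalid direction {bad.pop()!r}")
        if self.bound_promoter_ids - known:
            raise ConfigError("bound_promoter_ids contains unknown transcripts")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["bound_promoter_ids"] = sorted(self.bound_promoter_ids)
        d["target_correlated_ids"] = (list(self.target_correlated_ids)
                                      if self.target_correlated_ids else None)
        return json.dumps(d, indent=2, sort_keys=True)


def _split_counts(total: int, fractions) -> list[int]:
    raw = [total * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in rema[: total - sum(counts)]:
        counts[i] += 1
    return counts


def simulate_cohort(config: CohortConfig):
    """Generate (counts, models, annotations, truth) for one cohort.

    Deterministic for a given config: same config and seed give
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_s = config.n_transcripts, config.n_tumor + config.n_normal

    # -- transcripts and genomic models ------------------------------------
    width = max(4, len(str(n_t)))
    tids = np.array([f"T{i:0{width}d}" for i in range(n_t)])
    n_lnc = int(round(n_t * config.lncrna_fraction))
    lnc_idx = rng.choice(n_t, size=n_lnc, replace=False)
    biotype = np.full(n_t, "protein_coding", dtype=object)
    biotype[lnc_idx] = "lncRNA"
    lo, hi = config.transcript_length_range
    lengths = rng.integers(int(lo), int(hi) + 1, size=n_t)
    chroms = np.array([_CHROMS[i % len(_CHROMS)] for i in range(n_t)])
    rank_on_chrom = np.arange(n_t) // len(_CHROMS)
    tss = _TSS_SPACING * (rank_on_chrom + 1)
    strand = np.where(np.arange(n_t) % 2 == 0, "+", "-")
    start = np.where(strand == "+", tss, tss - lengths)
    models = pd.DataFrame({
        "transcript_id": tids, "chrom": chroms, "start": start,
        "end": start + lengths, "strand": strand, "tss": tss,
        "length_bp": lengths, "biotype": biotype,
    }).set_index("transcript_id")

    # -- samples -----------------------------------------------------------
    sids = np.array([f"S{i:04d}" for i in range(n_s)])
    cohort = np.array(["tumor"] * config.n_tumor + ["normal"] * config.n_normal)
    subtypes = sorted(config.subtype_proportions)
    counts_per = _split_counts(config.n_tumor,
                               [config.subtype_proportions[s] for s in subtypes])
    pam50 = np.full(n_s, "NA", dtype=object)
    tumor_labels = np.repeat(subtypes, counts_per)
    pam50[: config.n_tumor] = rng.permutation(tumor_labels)
    is_tumor = cohort == "tumor"
    is_luminal = np.isin(pam50, ("LumA", "LumB")) & is_tumor
    f_lum = is_luminal.sum() / max(config.n_tumor, 1)
    p_nonlum = 0.0
    if f_lum < 1:
        p_nonlum = (config.er_pos_fraction - config.er_prob_luminal * f_lum) / (1 - f_lum)
    p_nonlum = min(max(p_nonlum, 0.02), 0.9)
    u = rng.random(n_s)
    er = np.where(is_luminal, u < config.er_prob_luminal, u < p_nonlum)
    er_status = np.where(is_tumor, np.where(er, "positive", "negative"), "NA")
    u2 = rng.random(n_s)
    pr_status = np.where(is_tumor,
                         np.where(u2 < np.where(er, 0.8, 0.15), "positive", "negative"),
                         "NA")
    u3 = rng.random(n_s)
    her2_status = np.where(is_tumor,
                           np.where(u3 < np.where(pam50 == "Her2", 0.8, 0.15),
                                    "positive", "negative"), "NA")
    annotations = pd.DataFrame({
        "sample_id": sids, "cohort": cohort, "pam50": pam50,
        "er_status": er_status, "pr_status": pr_status, "her2_status": her2_status,
    }).set_index("sample_id")

    # -- planted truth ------------------------------------------------------
    truth = SimTruth(survival_hr=config.survival_hr,
                     concept_overlap_plan=dict(config.concept_overlap_plan))
    fold = np.ones((n_t, n_s))
    fc = config.fold_change
    is_er_pos = (er_status == "positive")
    is_er_neg = is_tumor & ~is_er_pos

    pc_idx = np.setdiff1d(np.arange(n_t), lnc_idx)
    pool_pc = rng.permutation(pc_idx)
    cursor = 0
    for subtype in subtypes:
        take = pool_pc[cursor: cursor + config.n_subtype_markers]
        cursor += config.n_subtype_markers
        truth.subtype_marker_ids[subtype] = [str(t) for t in tids[take]]
        in_subtype = is_tumor & (pam50 == subtype)
        fold[np.ix_(take, np.flatnonzero(in_subtype))] *= fc

    pool_lnc = rng.permutation(lnc_idx)
    n_up, n_down, n_lum = _split_counts(config.n_de_cancer,
                                        config.de_cancer_pattern_fractions)
    up_ids = pool_lnc[:n_up]
    down_ids = pool_lnc[n_up: n_up + n_down]
    lum_ids = pool_lnc[n_up + n_down: n_up + n_down + n_lum]
    rest_lnc = pool_lnc[n_up + n_down + n_lum:]
    for idx, pattern, direction in ((up_ids, "up", "+"), (down_ids, "down", "-"),
                                    (lum_ids, "luminal", "+")):
        for t in tids[idx]:
            truth.de_cancer_ids[str(t)] = direction
            truth.cancer_pattern[str(t)] = pattern
    fold[np.ix_(up_ids, np.flatnonzero(is_tumor))] *= fc
    fold[np.ix_(down_ids, np.flatnonzero(is_tumor))] /= fc
    fold[np.ix_(lum_ids, np.flatnonzero(is_luminal))] *= fc

    overlap_ids = lum_ids[: config.n_de_overlap]
    n_er_rest = config.n_de_er - len(overlap_ids)
    n_er_down = int(round(n_er_rest * 0.3))
    er_only_up = rest_lnc[: n_er_rest - n_er_down]
    er_down = rest_lnc[n_er_rest - n_er_down: n_er_rest]
    for t in tids[overlap_ids]:
        truth.de_er_ids[str(t)] = "+"
    for t in tids[er_only_up]:
        truth.de_er_ids[str(t)] = "+"
    for t in tids[er_down]:
        truth.de_er_ids[str(t)] = "-"
    # ER-specific (not cancer-wide): relative to ER-positive, ER-negative
    # tumors are depleted (up ids) or enriched (down ids)
    fold[np.ix_(er_only_up, np.flatnonzero(is_er_neg))] /= fc
    fold[np.ix_(er_down, np.flatnonzero(is_er_neg))] *= fc

    # -- baselines and counts ----------------------------------------------
    base_raw = rng.lognormal(mean=0.0, sigma=1.2, size=n_t)
    silent = rng.random(n_t) < config.lncrna_silent_fraction
    silent &= np.isin(np.arange(n_t), lnc_idx)
    silent[np.concatenate([up_ids, down_ids, lum_ids, er_only_up, er_down])] = False
    base_raw[silent] *= 1e-3
    lib_lo, lib_hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=n_s))
    target_total = math.exp((math.log(lib_lo) + math.log(lib_hi)) / 2)
    baseline = base_raw / base_raw.sum() * target_total
    if len(overlap_ids):
        # Designated best candidate: near-silent baseline (~0.3 FPKM, below
        # the survival low cut) and high across the ER-positive tumors,
        # with a fold large enough that its 95th-percentile expression tops
        # every other DE-up lncRNA — the bimodal, ER-restricted profile of
        # a top ER-driven lncRNA.
        best_i = int(overlap_ids[0])
        len_kb = lengths.astype(float) / 1000.0
        baseline[best_i] = 0.3 * len_kb[best_i] * target_total / 1e6
        rivals = np.concatenate([up_ids, lum_ids])
        rivals = rivals[rivals != best_i]
        rival_peak = (baseline[rivals] * fc / len_kb[rivals]).max() if len(rivals) else 1.0
        best_fold = 3.0 * rival_peak / (baseline[best_i] / len_kb[best_i])
        fold[best_i, :] = 1.0
        fold[best_i, np.flatnonzero(is_er_pos)] = best_fold
        truth.best_candidate_id = str(tids[best_i])
        truth.bound_promoter_ids.add(truth.best_candidate_id)
        bound_extra = overlap_ids[1::2]
        truth.bound_promoter_ids.update(str(t) for t in tids[bound_extra])
        folds_cycle = [2.0, 1.2, 2.8, 1.0, 2.2, 1.4]
        truth.induced_ids[truth.best_candidate_id] = 3.0
        for j, t in enumerate(tids[overlap_ids[1:]]):
            truth.induced_ids[str(t)] = folds_cycle[j % len(folds_cycle)]
    mean = baseline[:, None] * fold * (lib / np.median(lib))[None, :]
    if config.nb_dispersion == 0:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean * config.nb_dispersion)
        counts = rng.poisson(lam)
    values = pd.DataFrame(counts.astype(float), index=pd.Index(tids, name="transcript_id"),
                          columns=sids)
    matrix = ExpressionMatrix(values, "counts",
                              transcripts=models[["length_bp", "biotype"]],
                              samples=annotations)
    truth.validate(tids)
    return matrix, models, annotations, truth


def transcript_models(models: pd.DataFrame) -> list[TranscriptModel]:
    """Convert the transcript table to TranscriptModel records."""
    return [TranscriptModel(str(tid), row["chrom"], int(row["tss"]),
                            str(row["strand"]), int(row["length_bp"]))
            for tid, row in models.iterrows()]


def simulate_concept_library(truth: SimTruth, universe, n_concepts: int | None = None,
                             seed: int = 0, concept_size: int = 150) -> list[GeneSignature]:
    """Concept gene sets with exact planted overlap against the designated
    correlated gene set (``truth.target_correlated_ids``).

    Each planned concept draws exactly its planted count from the target
    set and the remainder uniformly (without replacement) from the rest of
    the universe. Concepts beyond the plan get planted overlap 0 and are
    added to the plan. Infeasible plans raise.
    """
    if truth.target_correlated_ids is None:
        raise ConfigError("truth.target_correlated_ids is not set")
    rng = np.random.default_rng(seed)
    target = sorted(set(truth.target_correlated_ids))
    uni = sorted(set(universe))
    if not set(target) <= set(uni):
        raise ConfigError("target correlated set must be inside the universe")
    rest = sorted(set(uni) - set(target))
    plan = dict(truth.concept_overlap_plan)
    if n_concepts is not None:
        for i in range(len(plan), n_concepts):
            plan[f"concept_rand_{i}"] = 0
    out = []
    for name in sorted(plan):
        k = plan[name]
        if k > concept_size or k > len(target) or concept_size - k > len(rest):
            raise ConfigError(f"concept {name!r}: planted overlap {k} infeasible")
        inside = list(rng.choice(target, size=k, replace=False)) if k else []
        outside = list(rng.choice(rest, size=concept_size - k, replace=False))
        out.append(GeneSignature(name, tuple(sorted(inside + outside)),
                                 "unsigned", "synthetic"))
    truth.concept_overlap_plan = plan
    return out


def simulate_chip_peaks(models, truth: SimTruth, peak_width: int = 400,
                        seed: int = 0, upstream_bp: int = 5000,
                        n_decoys: int = 100) -> list[GenomicInterval]:
    """ER ChIP peaks: one peak wholly inside the promoter of every planted
    bound transcript, plus decoy peaks >= 100 kb from any TSS."""
    if peak_width <= 0:
        raise ConfigError("peak_width must be > 0")
    if peak_width + 100 > upstream_bp:
        raise ConfigError(f"promoter window ({upstream_bp} bp) too small for "
                          f"peak_width {peak_width}")
    if isinstance(models, pd.DataFrame):
        models = transcript_models(models)
    by_id = {m.id: m for m in models}
    rng = np.random.default_rng(seed)
    peaks = []
    for i, tid in enumerate(sorted(truth.bound_promoter_ids)):
        m = by_id[tid]
        off = int(rng.integers(50, upstream_bp - peak_width - 49))
        if m.strand == "+":
            start = m.tss - off - peak_width
        else:
            start = m.tss + off
        start = max(0, start)
        peaks.append(GenomicInterval(m.chrom, start, start + peak_width, ".",
                                     f"peak_bound_{i}"))
    tss_by_chrom: dict[str, np.ndarray] = {}
    for m in models:
        tss_by_chrom.setdefault(m.chrom, [])
    for m in models:
        tss_by_chrom[m.chrom].append(m.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    chrom_names = sorted(tss_by_chrom)
    spans = {c: int(tss_by_chrom[c].max()) + 2 * _TSS_SPACING for c in chrom_names}
    placed = 0
    tries = 0
    while placed < n_decoys and tries < 100_000:
        tries += 1
        c = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(0, spans[c] - peak_width))
        t = tss_by_chrom[c]
        j = np.searchsorted(t, pos)
        near = min([abs(pos - t[jj]) for jj in (j - 1, j) if 0 <= jj < t.size] +
                   [abs(pos + peak_width - t[jj]) for jj in (j - 1, j) if 0 <= jj < t.size])
        if near >= 100_000:
            peaks.append(GenomicInterval(c, pos, pos + peak_width, ".",
                                         f"peak_decoy_{placed}"))
            placed += 1
    if placed < n_decoys:
        raise ConfigError("could not place decoy peaks >= 100 kb from all TSS")
    return peaks


def simulate_induction(truth: SimTruth, noise_sd: float = 0.05,
                       seed: int = 0) -> pd.DataFrame:
    """Vehicle / estrogen / estrogen+tamoxifen expression for the planted
    induced transcripts.

    The estrogen/vehicle ratio is centred on the planted fold
    (multiplicative log-normal noise); tamoxifen reverts three quarters of
    the induction toward vehicle.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = 10.0
    rows = []
    for tid in sorted(truth.induced_ids):
        f = truth.induced_ids[tid]
        noise = np.exp(rng.normal(0.0, noise_sd, size=2)) if noise_sd > 0 else np.ones(2)
        estrogen = base * f * noise[0]
        tam = base * (1 + 0.25 * (f - 1)) * noise[1]
        rows.append({"transcript_id": tid, "vehicle": base, "estrogen": estrogen,
                     "estrogen_tamoxifen": tam, "fold": estrogen / base})
    return pd.DataFrame(rows, columns=["transcript_id", "vehicle", "estrogen",
                                       "estrogen_tamoxifen", "fold"]).set_index("transcript_id")


def simulate_survival(annotations: pd.DataFrame, expression_of_target: pd.Series,
                      truth: SimTruth, seed: int = 0,
                      baseline_hazard: float = 1 / 60.0,
                      max_follow_up: float = 120.0) -> pd.DataFrame:
    """Exponential survival with the planted hazard ratio between the
    high (> 10 FPKM) and other expression groups; independent uniform
    censoring over (0, max_follow_up]."""
    if truth.survival_hr <= 0:
        raise ConfigError("survival_hr must be > 0")
    rng = np.random.default_rng(seed)
    expr = expression_of_target.reindex(annotations.index)
    if expr.isna().any():
        raise ConfigError("expression_of_target does not cover all samples")
    groups = group_by_expression(expr)
    hazard = np.where(groups == "high", baseline_hazard * truth.survival_hr,
                      baseline_hazard)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.uniform(0.0, max_follow_up, size=len(hazard))
    time = np.minimum(event_t, censor_t)
    time = np.maximum(time, 1e-6)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"time": time, "event": event, "group": groups.to_numpy()},
                        index=annotations.index.rename("sample_id"))


def prepare_landscape_run(outdir, config: CohortConfig, n_permutations: int = 200,
                          n_concepts: int = 12, concept_size: int = 40):
    """Generate and write every input the full pipeline needs.

    The concept library is planted against the *measured* top-150
    positively correlated signature of the designated best candidate, so
    the network stage's planted truth holds exactly for the generated
    cohort. Returns ``(RunConfig, SimTruth)``.
    """
    from .association import spearman_correlations, top_signatures
    from .pipeline import RunConfig

    matrix, models, ann, truth = simulate_cohort(config)
    if truth.best_candidate_id is None:
        raise ConfigError("config plants no overlap candidate; nothing to target")
    fpkm = matrix.to_fpkm()
    target = truth.best_candidate_id
    peaks = simulate_chip_peaks(models, truth, seed=config.seed + 1)
    induction = simulate_induction(truth, noise_sd=0.05, seed=config.seed + 2)
    er_pos = set(ann.index[(ann["cohort"] == "tumor") & (ann["er_status"] == "positive")])
    ranked = spearman_correlations(fpkm, target, sample_filter=lambda s: s in er_pos)
    pos_sig, _ = top_signatures(ranked, n=min(150, len(ranked) // 2), name=target)
    truth.target_correlated_ids = pos_sig.genes
    universe = list(ranked["gene_id"])
    concepts = simulate_concept_library(truth, universe, n_concepts=n_concepts,
                                        seed=config.seed + 3, concept_size=concept_size)
    survival = simulate_survival(ann, fpkm.values.loc[target], truth,
                                 seed=config.seed + 4)
    paths = write_cohort(outdir, matrix, models, ann, truth, peaks=peaks,
                         concepts=concepts, induction=induction, survival=survival)
    run_config = RunConfig(
        matrix_path=paths["matrix"], models_path=paths["models"],
        annotations_path=paths["annotations"], peaks_path=paths["peaks"],
        induction_path=paths["induction"], concepts_path=paths["concepts"],
        survival_path=paths["survival"], outdir=str(Path(outdir) / "run"),
        seed=config.seed, n_permutations=n_permutations,
        # desk-scale FDR operating point: a permutation FDR of 1e-5 is not
        # resolvable from a few hundred permutations at n ~ 200 samples
        fdr_cutoff=0.05,
        signature_n=min(150, len(ranked) // 2))
    return run_config, truth


def write_cohort(outdir, matrix: ExpressionMatrix, models: pd.DataFrame,
                 annotations: pd.DataFrame, truth: SimTruth,
                 peaks=None, concepts=None, induction=None, survival=None) -> dict:
    """Write all generated artifacts as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": outdir / "counts.tsv", "models": outdir / "transcripts.tsv",
             "annotations": outdir / "samples.tsv", "truth": outdir / "truth.json"}
    write_matrix(matrix, paths["matrix"])
    models.to_csv(paths["models"], sep="\t")
    annotations.to_csv(paths["annotations"], sep="\t")
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    if peaks is not None:
        paths["peaks"] = outdir / "peaks.bed"
        write_bed(peaks, paths["peaks"])
    if concepts is not None:
        paths["concepts"] = outdir / "concepts.gmt"
        write_gmt({c.name: c.genes for c in concepts}, paths["concepts"])
    if induction is not None:
        paths["induction"] = outdir / "induction.tsv"
        induction.to_csv(paths["induction"], sep="\t")
    if survival is not None:
        paths["survival"] = outdir / "survival.tsv"
        write_survival(survival, paths["survival"])
    return {k: str(v) for k, v in paths.items()}
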