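"""Guilt-by-association analysis for a target transcript.

Because most lncRNAs are absent from the clinically annotated microarray
platforms, clinical relevance is inferred transitively: rank all
protein-coding genes by Spearman correlation to the target (within the
relevant samples, e.g. ER-positive tumors), take the top-150 positively
and negatively correlated signatures, and test their overlap against
published clinical concept gene sets with a one-sided Fisher's exact
test. Passing associations are exported as a concept network; the full
ranked list additionally feeds a weighted preranked GSEA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from . import ssea as _ssea

__all__ = [
    "GeneSignature",
    "ConceptAssociation",
    "ConceptStudy",
    "NetworkPreset",
    "METHODS_PRESET",
    "FIGURE_PRESET",
    "spearman_correlations",
    "top_signatures",
    "fisher_overlap",
    "best_variant_association",
    "concept_network",
    "preranked_gsea",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named, optionally directed gene list."""
    name: str
    genes: tuple
    direction: str = "unsigned"  # up | down | unsigned
    source: str = ""

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")
        if self.direction not in ("up", "down", "unsigned"):
            raise ValueError(f"invalid direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ConceptAssociation:
    """2x2 overlap between a correlation signature and a concept set."""
    signature: str
    concept: str
    a: int  # overlap
    b: int  # signature only
    c: int  # concept only
    d: int  # neither
    odds_ratio: float
    p_one_sided: float
    sign: str = "positive"           # positive | negative association
    chosen_variant: str | None = None
    zero_cell_corrected: bool = False

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ConceptStudy:
    """A clinical study offering up/down gene-list variants at several
    percent cutoffs (e.g. top 1/5/10% up- and downregulated genes)."""
    name: str
    variants: dict  # (direction, percent) -> tuple of gene ids


def spearman_correlations(m: ExpressionMatrix, target_id: str,
                          sample_filter=None, biotype: str | None = "protein_coding",
                          ) -> pd.DataFrame:
    """Spearman rho of every (protein-coding) gene against the target.

    Rho is Pearson correlation on mid-ranks (average ranks for ties),
    computed over the filtered samples. Returns a DataFrame with columns
    ``gene_id`` and ``rho``, sorted by rho descending (ties by gene id);
    the target itself is excluded.
    """
    if target_id not in m.transcript_ids:
        raise KeyError(f"target {target_id!r} not in matrix")
    sample_ids = list(m.sample_ids)
    if sample_filter is not None:
        sample_ids = [s for s in sample_ids if sample_filter(s)]
    if len(sample_ids) < 3:
        raise ValueError("sample filter leaves fewer than 3 samples")
    target = m.values.loc[target_id, sample_ids].to_numpy(float)
    if np.ptp(target) == 0:
        raise ValueError(f"target {target_id!r} is constant over the selected samples; "
                         "rho undefined")
    genes = m.transcript_ids
    if biotype is not None:
        if m.transcripts is None or "biotype" not in m.transcripts:
            raise ValueError("biotype filter requested but matrix has no biotype metadata")
        genes = genes[(m.transcripts["biotype"] == biotype).to_numpy()]
    genes = [g for g in genes if g != target_id]
    sub = m.values.loc[genes, sample_ids]
    ranks = sub.rank(axis=1, method="average").to_numpy(float)
    tr = pd.Series(target).rank(method="average").to_numpy(float)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    tc = tr - tr.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1)) * np.sqrt((tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rc @ tc / np.where(denom > 0, denom, 1.0), np.nan)
    out = pd.DataFrame({"gene_id": genes, "rho": rho}).dropna()
    return (out.sort_values(["rho", "gene_id"], ascending=[False, True], kind="stable")
            .reset_index(drop=True))


def top_signatures(ranked: pd.DataFrame, n: int = 150, name: str = "target",
                   ) -> tuple[GeneSignature, GeneSignature]:
    """Top-n positively and top-n negatively correlated gene signatures.

    Boundary ties resolve by gene id (ascending), the same recorded rule
    used by :func:`spearman_correlations` sorting.
    """
    if len(ranked) < 2 * n:
        raise ValueError(f"need >= {2 * n} ranked genes, have {len(ranked)}")
    pos = ranked.sort_values(["rho", "gene_id"], ascending=[False, True], kind="stable")
    neg = ranked.sort_values(["rho", "gene_id"], ascending=[True, True], kind="stable")
    return (GeneSignature(f"{name}_pos", tuple(pos["gene_id"].head(n)), "up", name),
            GeneSignature(f"{name}_neg", tuple(neg["gene_id"].head(n)), "down", name))


def fisher_overlap(sig: GeneSignature, concept: GeneSignature, universe,
                   ) -> ConceptAssociation:
    """One-sided (enrichment) Fisher's exact test of signature/concept
    overlap within a gene universe.

    p is the hypergeometric upper tail P(X >= a); the odds ratio gets a
    Haldane-Anscombe +0.5 on all cells iff any cell is zero (flagged).
    """
    uni = set(universe)
    s, c = set(sig.genes), set(concept.genes)
    if not s <= uni:
        raise ValueError(f"signature {sig.name!r} not a subset of the universe")
    if not c <= uni:
        raise ValueError(f"concept {concept.name!r} not a subset of the universe")
    a = len(s & c)
    b = len(s) - a
    cc = len(c) - a
    d = len(uni) - a - b - cc
    p = float(stats.hypergeom.sf(a - 1, len(uni), len(c), len(s)))
    corrected = min(a, b, cc, d) == 0
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (cc + 0.5))
    else:
        odds = (a * d) / (b * cc)
    sign = "positive" if sig.direction != "down" else "negative"
    return ConceptAssociation(sig.name, concept.name, a, b, cc, d,
                              float(odds), min(p, 1.0), sign=sign,
                              zero_cell_corrected=corrected)


def best_variant_association(sig: GeneSignature, study: ConceptStudy, universe,
                             percents=(1, 5, 10), directions=("up", "down"),
                             ) -> ConceptAssociation | None:
    """Evaluate every (direction, percent) concept variant of a study
    against the signature and keep the greatest odds ratio.

    Ties resolve by smaller p, then smaller percent. Empty variants are
    skipped with a warning; None when no variant is usable.
    """
    best = None
    best_key = None
    for direction in directions:
        for pct in percents:
            genes = study.variants.get((direction, pct))
            if not genes:
                warnings.warn(f"study {study.name!r}: empty variant {direction} {pct}%")
                continue
            concept = GeneSignature(f"{study.name}_{direction}_{pct}pct",
                                    tuple(genes), direction, study.name)
            assoc = fisher_overlap(sig, concept, universe)
            key = (-assoc.odds_ratio, assoc.p_one_sided, pct)
            if best is None or key < best_key:
                assoc.chosen_variant = f"{direction}_{pct}pct"
                best, best_key = assoc, key
    return best


@dataclass(frozen=True)
class NetworkPreset:
    """Thresholds for admitting a concept association into the network."""
    or_threshold_pos: float
    or_threshold_neg: float
    p_threshold: float
    name: str = ""


#: Thresholds used to nominate concepts (OR > 6 positive, > 4 negative, p < 1e-6).
METHODS_PRESET = NetworkPreset(6.0, 4.0, 1e-6, name="methods")
#: Thresholds of the displayed network figure (OR > 6 both sides, p < 1e-4).
FIGURE_PRESET = NetworkPreset(6.0, 6.0, 1e-4, name="figure")


def concept_network(associations, preset: NetworkPreset = METHODS_PRESET,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter associations into node/edge tables for network export.

    An edge passes iff its odds ratio strictly exceeds the sign-matched
    threshold and p is strictly below the p threshold. Node size is the
    gene-set size; edge weight is the odds ratio. Layout is left to the
    consumer (e.g. Cytoscape).
    """
    edges = []
    nodes: dict[str, dict] = {}
    for assoc in associations:
        thr = (preset.or_threshold_pos if assoc.sign == "positive"
               else preset.or_threshold_neg)
        if assoc.odds_ratio > thr and assoc.p_one_sided < preset.p_threshold:
            edges.append({"source": assoc.signature, "target": assoc.concept,
                          "odds_ratio": assoc.odds_ratio, "p": assoc.p_one_sided,
                          "sign": assoc.sign, "variant": assoc.chosen_variant or ""})
            nodes.setdefault(assoc.signature, {"node": assoc.signature,
                                               "size": assoc.a + assoc.b})
            nodes.setdefault(assoc.concept, {"node": assoc.concept,
                                             "size": assoc.a + assoc.c})
    edge_df = pd.DataFrame(edges, columns=["source", "target", "odds_ratio",
                                           "p", "sign", "variant"])
    node_df = pd.DataFrame(list(nodes.values()), columns=["node", "size"])
    return node_df, edge_df


def preranked_gsea(ranked: pd.DataFrame, gene_sets: dict, weight: float = 1.0,
                   n_permutations: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Weighted preranked GSEA of gene sets against a rho-ranked list.

    The running sum walks the ranked genes (descending rho): members add
    ``|rho|^weight`` (normalized over members), non-members subtract
    ``1/(N-k)``. Significance is by gene-label permutation — random
    member sets of the same size, seeded — with NES, nominal p and pooled
    FDR q computed as in the sample-set engine. Genes absent from the
    ranking are dropped with a warning; sets empty after intersection are
    skipped.
    """
    rho = ranked["rho"].to_numpy(float)
    order = np.argsort(-rho, kind="stable")
    rho_sorted = rho[order]
    gene_pos = {g: i for i, g in enumerate(ranked["gene_id"].to_numpy()[order])}
    n = len(gene_pos)
    rng = np.random.default_rng(seed)
    rows = []
    es_list, null_list = [], []
    for set_name in sorted(gene_sets):
        genes = gene_sets[set_name]
        present = [g for g in genes if g in gene_pos]
        if len(present) < len(set(genes)):
            warnings.warn(f"gene set {set_name!r}: "
                          f"{len(set(genes)) - len(present)} gene(s) not in ranking dropped")
        if not present or len(present) >= n:
            warnings.warn(f"gene set {set_name!r} skipped (empty or full after intersection)")
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        es = _ssea._es_batch(rho_sorted, mask[None, :], weight)[0]
        membership = _ssea._null_membership(n, len(present), n_permutations, rng)
        null = _ssea._es_batch(rho_sorted, membership, weight)
        rows.append({"gene_set": set_name, "n_genes": len(present), "es": float(es),
                     "p_nominal": _ssea.nominal_p(es, null),
                     "nes": _ssea.normalize_es(es, null)})
        es_list.append(es)
        null_list.append(null)
    table = pd.DataFrame(rows, columns=["gene_set", "n_genes", "es", "nes", "p_nominal"])
    if len(table):
        table["fdr_q"] = _ssea.fdr_q(table["nes"].to_numpy(),
                                     _ssea._normalize_null(np.vstack(null_list)))
    else:
        table["fdr_q"] = []
    return table.set_index("gene_set")


# -- GMT I/O ---------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT gene-set library: name <tab> description <tab> genes..."""
    sets = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            if f[0] in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene set {f[0]!r}")
            sets[f[0]] = tuple(g for g in f[2:] if g)
    return sets


def write_gmt(gene_sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")
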