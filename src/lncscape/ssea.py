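"""Sample Set Enrichment Analysis (SSEA): permutation-based differential
expression for RNA-seq without distributional assumptions.

For every transcript, the samples are ranked by expression (descending)
and a weighted Kolmogorov-Smirnov running sum asks whether a labelled
sample set (e.g. the tumors, or the ER-positive tumors) concentrates at
the top or bottom of the ranking:

* stepping on a member adds ``|x|^p / sum_members |x|^p``,
* stepping on a non-member subtracts ``1 / (N - |set|)``,

and the enrichment score (ES) is the running-sum value of maximal
absolute deviation, signed. ES is +1 (-1) exactly when the members occupy
the top (bottom) ``|set|`` ranks with positive weight.

Significance comes from a permutation null: random sample sets of the
same size (label shuffling), 1,000 by default. The nominal p-value is the
sign-matched relative rank of the observed ES among the null ES, the
normalized enrichment score (NES) divides ES by the mean magnitude of the
same-sign null ES, and FDR Q values compare each observed NES against the
null NES of *all* transcripts pooled, in the GSEA manner, separately per
sign and monotonized.

The model-object entry point is :class:`SSEA`; ``SSEA(...).fit()`` returns
an :class:`SSEAResults` carrying the per-transcript table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ExpressionMatrixError, percentile_expression

__all__ = [
    "SampleSet",
    "SseaParams",
    "SSEA",
    "SSEAResults",
    "normalize_counts",
    "enrichment_score",
    "permutation_null",
    "nominal_p",
    "normalize_es",
    "fdr_q",
    "run_ssea",
]


@dataclass(frozen=True)
class SampleSet:
    """A named, proper, non-empty subset of the samples."""
    name: str
    member_ids: frozenset

    def __init__(self, name: str, member_ids):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "member_ids", frozenset(member_ids))
        if not self.member_ids:
            raise ValueError(f"sample set {name!r} is empty")

    def mask(self, sample_ids) -> np.ndarray:
        ids = list(sample_ids)
        missing = self.member_ids - set(ids)
        if missing:
            raise ValueError(f"sample set {self.name!r} member {sorted(missing)[0]!r} "
                             "not in matrix")
        m = np.array([s in self.member_ids for s in ids], dtype=bool)
        if m.all():
            raise ValueError(f"sample set {self.name!r} must be a proper subset "
                             "(complement is empty)")
        return m


@dataclass
class SseaParams:
    """Tuning knobs for an SSEA run.

    weight_exponent
        GSEA-style weight ``p`` on |expression| (default 1, the weighted
        scheme; 0 gives the classic unweighted KS statistic).
    n_permutations
        Size of the permutation null per transcript (default 1000).
    seed
        Seed for the shared permutation matrix and the tie-break shuffle.
    normalization
        ``"cpm"`` (counts per million, applied to counts matrices) or
        ``"none"``.
    min_null_support
        Minimum number of same-sign null ES required to normalize an ES
        into an NES; below it the NES (and hence q) is reported missing.
        Guards against wildly inflated NES when one tail of the
        permutation null is nearly empty, which happens for transcripts
        whose expression concentrates in a few samples.
    """
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    normalization: str = "cpm"
    min_null_support: int = 10

    def __post_init__(self):
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.normalization not in ("cpm", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def normalize_counts(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million scaling per sample (library-size normalization)."""
    if m.unit != "counts":
        raise ExpressionMatrixError("normalize_counts expects a counts matrix")
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ExpressionMatrixError(f"sample {bad!r} has zero total counts")
    return m.copy_with(m.values.div(totals, axis=1) * 1e6)


# -- running-sum core ------------------------------------------------------

def _es_batch(values_sorted: np.ndarray, membership_sorted: np.ndarray,
              weight_exponent: float) -> np.ndarray:
    """ES for each row of a membership matrix against one sorted profile.

    values_sorted : (N,) expression in rank order (descending).
    membership_sorted : (R, N) boolean membership in the same order.
    """
    n = values_sorted.size
    k = membership_sorted.sum(axis=1)
    if np.any((k < 1) | (k >= n)):
        raise ValueError("set size must be in [1, N-1]")
    w = np.abs(values_sorted) ** weight_exponent
    mw = membership_sorted * w
    denom = mw.sum(axis=1)
    zero = denom == 0  # all member values zero with p > 0: fall back to equal weights
    if zero.any():
        mw[zero] = membership_sorted[zero].astype(float)
        denom[zero] = k[zero]
    steps = mw / denom[:, None] - (~membership_sorted) / (n - k)[:, None]
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def _sort_order(values: np.ndarray, tie_key: np.ndarray) -> np.ndarray:
    # descending by value; ties broken by a seeded random key (recorded rule)
    return np.lexsort((tie_key, -values))


def enrichment_score(values, sample_set_mask, weight_exponent: float = 1.0,
                     tie_key: np.ndarray | None = None):
    """ES and running-sum profile for one transcript.

    Parameters
    ----------
    values : array-like, per-sample expression.
    sample_set_mask : boolean array, membership of the tested sample set.
    tie_key : optional array used to break expression ties (defaults to
        sample index, i.e. stable order).

    Returns
    -------
    (es, running) where ``running`` is the full running-sum profile in
    rank order.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(sample_set_mask, dtype=bool)
    if v.size < 2:
        raise ValueError("enrichment_score requires at least 2 samples")
    if v.shape != m.shape:
        raise ValueError("values and mask shapes differ")
    if tie_key is None:
        tie_key = np.arange(v.size)
    order = _sort_order(v, tie_key)
    vs, ms = v[order], m[order][None, :]
    n, k = v.size, int(m.sum())
    if not 1 <= k <= n - 1:
        raise ValueError("set size must be in [1, N-1]")
    w = np.abs(vs) ** weight_exponent
    mw = ms[0] * w
    denom = mw.sum()
    if denom == 0:
        mw = ms[0].astype(float)
        denom = k
    running = np.cumsum(mw / denom - (~ms[0]) / (n - k))
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _null_membership(n_samples: int, set_size: int, n_permutations: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_permutations, n_samples) boolean matrix of random same-size sets."""
    if not 1 <= set_size <= n_samples - 1:
        raise ValueError("set_size must be in [1, N-1]")
    keys = rng.random((n_permutations, n_samples))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    m = np.zeros((n_permutations, n_samples), dtype=bool)
    np.put_along_axis(m, idx, True, axis=1)
    return m


def permutation_null(values, set_size: int, weight_exponent: float = 1.0,
                     n_permutations: int = 1000, seed: int = 0,
                     membership: np.ndarray | None = None,
                     tie_key: np.ndarray | None = None) -> np.ndarray:
    """Null ES vector from uniform-random sample sets of ``set_size``.

    A precomputed ``membership`` matrix may be supplied so the same
    permutations are reused across transcripts (required for coherent
    pooled-null FDR).
    """
    v = np.asarray(values, dtype=float)
    if membership is None:
        membership = _null_membership(v.size, set_size, n_permutations,
                                      np.random.default_rng(seed))
    if tie_key is None:
        tie_key = np.arange(v.size)
    order = _sort_order(v, tie_key)
    return _es_batch(v[order], membership[:, order], weight_exponent)


def nominal_p(es_observed: float, null_es: np.ndarray) -> float:
    """Sign-matched one-sided permutation p-value.

    ``p = (1 + #{same-sign null with |null| >= |es|}) / (1 + #{same-sign
    null})``; never 0, and 1 when the observed ES is 0 or no same-sign
    nulls exist.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("null ES vector is empty")
    if es_observed == 0:
        return 1.0
    same = null_es > 0 if es_observed > 0 else null_es < 0
    n_same = int(same.sum())
    if n_same == 0:
        warnings.warn("no same-sign null ES; nominal p reported as 1.0")
        return 1.0
    n_ge = int((np.abs(null_es[same]) >= abs(es_observed)).sum())
    return (1 + n_ge) / (1 + n_same)


def normalize_es(es: float, null_es: np.ndarray) -> float:
    """NES: ES divided by the mean magnitude of same-sign null ES.

    NaN when no same-sign null exists (reported as missing downstream).
    """
    if es == 0:
        return 0.0
    null_es = np.asarray(null_es, dtype=float)
    same = null_es > 0 if es > 0 else null_es < 0
    if not same.any():
        return float("nan")
    return float(es / np.abs(null_es[same]).mean())


def _normalize_null(null_es: np.ndarray, min_support: int = 1) -> np.ndarray:
    """Null NES: each null ES scaled by its transcript's same-sign null mean.

    Sides with fewer than ``min_support`` values stay NaN (excluded from
    the pooled null).
    """
    out = np.full_like(null_es, np.nan, dtype=float)
    for i, row in enumerate(null_es):
        pos, neg = row > 0, row < 0
        if pos.sum() >= min_support:
            out[i, pos] = row[pos] / row[pos].mean()
        if neg.sum() >= min_support:
            out[i, neg] = row[neg] / np.abs(row[neg]).mean()
        out[i, row == 0] = 0.0
    return out


def fdr_q(observed_nes: np.ndarray, pooled_null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR Q values from a pooled permutation null.

    For a positive NES*, ``q = [fraction of pooled positive null NES >=
    NES*] / [fraction of observed positive NES >= NES*]`` clipped to
    [0, 1]; mirrored for negative NES. Within each sign, q is monotonized
    by a running minimum from the weakest |NES| upward.
    """
    obs = np.asarray(observed_nes, dtype=float)
    pool = np.asarray(pooled_null_nes, dtype=float).ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("pooled null is empty")
    q = np.full(obs.shape, np.nan)
    for sign in (1, -1):
        sel = np.isfinite(obs) & ((obs > 0) if sign > 0 else (obs < 0))
        if not sel.any():
            continue
        o = np.abs(obs[sel])
        nulls = pool[pool > 0] if sign > 0 else np.abs(pool[pool < 0])
        n_obs, n_null = o.size, nulls.size
        nulls_sorted = np.sort(nulls)
        o_sorted = np.sort(o)
        frac_null = (n_null - np.searchsorted(nulls_sorted, o, side="left")) / max(n_null, 1)
        frac_obs = (n_obs - np.searchsorted(o_sorted, o, side="left")) / n_obs
        raw = np.where(frac_obs > 0, np.clip(frac_null / np.where(frac_obs > 0, frac_obs, 1),
                                             0, 1), 1.0)
        # BH-style monotonization: each transcript takes the minimum raw q
        # over itself and all weaker (smaller-|NES|) transcripts, so q is
        # non-decreasing when sorted by |NES| descending
        order = np.argsort(o)  # ascending |NES| (weakest first)
        mono = np.minimum.accumulate(raw[order])
        adj = np.empty_like(raw)
        adj[order] = mono
        q[sel] = adj
    q[np.isfinite(obs) & (obs == 0)] = 1.0
    return q


# -- model / results objects ----------------------------------------------

class SSEA:
    """SSEA differential-expression model for one two-group contrast.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Counts (normalized to CPM internally) or pre-normalized values.
    sample_set : SampleSet
        The labelled group tested for enrichment (its complement is the
        reference group). A positive ES/direction ``+`` means higher
        expression inside the set.
    params : SseaParams
    percentile_q : float
        Sample quantile reported as ``percentile_value`` per transcript
        (default 0.975, the landscape cutoff quantile).
    percentile_matrix : ExpressionMatrix, optional
        Matrix (typically FPKM) from which the percentile metric and the
        percentile pre-filter are computed; defaults to ``matrix``.
    fdr_cutoff, min_percentile_value : float
        Cutoffs for the reported ``significant`` flag (defaults: FDR
        < 1e-5 and percentile value >= 1).
    """

    def __init__(self, matrix: ExpressionMatrix, sample_set: SampleSet,
                 params: SseaParams | None = None, percentile_q: float = 0.975,
                 percentile_matrix: ExpressionMatrix | None = None,
                 fdr_cutoff: float = 1e-5, min_percentile_value: float = 1.0):
        self.params = params or SseaParams()
        if matrix.unit == "counts" and self.params.normalization == "cpm":
            matrix = normalize_counts(matrix)
        self.matrix = matrix
        self.sample_set = sample_set
        self.percentile_q = percentile_q
        self.percentile_matrix = percentile_matrix or matrix
        if set(self.percentile_matrix.transcript_ids) < set(matrix.transcript_ids):
            raise ValueError("percentile_matrix must cover all tested transcripts")
        self.fdr_cutoff = fdr_cutoff
        self.min_percentile_value = min_percentile_value

    def fit(self) -> "SSEAResults":
        p = self.params
        values = self.matrix.values.to_numpy(float)
        n_tr, n_s = values.shape
        if n_tr == 0:
            raise ValueError("no transcripts to test")
        obs_mask = self.sample_set.mask(self.matrix.sample_ids)
        k = int(obs_mask.sum())
        rng = np.random.default_rng(p.seed)
        # Permutations and tie-break keys are drawn in canonical (sorted
        # sample id) order and mapped to column positions, so results are
        # invariant to the column order of the input matrix. One permutation
        # matrix is shared by all transcripts (pooled-null coherence).
        canon = np.argsort(np.asarray(self.matrix.sample_ids, dtype=object))
        membership = np.empty((p.n_permutations, n_s), dtype=bool)
        membership[:, canon] = _null_membership(n_s, k, p.n_permutations, rng)
        tie_keys = np.empty((n_tr, n_s))
        tie_keys[:, canon] = rng.random((n_tr, n_s))  # seeded tie-break, recorded
        es = np.empty(n_tr)
        nes = np.empty(n_tr)
        pvals = np.empty(n_tr)
        null_es = np.empty((n_tr, p.n_permutations))
        for i in range(n_tr):
            order = _sort_order(values[i], tie_keys[i])
            vs = values[i][order]
            es[i] = _es_batch(vs, obs_mask[order][None, :], p.weight_exponent)[0]
            null_es[i] = _es_batch(vs, membership[:, order], p.weight_exponent)
            pvals[i] = nominal_p(es[i], null_es[i])
            same = null_es[i] > 0 if es[i] > 0 else null_es[i] < 0
            if es[i] != 0 and same.sum() < p.min_null_support:
                nes[i] = float("nan")  # too little null support to normalize
            else:
                nes[i] = normalize_es(es[i], null_es[i])
        q = fdr_q(nes, _normalize_null(null_es, p.min_null_support))
        pct_vals = self.percentile_matrix.subset(
            transcript_ids=self.matrix.transcript_ids).values.to_numpy(float)
        pct = np.array([percentile_expression(row, self.percentile_q) for row in pct_vals])
        table = pd.DataFrame({
            "es": es, "nes": nes, "p_nominal": pvals, "fdr_q": q,
            "direction": np.where(es > 0, "+", np.where(es < 0, "-", ".")),
            "percentile_value": pct,
        }, index=self.matrix.transcript_ids.rename("transcript_id"))
        table["significant"] = ((table["fdr_q"] < self.fdr_cutoff) &
                                (table["percentile_value"] >= self.min_percentile_value))
        return SSEAResults(self, table, null_es)


class SSEAResults:
    """Per-transcript SSEA estimates with the permutation null retained."""

    def __init__(self, model: SSEA, table: pd.DataFrame, null_es: np.ndarray):
        self.model = model
        self.table = table
        self.null_es = null_es

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def significant_ids(self, direction: str | None = None) -> list:
        t = self.table[self.table["significant"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        return list(t.index)

    def summary(self) -> str:
        t, m = self.table, self.model
        lines = [
            "Sample Set Enrichment Analysis",
            "==============================",
            f"sample set:        {m.sample_set.name} "
            f"({len(m.sample_set.member_ids)} of {m.matrix.shape[1]} samples)",
            f"transcripts:       {len(t)}",
            f"permutations:      {m.params.n_permutations} (seed {m.params.seed})",
            f"weight exponent:   {m.params.weight_exponent}",
            f"significant:       {int(t['significant'].sum())} "
            f"(FDR<{m.fdr_cutoff:g}, percentile_{m.percentile_q:g} >= "
            f"{m.min_percentile_value:g})",
            f"  up in set (+):   {int((t['significant'] & (t['direction'] == '+')).sum())}",
            f"  down in set (-): {int((t['significant'] & (t['direction'] == '-')).sum())}",
        ]
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def run_ssea(matrix: ExpressionMatrix, sample_set: SampleSet,
             params: SseaParams | None = None, percentile_q: float = 0.975,
             **kwargs) -> pd.DataFrame:
    """Functional wrapper: fit :class:`SSEA` and return the result table."""
    return SSEA(matrix, sample_set, params=params, percentile_q=percentile_q,
                **kwargs).fit().table
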