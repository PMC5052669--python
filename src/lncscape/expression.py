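"""Expression-matrix container, I/O, unit conversion and expression metrics.

The central object is :class:`ExpressionMatrix`: a transcripts-by-samples
table of non-negative expression values (fragment counts or FPKM) together
with per-transcript metadata (length, biotype) and per-sample annotations
(tumor/normal cohort, receptor status, PAM50 label).

Unit conventions
----------------
FPKM (fragments per kilobase of transcript per million mapped fragments)
and raw fragment counts are interconvertible given the transcript length
and the per-sample mapped-fragment mass::

    fragments = FPKM * (length_bp / 1000) * (map_mass / 1e6)

The "95th percentile sample" summary used throughout the landscape
analysis is a nearest-rank quantile: the value of an actual sample, not an
interpolation between samples.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "fpkm_to_fragments",
    "fragments_to_fpkm",
    "percentile_expression",
    "expression_filter",
    "log2_fold_over_reference",
]

VALID_UNITS = ("counts", "FPKM")


class ExpressionMatrixError(ValueError):
    """Raised for malformed expression matrices or unit mismatches."""


class ExpressionMatrix:
    """Transcripts x samples expression values with metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values, transcripts as rows (index =
        transcript ids), samples as columns.
    unit : str
        ``"counts"`` or ``"FPKM"``.
    transcripts : pandas.DataFrame, optional
        Per-transcript metadata indexed by transcript id. Recognised
        columns: ``length_bp`` (int, > 0), ``biotype`` (``"lncRNA"`` or
        ``"protein_coding"``), and optionally ``chrom``, ``tss``,
        ``strand`` for promoter work.
    samples : pandas.DataFrame, optional
        Per-sample annotations indexed by sample id (e.g. ``cohort``,
        ``er_status``, ``pam50``). Must cover exactly the sample columns.
    """

    def __init__(self, values: pd.DataFrame, unit: str,
                 transcripts: pd.DataFrame | None = None,
                 samples: pd.DataFrame | None = None):
        if unit not in VALID_UNITS:
            raise ExpressionMatrixError(f"unknown unit {unit!r}; expected one of {VALID_UNITS}")
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ExpressionMatrixError(f"duplicate transcript id {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ExpressionMatrixError(f"duplicate sample id {dup!r}")
        if values.size and (values.to_numpy() < 0).any():
            bad = values.index[(values < 0).any(axis=1)][0]
            raise ExpressionMatrixError(f"negative expression value in transcript {bad!r}")
        values = values.rename_axis(index="transcript_id", columns=None)
        self.values = values
        self.unit = unit
        if transcripts is not None:
            transcripts = transcripts.reindex(values.index)
            if "length_bp" in transcripts and len(transcripts):
                if transcripts["length_bp"].isna().any():
                    missing = transcripts.index[transcripts["length_bp"].isna()][0]
                    raise ExpressionMatrixError(f"missing length for transcript {missing!r}")
                if (transcripts["length_bp"] <= 0).any():
                    raise ExpressionMatrixError("transcript lengths must be > 0")
        self.transcripts = transcripts
        if samples is not None:
            if set(samples.index) != set(values.columns):
                raise ExpressionMatrixError("sample annotations do not match sample ids 1:1")
            samples = samples.reindex(values.columns)
        self.samples = samples

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_t, n_s = self.shape
        return f"<ExpressionMatrix {n_t} transcripts x {n_s} samples [{self.unit}]>"

    def copy_with(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit or self.unit,
                                transcripts=self.transcripts, samples=self.samples)

    def subset(self, transcript_ids: Iterable | None = None,
               sample_ids: Iterable | None = None) -> "ExpressionMatrix":
        """Restrict to the given transcripts and/or samples (order preserved)."""
        values = self.values
        if transcript_ids is not None:
            transcript_ids = list(transcript_ids)
            missing = set(transcript_ids) - set(values.index)
            if missing:
                raise ExpressionMatrixError(f"unknown transcript id {sorted(missing)[0]!r}")
            values = values.loc[transcript_ids]
        if sample_ids is not None:
            sample_ids = list(sample_ids)
            missing = set(sample_ids) - set(values.columns)
            if missing:
                raise ExpressionMatrixError(f"unknown sample id {sorted(missing)[0]!r}")
            values = values[sample_ids]
        tr = self.transcripts.reindex(values.index) if self.transcripts is not None else None
        sm = self.samples.reindex(values.columns) if self.samples is not None else None
        return ExpressionMatrix(values, self.unit, transcripts=tr, samples=sm)

    # -- unit conversion ---------------------------------------------------
    def map_mass(self) -> pd.Series:
        """Total mapped-fragment mass per sample.

        For a counts matrix this is the column sum; FPKM matrices must be
        converted with an explicit map mass.
        """
        if self.unit != "counts":
            raise ExpressionMatrixError("map_mass derived from column sums requires counts")
        mm = self.values.sum(axis=0)
        if (mm <= 0).any():
            bad = mm.index[mm <= 0][0]
            raise ExpressionMatrixError(f"sample {bad!r} has zero total counts")
        return mm

    def to_fpkm(self, map_mass: pd.Series | None = None) -> "ExpressionMatrix":
        """Convert fragment counts to FPKM using transcript lengths."""
        if self.unit == "FPKM":
            return self
        if self.transcripts is None or "length_bp" not in self.transcripts:
            raise ExpressionMatrixError("FPKM conversion requires transcript lengths")
        mm = self.map_mass() if map_mass is None else map_mass.reindex(self.sample_ids)
        length_kb = self.transcripts["length_bp"].to_numpy(float) / 1000.0
        fpkm = self.values.div(length_kb, axis=0).div(mm / 1e6, axis=1)
        return self.copy_with(fpkm, unit="FPKM")

    def to_fragments(self, map_mass: pd.Series) -> "ExpressionMatrix":
        """Convert FPKM back to approximate fragment counts."""
        if self.unit == "counts":
            return self
        if self.transcripts is None or "length_bp" not in self.transcripts:
            raise ExpressionMatrixError("fragment conversion requires transcript lengths")
        length_kb = self.transcripts["length_bp"].to_numpy(float) / 1000.0
        frags = self.values.mul(length_kb, axis=0).mul(
            map_mass.reindex(self.sample_ids) / 1e6, axis=1)
        return self.copy_with(frags, unit="counts")


# -- I/O -------------------------------------------------------------------

def read_matrix(path, unit: str | None = None,
                transcripts: pd.DataFrame | None = None,
                samples: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column ``transcript_id``).

    A leading comment line ``#unit=FPKM`` (or ``counts``) records the unit;
    an explicit ``unit`` argument overrides it.
    """
    header_unit = None
    with open(path, "rt", encoding="utf-8") as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("#unit="):
            header_unit = first.strip().split("=", 1)[1]
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={0: str})
    if df.columns[0] != "transcript_id":
        raise ExpressionMatrixError(
            f"{path}: first column must be 'transcript_id', found {df.columns[0]!r}")
    if df["transcript_id"].duplicated().any():
        dup = df["transcript_id"][df["transcript_id"].duplicated()].iloc[0]
        raise ExpressionMatrixError(f"{path}: duplicate transcript id {dup!r}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ExpressionMatrixError(f"{path}: ragged or missing value at row {row + 1}")
    values = df.set_index("transcript_id")
    use_unit = unit or header_unit
    if use_unit is None:
        raise ExpressionMatrixError(f"{path}: no '#unit=' header line and no unit argument")
    return ExpressionMatrix(values, use_unit, transcripts=transcripts, samples=samples)


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with a ``#unit=`` comment header."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#unit={m.unit}\n")
        m.values.rename_axis("transcript_id").to_csv(fh, sep="\t")


# -- scalar conversions ----------------------------------------------------

def fpkm_to_fragments(fpkm: float, length_bp: float, map_mass: float) -> float:
    """Approximate fragment count for one transcript in one sample.

    ``fragments = fpkm * (length_bp/1000) * (map_mass/1e6)`` where
    ``map_mass`` is the sample's total mapped-fragment mass.
    """
    if length_bp <= 0:
        raise ValueError(f"length_bp must be > 0, got {length_bp}")
    if map_mass <= 0:
        raise ValueError(f"map_mass must be > 0, got {map_mass}")
    if fpkm < 0:
        raise ValueError(f"fpkm must be >= 0, got {fpkm}")
    return fpkm * (length_bp / 1000.0) * (map_mass / 1e6)


def fragments_to_fpkm(fragments: float, length_bp: float, map_mass: float) -> float:
    """Inverse of :func:`fpkm_to_fragments`."""
    if length_bp <= 0:
        raise ValueError(f"length_bp must be > 0, got {length_bp}")
    if map_mass <= 0:
        raise ValueError(f"map_mass must be > 0, got {map_mass}")
    if fragments < 0:
        raise ValueError(f"fragments must be >= 0, got {fragments}")
    return fragments / ((length_bp / 1000.0) * (map_mass / 1e6))


# -- metrics ---------------------------------------------------------------

def percentile_expression(values: Sequence[float], q: float) -> float:
    """Nearest-rank quantile: the value of the ``ceil(q*n)``-th sample
    (1-based) of the ascending sort.

    With ``q=0.95`` this is the "expression level of the 95th percentile
    sample": always the measured value of an actual sample.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_expression requires at least one value")
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    k = math.ceil(q * arr.size)  # 1-based rank
    return float(np.sort(arr)[k - 1])


def expression_filter(m: ExpressionMatrix, q: float = 0.95,
                      min_fpkm: float = 1.0) -> list:
    """Transcripts whose expression at the ``q`` sample quantile reaches
    ``min_fpkm`` (inclusive: "at least" ``min_fpkm``).

    The matrix must be in FPKM units.
    """
    if m.unit != "FPKM":
        raise ExpressionMatrixError(f"expression_filter requires FPKM, matrix is {m.unit!r}")
    n = m.shape[1]
    if n == 0:
        raise ExpressionMatrixError("expression_filter requires at least one sample")
    k = math.ceil(q * n)  # 1-based nearest rank, same convention as percentile_expression
    vals = np.sort(m.values.to_numpy(), axis=1)[:, k - 1]
    keep = vals >= min_fpkm
    return [t for t, ok in zip(m.transcript_ids, keep) if ok]


def log2_fold_over_reference(m: ExpressionMatrix, reference_sample_ids: Iterable,
                             pseudocount: float = 0.1) -> pd.DataFrame:
    """Per-transcript log2 fold change over the median of reference samples.

    ``out[g, s] = log2((m[g, s] + pc) / (median_ref(m[g, .]) + pc))``.
    Reference samples are typically the normal (or ER-negative) samples.
    The pseudocount guards the exact zeros common in FPKM matrices.
    """
    ref = list(reference_sample_ids)
    if not ref:
        raise ExpressionMatrixError("reference sample set is empty")
    missing = set(ref) - set(m.sample_ids)
    if missing:
        raise ExpressionMatrixError(f"unknown reference sample {sorted(missing)[0]!r}")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    med = m.values[ref].median(axis=1)
    return np.log2(m.values.add(pseudocount, axis=0).div(med + pseudocount, axis=0))
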