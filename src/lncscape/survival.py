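"""Expression-stratified survival: high/low FPKM grouping, Kaplan-Meier
product-limit curves and the two-group log-rank test.

The stratification mirrors the two-threshold design used for the tissue
cohort: samples above ``high_cut`` FPKM form the high group, samples
below ``low_cut`` the low group, and the middle band is excluded from the
test (both inequalities strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_by_expression",
    "km_estimate",
    "logrank_test",
    "ExpressionStratifiedKM",
    "KMResults",
    "read_survival",
    "write_survival",
]


def group_by_expression(fpkm: pd.Series, high_cut: float = 10.0,
                        low_cut: float = 1.0) -> pd.Series:
    """Label samples high (> high_cut), low (< low_cut) or excluded."""
    if high_cut <= low_cut:
        raise ValueError("high_cut must exceed low_cut")
    x = fpkm.astype(float)
    if (x < 0).any():
        bad = x.index[x < 0][0]
        raise ValueError(f"negative expression for sample {bad!r}")
    out = pd.Series("excluded", index=x.index, name="group")
    out[x > high_cut] = "high"
    out[x < low_cut] = "low"
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator for one group.

    Subjects censored at an event time remain at risk for that event
    (standard convention). Returns one row per distinct event time with
    columns time, at_risk, events, censored, survival.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one record")
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    rows = []
    s = 1.0
    for ti in np.unique(t):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        c = int(((t == ti) & (e == 0)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": ti, "at_risk": at_risk, "events": d,
                     "censored": c, "survival": s})
    return pd.DataFrame(rows)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    chi2 = (sum(O - E))^2 / sum(V) over distinct event times, with the
    standard hypergeometric variance; p from chi2 with 1 df. Ties at
    event times are handled by the aggregate O/E/V formulation.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        na = (ta >= ti).sum()
        nb = (tb >= ti).sum()
        n = na + nb
        da = ((ta == ti) & (ea == 1)).sum()
        db = ((tb == ti) & (eb == 1)).sum()
        d = da + db
        if n < 2 or n == d:
            # variance term degenerates when everyone remaining dies at ti
            o_minus_e += da - d * na / n
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


class ExpressionStratifiedKM:
    """Survival model: stratify samples by a transcript's FPKM and compare
    the high and low groups.

    Parameters
    ----------
    expression : pandas.Series
        FPKM per sample (index = sample ids).
    survival : pandas.DataFrame
        Columns ``time`` (> 0) and ``event`` (0/1), indexed by sample id.
    high_cut, low_cut : float
        FPKM thresholds (strict >, strict <); the middle band is dropped.
    """

    def __init__(self, expression: pd.Series, survival: pd.DataFrame,
                 high_cut: float = 10.0, low_cut: float = 1.0):
        common = expression.index.intersection(survival.index)
        if len(common) == 0:
            raise ValueError("no samples shared between expression and survival table")
        self.expression = expression.loc[common]
        self.survival = survival.loc[common]
        if (self.survival["time"] <= 0).any():
            bad = self.survival.index[self.survival["time"] <= 0][0]
            raise ValueError(f"non-positive survival time for sample {bad!r}")
        self.high_cut = high_cut
        self.low_cut = low_cut

    def fit(self) -> "KMResults":
        groups = group_by_expression(self.expression, self.high_cut, self.low_cut)
        records = self.survival.assign(group=groups)
        used = records[records["group"] != "excluded"]
        hi = used[used["group"] == "high"]
        lo = used[used["group"] == "low"]
        if hi.empty or lo.empty:
            raise ValueError("one of the expression groups is empty; cannot test")
        curves = {g: km_estimate(df["time"], df["event"])
                  for g, df in (("high", hi), ("low", lo))}
        chi2, p = logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
        return KMResults(self, records, curves, chi2, p)


@dataclass
class KMResults:
    model: ExpressionStratifiedKM
    records: pd.DataFrame
    curves: dict
    chi2: float
    p_value: float

    def summary(self) -> str:
        counts = self.records["group"].value_counts()
        lines = [
            "Expression-stratified Kaplan-Meier",
            "==================================",
            f"high (> {self.model.high_cut:g} FPKM): {counts.get('high', 0)} samples, "
            f"{int(self.records.loc[self.records['group'] == 'high', 'event'].sum())} events",
            f"low  (< {self.model.low_cut:g} FPKM): {counts.get('low', 0)} samples, "
            f"{int(self.records.loc[self.records['group'] == 'low', 'event'].sum())} events",
            f"excluded (middle band): {counts.get('excluded', 0)} samples",
            f"log-rank chi2 = {self.chi2:.4f}, p = {self.p_value:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Step plot of the two KM curves (matplotlib axes returned)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for g, curve in self.curves.items():
            x = np.concatenate([[0.0], curve["time"].to_numpy()])
            y = np.concatenate([[1.0], curve["survival"].to_numpy()])
            ax.step(x, y, where="post", label=g)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df.set_index("sample_id")


def write_survival(df: pd.DataFrame, path) -> None:
    df.rename_axis("sample_id").to_csv(path, sep="\t")
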