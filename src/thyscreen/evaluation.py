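"""Performance estimation for conformal activity models.

Conformal models are judged on two axes.  The CP-specific axis: per-class
*validity* (fraction of compounds of that class whose prediction set
contains the true label, with the uncertain ``both`` region always counting
as correct and ``empty`` always as an error) and per-class *efficiency*
(fraction receiving single-label predictions, correct or not).  The
classical axis, computed from single-label predictions only:

    TPR   = TP / nA        FPR   = FP / nIA       NPV = TN / nIAp
    TDR.A = TP / nAp       TDR.B = TP.B / nBp

where nA/nIA are the true class sizes in the validation set, nAp/nIAp/nBp/
nEp the numbers of compounds predicted active/inactive/both/empty, and TP.B
the actives landing in the ``both`` region.  TDR (true discovery rate) is
the expected hit rate were the compounds in that region sent for testing.
Rates with a zero denominator are reported as NA, never as 0.

The sweep evaluates one fitted model across significance levels
(default 0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3), computing p-values
once and re-deriving regions per level.  A model is accepted at a level when
both per-class validities reach the confidence level ``1 - sl`` within a
0.01 tolerance (one-sided: conformal models are typically conservative and
may exceed it).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .conformal import AggregatedConformalClassifier, REGION_BOTH, REGION_EMPTY

__all__ = [
    "DEFAULT_SL_SWEEP",
    "ConfusionCounts",
    "tabulate",
    "metrics",
    "validity_efficiency",
    "sweep",
    "is_valid",
    "report_to_markdown",
    "report_to_csv",
]

DEFAULT_SL_SWEEP = (0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)

#: column order of the per-level performance report
REPORT_COLUMNS = [
    "sl", "validity_active", "validity_inactive",
    "efficiency_active", "efficiency_inactive",
    "nAp", "TDR.A", "nIAp", "NPV", "nBp", "TDR.B", "nEp", "TPR", "FPR",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Region-aware confusion counts for one significance level.

    ``TP``/``FP``/``TN`` count single-label predictions only; ``TP_B`` is
    the number of true actives in the ``both`` region.
    """

    TP: int
    FP: int
    TN: int
    TP_B: int
    nA: int
    nIA: int
    nAp: int
    nIAp: int
    nBp: int
    nEp: int

    def __post_init__(self):
        if self.nAp + self.nIAp + self.nBp + self.nEp != self.nA + self.nIA:
            raise ValueError("region counts do not partition the compounds")
        if self.TP > min(self.nA, self.nAp) or self.FP > min(self.nIA, self.nAp):
            raise ValueError("inconsistent single-label counts")
        if self.TP_B > min(self.nA, self.nBp):
            raise ValueError("inconsistent both-region counts")


def _check_regions(regions: Sequence[str]):
    valid = {"active", "inactive", REGION_BOTH, REGION_EMPTY}
    bad = set(regions) - valid
    if bad:
        raise ValueError(f"unknown region labels: {sorted(bad)}")


def tabulate(regions: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Count regions against true binary labels.

    Parameters
    ----------
    regions : sequence over {"active", "inactive", "both", "empty"}
    truth : sequence over {"active", "inactive"}, aligned with ``regions``
    """
    regions = list(regions)
    if regions and hasattr(regions[0], "region"):
        records = regions
        if isinstance(truth, dict):
            missing = [r.compound_id for r in records
                       if r.compound_id not in truth]
            if missing:
                raise ValueError(f"no truth label for compounds: {missing}")
            truth = [truth[r.compound_id] for r in records]
        regions = [r.region for r in records]
    truth = list(truth)
    if len(regions) != len(truth):
        raise ValueError(
            f"{len(regions)} predictions vs {len(truth)} truth labels")
    _check_regions(regions)
    bad = set(truth) - {"active", "inactive"}
    if bad:
        raise ValueError(f"truth labels must be binary, got extra {sorted(bad)}")
    r = np.asarray(regions, dtype=object)
    t = np.asarray(truth, dtype=object)
    return ConfusionCounts(
        TP=int(np.sum((r == "active") & (t == "active"))),
        FP=int(np.sum((r == "active") & (t == "inactive"))),
        TN=int(np.sum((r == "inactive") & (t == "inactive"))),
        TP_B=int(np.sum((r == REGION_BOTH) & (t == "active"))),
        nA=int(np.sum(t == "active")),
        nIA=int(np.sum(t == "inactive")),
        nAp=int(np.sum(r == "active")),
        nIAp=int(np.sum(r == "inactive")),
        nBp=int(np.sum(r == REGION_BOTH)),
        nEp=int(np.sum(r == REGION_EMPTY)),
    )


def _rate(num: int, den: int) -> float:
    """num/den with NA (NaN) for a zero denominator."""
    return num / den if den else float("nan")


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Classical rates from region-aware counts; NaN encodes NA."""
    return {
        "TPR": _rate(c.TP, c.nA),
        "FPR": _rate(c.FP, c.nIA),
        "NPV": _rate(c.TN, c.nIAp),
        "TDR.A": _rate(c.TP, c.nAp),
        "TDR.B": _rate(c.TP_B, c.nBp),
    }


def validity_efficiency(
    regions: Sequence[str], truth: Sequence[str]
) -> dict[str, float]:
    """Per-class validity and efficiency.

    For class c: validity = (correct singles + both) / n_c, efficiency =
    singles / n_c.  ``empty`` counts in the denominator and is always an
    error and never a single.  A class absent from the truth gets NaN.
    """
    regions = np.asarray(list(regions), dtype=object)
    truth = np.asarray(list(truth), dtype=object)
    if len(regions) != len(truth):
        raise ValueError("predictions and truth must align")
    _check_regions(regions)
    out = {}
    for cls in ("active", "inactive"):
        mask = truth == cls
        n = int(mask.sum())
        correct = int(np.sum(mask & ((regions == cls) | (regions == REGION_BOTH))))
        singles = int(np.sum(mask & ((regions == "active") |
                                     (regions == "inactive"))))
        out[f"validity_{cls}"] = _rate(correct, n)
        out[f"efficiency_{cls}"] = _rate(singles, n)
    return out


def _row_for_sl(regions, truth, sl: float) -> dict[str, float]:
    c = tabulate(regions, truth)
    row = {"sl": sl, **validity_efficiency(regions, truth)}
    m = metrics(c)
    row.update({"nAp": c.nAp, "nIAp": c.nIAp, "nBp": c.nBp, "nEp": c.nEp})
    row.update(m)
    return row


def sweep(
    model: AggregatedConformalClassifier,
    X_val,
    y_val: Sequence[str],
    sls: Sequence[float] = DEFAULT_SL_SWEEP,
) -> pd.DataFrame:
    """Evaluate a fitted model across a significance-level sweep.

    p-values are computed once; regions are re-derived per level.  Returns
    one row per significance level in the standard report column order.
    """
    y_val = list(y_val)
    if len(y_val) == 0:
        raise ValueError("validation set is empty")
    p = model.predict_p(X_val)
    ia = int(np.flatnonzero(model.classes_ == model.pos_label_)[0])
    neg = model.classes_[1 - ia]
    truth = ["active" if y == model.pos_label_ else "inactive" for y in y_val]
    rows = []
    for sl in sls:
        include_a = p[:, ia] > sl
        include_i = p[:, 1 - ia] > sl
        regions = np.where(
            include_a & include_i, REGION_BOTH,
            np.where(include_a, "active",
                     np.where(include_i, "inactive", REGION_EMPTY)))
        rows.append(_row_for_sl(regions.astype(object), truth, sl))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def is_valid(row, tolerance: float = 0.01) -> bool:
    """Acceptance rule for one report row.

    True iff for both classes the shortfall of validity below the
    confidence level ``1 - sl`` is strictly smaller than the
    negligible-difference tolerance (one-sided; validity exceeding the
    confidence level is always acceptable).  A shortfall of exactly the
    tolerance fails.  NA validity fails.
    """
    va, vi = row["validity_active"], row["validity_inactive"]
    if np.isnan(va) or np.isnan(vi):
        return False
    confidence = 1.0 - row["sl"]
    # round away float noise so the strict boundary is exact at printed
    # precision
    return all(round(confidence - v, 9) < tolerance for v in (va, vi))


def _format_report(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    rate_cols = [c for c in out.columns
                 if c not in ("sl", "nAp", "nIAp", "nBp", "nEp")]
    for c in rate_cols:
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.2f}")
    return out


def report_to_csv(df: pd.DataFrame, path=None) -> str | None:
    """Write a sweep report as CSV with NA for undefined rates."""
    out = _format_report(df)
    if path is None:
        return out.to_csv(index=False)
    out.to_csv(path, index=False)
    return None


def report_to_markdown(df: pd.DataFrame) -> str:
    """Render a sweep report as a Markdown table."""
    out = _format_report(df)
    buf = StringIO()
    buf.write("| " + " | ".join(out.columns) + " |\n")
    buf.write("|" + "---|" * len(out.columns) + "\n")
    for _, row in out.iterrows():
        buf.write("| " + " | ".join(str(v) for v in row) + " |\n")
    return buf.getvalue()
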