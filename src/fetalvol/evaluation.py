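"""Bland–Altman agreement analysis between paired measurement methods.

Agreement between two methods measuring the same quantity (for example
automatic versus manual fetal volume) is summarised by the mean of the
paired differences (bias), the sample standard deviation of the differences,
and the 95% limits of agreement bias ± 1.96·SD.  Percent statistics use the
per-pair mean of the two methods as denominator, the standard practice for
ratio-style Bland–Altman reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AgreementReport:
    """Bias and 95% limits of agreement, absolute and (when defined) percent."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_pct: float | None = None
    sd_pct: float | None = None
    loa_pct_low: float | None = None
    loa_pct_high: float | None = None

    def summary(self, unit: str = "") -> str:
        u = f" {unit}" if unit else ""
        s = (
            f"n = {self.n}; bias = {self.bias:.3g}{u}; SD = {self.sd_diff:.3g}{u}; "
            f"95% LoA = [{self.loa_low:.3g}, {self.loa_high:.3g}]{u}"
        )
        if self.bias_pct is not None:
            s += (
                f"; bias% = {self.bias_pct:.3g}%; "
                f"95% LoA% = [{self.loa_pct_low:.3g}, {self.loa_pct_high:.3g}]%"
            )
        return s


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    # sample SD, n-1 denominator; SD of a single value is 0 by convention
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return m, s


def bland_altman(pairs) -> AgreementReport:
    """Bland–Altman statistics for paired measurements (method_a, method_b).

    diff = a − b; bias = mean(diff); SD uses the n−1 denominator; limits of
    agreement are bias ± 1.96·SD.  Percent differences 100·diff / mean(a, b)
    get the same treatment; if any per-pair mean is zero the percent block is
    undefined (None) while the absolute statistics are still returned.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    if arr.shape[0] < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("paired values must be finite")
    a, b = arr[:, 0], arr[:, 1]
    diff = a - b
    bias, sd = _mean_sd(diff)
    report = AgreementReport(
        n=arr.shape[0],
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )
    means = (a + b) / 2.0
    if np.all(means != 0):
        pct = 100.0 * diff / means
        bias_p, sd_p = _mean_sd(pct)
        report.bias_pct = bias_p
        report.sd_pct = sd_p
        report.loa_pct_low = bias_p - 1.96 * sd_p
        report.loa_pct_high = bias_p + 1.96 * sd_p
    return report


def agreement_table(auto, manual, labels) -> pd.DataFrame:
    """Per-case agreement table with an attached AgreementReport.

    Rows (one per case, ordered by id): id, value_a, value_b, diff, pct_diff.
    The overall report is attached as ``df.attrs['report']``.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    labels = list(labels)
    if not (len(auto) == len(manual) == len(labels)):
        raise ValueError("auto, manual and labels must have equal lengths")
    if len(labels) == 0:
        raise ValueError("no cases supplied")
    order = np.argsort(np.asarray(labels, dtype=object))
    diff = auto - manual
    means = (auto + manual) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(means != 0, 100.0 * diff / means, np.nan)
    df = pd.DataFrame(
        {
            "id": np.asarray(labels, dtype=object)[order],
            "value_a": auto[order],
            "value_b": manual[order],
            "diff": diff[order],
            "pct_diff": pct[order],
        }
    )
    if len(labels) >= 2:
        df.attrs["report"] = bland_altman(np.column_stack([auto, manual]))
    return df
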