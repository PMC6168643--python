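"""Group summaries and the statistical comparisons used for population
tables: mean ± SEM per group, Wilcoxon rank-sum tests for unpaired data,
paired t tests for paired data, and Bonferroni-Holm adjustment for
multiple comparisons (with the raw p values retained, mirroring the
reporting convention of reporting original p values alongside the
adjusted significance threshold)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "compare",
    "adjust_holm",
]


@dataclass
class GroupSummary:
    group: str
    n_units: int
    mean: float
    sem: float
    proportion_excited: Optional[float] = None
    n_animals: Optional[int] = None


@dataclass
class ComparisonResult:
    statistic: float  # z (rank-sum) or t (paired t)
    p_raw: float
    test_name: str
    paired: bool
    p_adjusted: Optional[float] = None


def summarize(groups: Mapping[str, Sequence[float]],
              excited: Optional[Mapping[str, Sequence[bool]]] = None,
              n_animals: Optional[Mapping[str, int]] = None,
              ) -> list[GroupSummary]:
    """Mean ± SEM (sd / sqrt(n)) per group, plus the excited proportion.

    ``groups`` maps condition label -> per-unit metric values; ``excited``
    optionally maps the same labels -> per-unit excitation flags.
    """
    out = []
    for label, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {label!r}")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        prop = None
        if excited is not None and label in excited:
            flags = np.asarray(list(excited[label]), dtype=bool)
            prop = float(flags.mean())
        out.append(GroupSummary(
            group=label, n_units=int(v.size), mean=float(v.mean()), sem=sem,
            proportion_excited=prop,
            n_animals=None if n_animals is None else n_animals.get(label),
        ))
    return out


def summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum z statistic (normal approximation, tie-corrected)
    and its two-sided p value."""
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (r1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


def compare(a: Sequence[float], b: Sequence[float], paired: bool = False,
            ) -> ComparisonResult:
    """Two-sided comparison of two samples.

    Unpaired data: Wilcoxon rank-sum test (z from the tie-corrected normal
    approximation).  Paired data: paired t test.  Both two-sided.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.allclose(d, 0):
            return ComparisonResult(0.0, 1.0, "paired t", True)
        t, p = sps.ttest_rel(a, b)
        return ComparisonResult(float(t), float(min(p, 1.0)), "paired t", True)
    z, p = _ranksum_z(a, b)
    return ComparisonResult(z, p, "Wilcoxon rank-sum", False)


def adjust_holm(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p values, order-preserving.

    ``adj_(i) = max_{j <= i} (m - j + 1) * p_(j)`` over the ascending
    order, capped at 1; the output is returned in the input order so raw
    and adjusted values can be reported side by side.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def compare_table(pairs: Mapping[str, tuple[Sequence[float], Sequence[float], bool]],
                  ) -> pd.DataFrame:
    """Run several comparisons and Holm-adjust them jointly.

    ``pairs`` maps a comparison label to ``(a, b, paired)``.  Returns a
    table with the statistic, raw p and Holm-adjusted p per comparison.
    """
    rows = []
    for label, (a, b, paired) in pairs.items():
        res = compare(a, b, paired=paired)
        rows.append({"comparison": label, "test": res.test_name,
                     "statistic": res.statistic, "p_raw": res.p_raw,
                     "paired": paired})
    df = pd.DataFrame(rows)
    df["p_holm"] = adjust_holm(df["p_raw"].to_numpy())
    return df
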