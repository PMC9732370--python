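"""Benchmarking protocol: correlation of denoised trials to a reference.

The reference is the across-trial average (the standard ERP estimate).  Each
method denoises each single trial; the Pearson correlation between the
denoised trial and the reference measures how much of the stimulus-locked
waveform survives.  The raw trials enter as the "original" column.  Method
means are compared by a paired test on Fisher z-transformed correlations.

Note the usual reference includes the trial under test, which biases every
correlation slightly upward; ``reference_policy="loo"`` offers the unbiased
leave-one-out alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

# a denoiser: (trial, reference) -> denoised trial
Method = Callable[[np.ndarray, np.ndarray], np.ndarray]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input (undefined)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson needs two equal-length 1-D series (n >= 2)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    am, bm = a - a.mean(), b - b.mean()
    return float(np.dot(am, bm) /
                 np.sqrt(np.dot(am, am) * np.dot(bm, bm)))


@dataclass
class BenchmarkResult:
    """Per-trial correlations, method means and pairwise p-values."""

    per_trial: pd.DataFrame            # trials x methods -> r
    means: pd.Series                   # method -> mean r
    pairwise_p: dict[tuple[str, str], float]
    config_snapshot: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["method            mean r", "-" * 26]
        for name, m in self.means.items():
            lines.append(f"{name:<16} {m: .4f}")
        if self.pairwise_p:
            lines.append("")
            lines.append("paired tests (Fisher z):")
            for (a, b), p in self.pairwise_p.items():
                lines.append(f"  {a} vs {b}: p = {p:.4g}")
        return "\n".join(lines)


def paired_test(r_a: np.ndarray, r_b: np.ndarray,
                kind: str = "t") -> float:
    """Two-sided paired test on Fisher z-transformed correlations.

    ``kind='t'`` is a paired t-test, ``kind='wilcoxon'`` the signed-rank
    alternative.  Identical samples (all differences zero) give p = 1.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape or r_a.size < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    z_a = np.arctanh(np.clip(r_a, -1 + 1e-12, 1 - 1e-12))
    z_b = np.arctanh(np.clip(r_b, -1 + 1e-12, 1 - 1e-12))
    d = z_a - z_b
    if np.allclose(d, 0.0):
        return 1.0
    if kind == "wilcoxon":
        return float(stats.wilcoxon(d).pvalue)
    if np.ptp(d) == 0:  # constant non-zero differences: t is infinite
        return 0.0
    return float(stats.ttest_rel(z_a, z_b).pvalue)


def benchmark(trials: np.ndarray, methods: Mapping[str, Method],
              reference_policy: str = "pooled",
              test_kind: str = "t",
              config_snapshot: dict | None = None) -> BenchmarkResult:
    """Run every method over every trial and score against the reference.

    ``reference_policy='pooled'`` correlates each trial against the mean of
    *all* trials (the trial under test included); ``'loo'`` uses the mean of
    the remaining trials.  A method failure on one trial is recorded as NaN
    for that cell, not raised.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 2:
        raise ValueError("benchmark needs at least two trials")
    if reference_policy not in ("pooled", "loo"):
        raise ValueError("reference_policy must be 'pooled' or 'loo'")
    n = trials.shape[0]
    grand = trials.mean(axis=0)

    def _reference(i: int) -> np.ndarray:
        if reference_policy == "pooled":
            return grand
        return (grand * n - trials[i]) / (n - 1)

    columns = ["original", *methods.keys()]
    table = pd.DataFrame(index=pd.RangeIndex(n, name="trial"),
                         columns=columns, dtype=float)
    for i in range(n):
        ref = _reference(i)
        table.loc[i, "original"] = pearson(trials[i], ref)
        for name, fn in methods.items():
            try:
                table.loc[i, name] = pearson(fn(trials[i], ref), ref)
            except Exception:
                table.loc[i, name] = np.nan

    means = table.mean(axis=0)
    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            mask = table[a].notna() & table[b].notna()
            if mask.sum() >= 3:
                pairwise[(a, b)] = paired_test(table.loc[mask, a],
                                               table.loc[mask, b],
                                               kind=test_kind)
    return BenchmarkResult(per_trial=table, means=means,
                           pairwise_p=pairwise,
                           config_snapshot=config_snapshot or {})


def standard_methods(denoise_config=None, eemd_config=None
                     ) -> dict[str, Method]:
    """The four denoisers under their benchmark names.

    Each entry accepts ``(trial, reference)``; only EEMD-ICA actually uses
    the reference (its component-selection step requires it).
    """
    from . import baselines, pipeline

    dcfg = denoise_config or pipeline.DenoiseConfig()
    ecfg = eemd_config or baselines.EemdConfig()
    return {
        "tf": lambda x, ref: pipeline.tf_denoise(x, dcfg),
        "eemd_ica": lambda x, ref: baselines.eemd_ica_denoise(x, ref, ecfg),
        "eemd_cca": lambda x, ref: baselines.eemd_cca_denoise(x, ecfg),
        "wavelet": lambda x, ref: baselines.wavelet_threshold_denoise(x),
    }
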