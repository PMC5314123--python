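"""Per-probe differential-methylation calling on two-channel log-ratios.

The chain is: log2(bound/input) per probe and sample, per-array median
centering, a two-group test per probe (Welch t by default, Wilcoxon rank-sum
as an option), Benjamini-Hochberg adjustment across all probes of the
dataset, and a direction call at the FDR threshold (default q < 0.2).

Sign convention: positive effect = stress above control = "hyper".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

GROUPS = ("control", "stress")
DEFAULT_FDR = 0.2

TestName = Literal["welch", "wilcoxon"]


@dataclass
class LogRatioMatrix:
    """Probe x sample matrix of log2(bound/input) with the sample design.

    ``values`` is indexed by probe_id with sample_id columns; ``groups`` maps
    every sample to "control" or "stress".
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise InputError(f"samples without a group label: {missing}")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise InputError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("log-ratio matrix contains non-finite values")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(control, stress) value arrays, probes x samples."""
        v = self.values
        return (v.loc[:, self.groups == "control"].to_numpy(),
                v.loc[:, self.groups == "stress"].to_numpy())


def compute_log_ratios(bound: pd.DataFrame, input_: pd.DataFrame,
                       groups: pd.Series) -> LogRatioMatrix:
    """Element-wise log2(bound/input) for aligned probe x sample tables."""
    if set(bound.index) != set(input_.index) or set(bound.columns) != set(input_.columns):
        raise InputError("bound and input tables must share probes and samples")
    input_ = input_.reindex(index=bound.index, columns=bound.columns)
    for name, tab in (("bound", bound), ("input", input_)):
        arr = tab.to_numpy(dtype=float)
        bad = ~(arr > 0) | ~np.isfinite(arr)
        if bad.any():
            p, s = np.argwhere(bad)[0]
            raise InputError(
                f"non-positive or missing {name} intensity at probe "
                f"{tab.index[p]!r}, sample {tab.columns[s]!r}"
            )
    values = np.log2(bound.to_numpy(dtype=float) / input_.to_numpy(dtype=float))
    return LogRatioMatrix(pd.DataFrame(values, index=bound.index,
                                       columns=bound.columns), groups)


def normalize_log_ratios(m: LogRatioMatrix) -> LogRatioMatrix:
    """Median-center each array (column); preserves within-column ordering."""
    if m.values.empty:
        raise InputError("cannot normalize an empty log-ratio matrix")
    return LogRatioMatrix(m.values - m.values.median(axis=0), m.groups)


def _welch(ctrl: np.ndarray, strs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(strs, ctrl, axis=1, equal_var=False)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    effect = strs.mean(axis=1) - ctrl.mean(axis=1)
    # zero variance in both groups: p undefined by the formula; by convention
    # identical means -> p=1, distinct means -> p=0
    degenerate = (ctrl.var(axis=1) == 0) & (strs.var(axis=1) == 0)
    if degenerate.any():
        eff_d = effect[degenerate]
        t_d = np.zeros_like(eff_d)
        t_d[eff_d != 0] = np.sign(eff_d[eff_d != 0]) * np.inf
        t[degenerate] = t_d
        p[degenerate] = np.where(eff_d == 0, 1.0, 0.0)
    return t, p


def _wilcoxon(ctrl: np.ndarray, strs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = stats.mannwhitneyu(strs, ctrl, axis=1, alternative="two-sided")
    return res.statistic, res.pvalue


def differential_probe_test(m: LogRatioMatrix,
                            test: TestName = "welch") -> pd.DataFrame:
    """Two-sided two-group test per probe.

    Returns a frame indexed by probe with ``log2_fold_diff`` (mean stress minus
    mean control), ``statistic`` and ``p_value``.
    """
    ctrl, strs = m.split()
    if ctrl.shape[1] < 2 or strs.shape[1] < 2:
        raise InputError(
            f"need >=2 samples per group, got control={ctrl.shape[1]}, "
            f"stress={strs.shape[1]}"
        )
    if test == "welch":
        stat, p = _welch(ctrl, strs)
    elif test == "wilcoxon":
        stat, p = _wilcoxon(ctrl, strs)
    else:
        raise InputError(f"unknown test {test!r}")
    return pd.DataFrame(
        {"log2_fold_diff": strs.mean(axis=1) - ctrl.mean(axis=1),
         "statistic": stat, "p_value": p},
        index=m.values.index,
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (not np.isfinite(p).all() or (p < 0).any() or (p > 1).any()):
        raise InputError("p-values must be finite and within [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_probe_directions(effects, q_values,
                          threshold: float = DEFAULT_FDR) -> np.ndarray:
    """hyper / hypo / ns per probe; a zero effect is never given a direction."""
    effects = np.asarray(effects, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if effects.shape != q.shape:
        raise InputError("effects and q-values are not aligned")
    out = np.full(effects.shape, "ns", dtype=object)
    out[(q < threshold) & (effects > 0)] = "hyper"
    out[(q < threshold) & (effects < 0)] = "hypo"
    return out


def call_probes(m: LogRatioMatrix, fdr_threshold: float = DEFAULT_FDR,
                test: TestName = "welch", normalize: bool = True) -> pd.DataFrame:
    """Full per-probe pipeline: normalize, test, adjust, assign direction."""
    if normalize:
        m = normalize_log_ratios(m)
    res = differential_probe_test(m, test=test)
    res["q_value"] = adjust_fdr(res["p_value"].to_numpy())
    res["direction"] = call_probe_directions(
        res["log2_fold_diff"].to_numpy(), res["q_value"].to_numpy(), fdr_threshold
    )
    res.index.name = "probe_id"
    return res


def call_dataset(bound: pd.DataFrame, input_: pd.DataFrame, groups: pd.Series,
                 annotation: pd.DataFrame | None = None,
                 fdr_threshold: float = DEFAULT_FDR,
                 test: TestName = "welch") -> pd.DataFrame:
    """Convenience wrapper from raw intensities to a probe-call table.

    With ``annotation`` (chrom/start/end/probe_id) the genomic coordinates are
    merged into the result.
    """
    calls = call_probes(compute_log_ratios(bound, input_, groups),
                        fdr_threshold=fdr_threshold, test=test).reset_index()
    if annotation is not None:
        coords = annotation[["probe_id", "chrom", "start", "end"]]
        calls = coords.merge(calls, on="probe_id", how="right")
    return calls
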