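"""Group-level statistics for the neuro-cognitive assessment.

Channel x time significance maps between error and non-error trials (Tukey
HSD per cell), condition comparisons (Tukey HSD across control conditions,
Lilliefors normality screening, paired t-tests between schemes), Pearson
similarity of ERP waveforms over the 300-400 ms negative deflection, and a
subject-replication power extrapolation that asks how many identically
behaving subjects would make the paired scheme contrast significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from errp_exo.preprocess import EpochSet


@dataclass
class GroupResult:
    """Per-subject accuracy table with grand mean +/- SEM and test outcomes."""

    accuracies: pd.DataFrame          # columns: subject, modality, scheme, accuracy
    grand_mean: float
    sem: float
    tests: dict


def summarize_accuracies(table: pd.DataFrame) -> GroupResult:
    vals = table["accuracy"].to_numpy(dtype=float)
    n = len(vals)
    return GroupResult(
        accuracies=table,
        grand_mean=float(vals.mean()),
        sem=float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        tests={},
    )


def tukey_hsd_map(
    epochs: EpochSet | None = None,
    alpha: float = 0.05,
    *,
    error_data: np.ndarray | None = None,
    nonerror_data: np.ndarray | None = None,
    return_p: bool = False,
) -> np.ndarray:
    """Per-(channel, time) Tukey HSD comparison of error vs non-error trials.

    For two groups the Tukey test reduces to the studentized-range statistic
    q = |m1 - m0| / sqrt(MSW/2 * (1/n1 + 1/n0)) with k=2 groups and
    n1+n0-2 degrees of freedom; for k=2 the studentized range satisfies
    Q = sqrt(2)|T| exactly, so p = 2*P(T > q/sqrt(2)) — evaluated through
    the t distribution, which vectorises cheaply over all cells (the
    generic studentized-range survival function integrates numerically and
    is ~1e4 times slower).  Returns the boolean mask of p < alpha
    (channels x samples), or the p-map itself when ``return_p``.
    """
    if epochs is not None:
        error_data = epochs.data[epochs.labels == 1].astype(np.float64)
        nonerror_data = epochs.data[epochs.labels == 0].astype(np.float64)
    a = np.asarray(error_data, dtype=np.float64)
    b = np.asarray(nonerror_data, dtype=np.float64)
    n1, n0 = a.shape[0], b.shape[0]
    if min(n1, n0) < 2:
        raise ValueError("need at least 2 trials per class")
    df = n1 + n0 - 2
    msw = (a.var(0, ddof=1) * (n1 - 1) + b.var(0, ddof=1) * (n0 - 1)) / df
    denom = np.sqrt(np.maximum(msw, 1e-300) / 2.0 * (1.0 / n1 + 1.0 / n0))
    q = np.abs(a.mean(0) - b.mean(0)) / denom
    p = 2.0 * sstats.t.sf(q / np.sqrt(2.0), df)
    return p if return_p else p < alpha


@dataclass
class ConditionComparison:
    tukey_table: pd.DataFrame         # pairwise condition comparisons
    lilliefors_p: dict[str, float]    # normality screen per paired-diff set
    paired_t: dict[str, tuple[float, float]]   # name -> (t, p)


def compare_conditions(
    accuracy_table: pd.DataFrame,
    condition_col: str = "condition",
    value_col: str = "accuracy",
    subject_col: str = "subject",
    paired: tuple[str, str] = ("gravity", "myoprocessor"),
) -> ConditionComparison:
    """Tukey HSD across conditions plus a paired scheme contrast.

    The Tukey HSD cross-compares all conditions in the table (e.g. the
    unassisted / gravity / myoprocessor trajectory accuracies); the paired
    t-test contrasts the two assisted schemes within subjects, preceded by a
    Lilliefors normality check on the paired differences.
    """
    df = accuracy_table
    res = pairwise_tukeyhsd(df[value_col].to_numpy(dtype=float),
                            df[condition_col].to_numpy(), alpha=0.05)
    tukey_table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])

    wide = df.pivot_table(index=subject_col, columns=condition_col, values=value_col)
    missing = [c for c in paired if c not in wide.columns]
    if missing:
        raise ValueError(f"conditions {missing} absent from the table")
    pair = wide[list(paired)].dropna()
    if pair.isna().any().any() or len(pair) < 2:
        raise ValueError("mismatched subject sets for the paired contrast")
    diffs = (pair[paired[0]] - pair[paired[1]]).to_numpy(dtype=float)
    if np.allclose(diffs, diffs[0]):
        lp = 1.0  # degenerate spread: normality test undefined, treat as pass
    else:
        lp = float(lilliefors(diffs, dist="norm")[1])
    t, p = sstats.ttest_rel(pair[paired[0]], pair[paired[1]])
    return ConditionComparison(
        tukey_table=tukey_table,
        lilliefors_p={f"{paired[0]}-{paired[1]}": lp},
        paired_t={f"{paired[0]}_vs_{paired[1]}": (float(t), float(p))},
    )


def erp_similarity(
    erp_a: np.ndarray,
    erp_b: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (0.300, 0.400),
) -> float:
    """Pearson correlation of two waveforms over the negative deflection window."""
    erp_a, erp_b, times = map(np.asarray, (erp_a, erp_b, times))
    if erp_a.shape != erp_b.shape or erp_a.shape != times.shape:
        raise ValueError("waveforms must share one time grid")
    m = (times >= window[0]) & (times <= window[1])
    a, b = erp_a[m], erp_b[m]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance segment; correlation undefined")
    return float(sstats.pearsonr(a, b)[0])


def power_extrapolation(
    values_a: np.ndarray,
    values_b: np.ndarray,
    replication_factor: int,
) -> dict[int, float]:
    """Paired-t p-value as the subject set is replicated k times.

    Each subject's paired values are duplicated k = 1..replication_factor
    times (identical behaviour assumed) and the paired t-test recomputed at
    each total n; the mean difference is fixed so the t statistic grows with
    sqrt(n) and p falls.
    """
    if replication_factor < 1:
        raise ValueError("replication_factor must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need matched pairs, at least 2 subjects")
    out: dict[int, float] = {}
    for k in range(1, replication_factor + 1):
        t, p = sstats.ttest_rel(np.tile(a, k), np.tile(b, k))
        out[k * len(a)] = float(p)
    return out
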