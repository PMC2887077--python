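"""Differential-expression signature between histology seed groups.

The chain mirrors a classic two-group microarray analysis on an
RMA-normalized (log2) probe x sample matrix:

1. per-gene median normalization (subtract each probe's median, log2 scale);
2. fold-change filter: keep probes with 2^|mean_log2(A) - mean_log2(B)|
   strictly greater than a threshold (default 2);
3. Welch's unequal-variance t-test on the surviving probes;
4. Benjamini-Hochberg step-up FDR on the survivors' p-values, retaining
   probes with q strictly below the FDR level (default 0.05).

The filter trail (n_input -> n_after_fc -> n_after_fdr) is recorded so a
run can be audited against the cohort it came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("bastage.signature")


class SignatureError(ValueError):
    """Invalid input to the signature-derivation chain."""


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


class FilterTrail(NamedTuple):
    n_input: int
    n_after_fc: int
    n_after_fdr: int


@dataclass(frozen=True)
class SignatureResult:
    """Outcome of the signature chain.

    ``table`` holds one row per fold-change survivor (probe IDs as index)
    with group means, signed log2 fold change, Welch t/df/p, BH q and
    direction.  ``probe_ids`` lists the retained signature probes
    (q < fdr), ordered by ascending q then p.
    """

    table: pd.DataFrame
    trail: FilterTrail
    group_labels: tuple[str, str]
    fc_threshold: float
    alpha: float
    fdr: float

    @property
    def probe_ids(self) -> list[str]:
        retained = self.table[self.table["retained"]]
        return list(retained.sort_values(["q_value", "p_value"]).index)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise SignatureError("empty expression matrix")
    if matrix.index.has_duplicates:
        raise SignatureError("duplicate probe IDs in expression matrix")
    if matrix.columns.has_duplicates:
        raise SignatureError("duplicate sample IDs in expression matrix")


def per_gene_median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each probe row's median (log2 scale).

    Idempotent; output row medians are zero to numerical tolerance.
    """
    _check_matrix(matrix)
    return matrix.sub(matrix.median(axis=1), axis=0)


def _resolve_groups(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[list[str], list[str]]:
    a, b = list(group_a), list(group_b)
    overlap = set(a) & set(b)
    if overlap:
        raise SignatureError(f"groups overlap: {sorted(overlap)}")
    for name, ids in (("group A", a), ("group B", b)):
        missing = set(ids) - set(matrix.columns)
        if missing:
            raise SignatureError(f"{name} samples absent from matrix: {sorted(missing)}")
        if len(ids) < 2:
            raise SignatureError(f"{name} needs >=2 samples, got {len(ids)}")
    return a, b


def fold_change_filter(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Retain probes whose between-group fold change strictly exceeds the cutoff.

    Fold change is computed on log2 group means: FC = 2^|mean(A) - mean(B)|,
    retained iff FC > fc_threshold (strict, so |delta log2| = 1 at the
    default cutoff is excluded).  Returns a frame indexed by the retained
    probes with columns mean_log2_a, mean_log2_b, log2_fold_change
    (signed, A minus B) and fold_change.
    """
    _check_matrix(matrix)
    if fc_threshold <= 0:
        raise SignatureError(f"fc_threshold must be positive, got {fc_threshold}")
    a, b = _resolve_groups(matrix, group_a, group_b)
    mean_a = matrix[a].mean(axis=1)
    mean_b = matrix[b].mean(axis=1)
    lfc = mean_a - mean_b
    fc = np.power(2.0, lfc.abs())
    keep = fc > fc_threshold
    out = pd.DataFrame(
        {
            "mean_log2_a": mean_a[keep],
            "mean_log2_b": mean_b[keep],
            "log2_fold_change": lfc[keep],
            "fold_change": fc[keep],
        }
    )
    out.index.name = matrix.index.name or "probe_id"
    return out


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (mean(x) - mean(y)) / sqrt(s2x/nx + s2y/ny) with unbiased
    variances; degrees of freedom by Welch-Satterthwaite; p two-sided
    from the Student-t distribution with that df.

    Degenerate inputs: both groups zero-variance with equal means gives
    (t=0, p=1); zero-variance with different means is flagged with a
    warning and returns p -> 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise SignatureError("welch_t needs >=2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        pooled_df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return WelchResult(0.0, pooled_df, 1.0)
        logger.warning(
            "welch_t: both groups have zero variance with unequal means; "
            "degenerate p -> 0"
        )
        t = np.inf if x.mean() > y.mean() else -np.inf
        return WelchResult(float(t), pooled_df, 0.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min over j with p_(j) >= p_(i) of (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise SignatureError("bh_adjust: empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise SignatureError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def derive_signature(
    matrix: pd.DataFrame,
    seed_groups: Mapping[str, Sequence[str]],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    fdr: float = 0.05,
    normalize: bool = True,
) -> SignatureResult:
    """Run the full signature chain between two labelled seed groups.

    Parameters
    ----------
    matrix
        log2 expression, probes x samples.
    seed_groups
        Mapping of exactly two group labels (e.g. ``inflammation``,
        ``fibrosis``) to disjoint sample-ID lists; the first label is the
        reference for the sign of the fold change ("up in <first label>"
        when positive).
    fc_threshold, alpha, fdr
        Fold-change cutoff (strict), raw-p cutoff, and BH FDR level.

    Notes
    -----
    Probes whose two groups are both zero-variance are excluded from
    testing with a logged warning rather than producing infinite t
    statistics.  The raw-p cutoff is subsumed by the FDR step at the
    default settings (any probe with q < 0.05 also has p < 0.05).
    """
    if len(seed_groups) != 2:
        raise SignatureError(
            f"seed_groups must contain exactly two groups, got {len(seed_groups)}"
        )
    (label_a, ids_a), (label_b, ids_b) = seed_groups.items()
    norm = per_gene_median_normalize(matrix) if normalize else matrix
    n_input = norm.shape[0]
    fc_table = fold_change_filter(norm, ids_a, ids_b, fc_threshold)
    n_after_fc = fc_table.shape[0]

    a, b = list(ids_a), list(ids_b)
    records = []
    for probe in fc_table.index:
        x = norm.loc[probe, a].to_numpy(dtype=float)
        y = norm.loc[probe, b].to_numpy(dtype=float)
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
            logger.warning("excluding zero-variance probe %s from testing", probe)
            continue
        records.append((probe, welch_t(x, y)))

    table = fc_table.copy()
    table = table.rename(
        columns={
            "mean_log2_a": f"mean_log2_{label_a}",
            "mean_log2_b": f"mean_log2_{label_b}",
        }
    )
    table["t_stat"] = np.nan
    table["df"] = np.nan
    table["p_value"] = np.nan
    table["q_value"] = np.nan
    if records:
        probes = [r[0] for r in records]
        table.loc[probes, "t_stat"] = [r[1].t for r in records]
        table.loc[probes, "df"] = [r[1].df for r in records]
        table.loc[probes, "p_value"] = [r[1].p for r in records]
        table.loc[probes, "q_value"] = bh_adjust([r[1].p for r in records])
    table["direction"] = np.where(
        table["log2_fold_change"] > 0, f"up_in_{label_a}", f"up_in_{label_b}"
    )
    table["retained"] = (table["q_value"] < fdr) & (table["p_value"] < alpha)
    n_after_fdr = int(table["retained"].sum())

    trail = FilterTrail(n_input, n_after_fc, n_after_fdr)
    logger.info(
        "signature filter trail: %d -> %d (FC > %g) -> %d (q < %g)",
        trail.n_input, trail.n_after_fc, fc_threshold, trail.n_after_fdr, fdr,
    )
    return SignatureResult(
        table=table,
        trail=trail,
        group_labels=(label_a, label_b),
        fc_threshold=fc_threshold,
        alpha=alpha,
        fdr=fdr,
    )
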