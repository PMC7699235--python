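"""Feature screening: z-scoring, presence/IQR/fold-change filters, permutation test.

Features (OTUs and metabolites) are screened before network construction:

1. z-score each feature across all N subjects (population SD, divisor N);
2. drop features present (non-zero) in fewer than 25% of samples;
3. drop features whose interquartile range ranks below the 11th percentile
   of all feature IQRs;
4. drop features with |log2 fold change| between case and control group
   means below 3.4;
5. drop features whose two-group label-permutation test, Benjamini-Hochberg
   adjusted across features, gives q > 0.05.

All filters are computed per feature on the full table and the survivor set
is their conjunction, so the cascade order affects only reporting.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, MergedDataset, TraitTable

logger = logging.getLogger(__name__)

# exhaustive label enumeration is used when the number of distinct
# case/control assignments does not exceed this
EXHAUSTIVE_LIMIT = 20_000

__all__ = [
    "Thresholds",
    "ZScoreMatrix",
    "FilterReport",
    "zscore",
    "presence_fraction",
    "presence_filter",
    "feature_iqr",
    "iqr_percentile_rank",
    "iqr_filter",
    "log_fold_change",
    "lfc_filter",
    "permutation_test",
    "bh_fdr",
    "select_features",
    "log2_stabilized",
]


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Screening thresholds; defaults follow the reference configuration."""

    min_presence: float = 0.25
    iqr_min_percentile: float = 11.0
    lfc_cutoff: float = 3.4
    alpha: float = 0.05
    n_perm: int = 10_000
    two_sided: bool = True
    pseudocount: float | None = None  # None -> half the smallest nonzero value


@dataclasses.dataclass
class ZScoreMatrix:
    """Row-standardized feature matrix.

    Each non-degenerate row has mean 0 and population SD 1 (divisor N).
    Constant rows cannot be standardized; they are flagged in
    ``degenerate`` and left as zeros rather than NaN.
    """

    values: pd.DataFrame
    degenerate: pd.Series

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclasses.dataclass
class FilterReport:
    """Per-feature audit of every filter plus the thresholds used."""

    table: pd.DataFrame
    thresholds: Thresholds

    @property
    def survivors(self) -> list:
        return list(self.table.index[self.table["pass_overall"]])

    @property
    def n_survivors(self) -> int:
        return int(self.table["pass_overall"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, FeatureTable):
        return table.data
    if isinstance(table, ZScoreMatrix):
        return table.values
    return pd.DataFrame(table)


def zscore(table: FeatureTable | pd.DataFrame) -> ZScoreMatrix:
    """Standardize each feature across subjects: z = (x - mean) / popSD.

    The population standard deviation (divisor N, not N-1) is used.
    Constant rows are flagged degenerate and zero-filled.
    """
    data = _as_frame(table)
    if data.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    vals = data.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    # relative tolerance: a constant row can carry roundoff-level spread
    degenerate = sd[:, 0] <= 1e-9 * (np.abs(mean[:, 0]) + 1.0)
    safe_sd = np.where(degenerate[:, None], 1.0, sd)
    z = (vals - mean) / safe_sd
    z[degenerate, :] = 0.0
    return ZScoreMatrix(
        pd.DataFrame(z, index=data.index, columns=data.columns),
        pd.Series(degenerate, index=data.index),
    )


def presence_fraction(table: FeatureTable | pd.DataFrame) -> pd.Series:
    data = _as_frame(table)
    return (data > 0).sum(axis=1) / data.shape[1]


def presence_filter(
    table: FeatureTable | pd.DataFrame, min_presence: float = 0.25
) -> pd.Series:
    """Pass iff the fraction of samples with a non-zero value is >= min_presence."""
    return presence_fraction(table) >= min_presence


def feature_iqr(table: FeatureTable | pd.DataFrame) -> pd.Series:
    data = _as_frame(table)
    q75 = data.quantile(0.75, axis=1)
    q25 = data.quantile(0.25, axis=1)
    return q75 - q25


def iqr_percentile_rank(table: FeatureTable | pd.DataFrame) -> pd.Series:
    """Percentile rank (0-100, average ties) of each feature's IQR among all."""
    iqr = feature_iqr(table)
    return iqr.rank(method="average") / len(iqr) * 100.0


def iqr_filter(
    table: FeatureTable | pd.DataFrame, min_percentile: float = 11.0
) -> pd.Series:
    """Pass iff the feature's IQR percentile rank is >= min_percentile.

    Ranks are averaged over ties, so a table of identical IQRs places every
    feature at the 50th percentile and all pass.
    """
    data = _as_frame(table)
    if data.shape[1] < 4:
        raise ValueError("IQR filtering needs at least 4 samples")
    return iqr_percentile_rank(table) >= min_percentile


def _split_groups(data: pd.DataFrame, traits: TraitTable):
    cond = traits.condition.reindex(data.columns)
    if cond.isna().any():
        raise ValueError("trait table missing samples present in feature table")
    case = data.loc[:, cond == 1]
    ctrl = data.loc[:, cond == 0]
    return case, ctrl


def log_fold_change(
    table: FeatureTable | pd.DataFrame,
    traits: TraitTable,
    pseudocount: float | None = None,
) -> pd.Series:
    """log2 of the ratio of case to control group means.

    A pseudocount (default: half the smallest non-zero value in the table)
    keeps the ratio finite; two all-zero group means give LFC 0.
    """
    data = _as_frame(table)
    case, ctrl = _split_groups(data, traits)
    if case.shape[1] == 0 or ctrl.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    if pseudocount is None:
        nonzero = data.to_numpy()[data.to_numpy() > 0]
        pseudocount = float(nonzero.min()) / 2.0 if nonzero.size else 1e-9
    return np.log2(
        (case.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount)
    )


def lfc_filter(lfc: pd.Series, cutoff: float = 3.4) -> pd.Series:
    """Pass iff |LFC| >= cutoff (boundary inclusive)."""
    return lfc.abs() >= cutoff


def _assignment_weights(n: int, case_idx: np.ndarray) -> np.ndarray:
    """Weight vector turning a sample matrix product into a group-mean difference."""
    n1 = case_idx.size
    n0 = n - n1
    w = np.full(n, -1.0 / n0)
    w[case_idx] = 1.0 / n1
    return w


def permutation_test(
    z: ZScoreMatrix | pd.DataFrame,
    traits: TraitTable,
    n_perm: int = 10_000,
    seed: int | None = 0,
    two_sided: bool = True,
) -> pd.Series:
    """Label-permutation test of equal group means, per feature.

    The statistic is the difference of case and control means of the
    (z-scored) feature. When the number of distinct case/control label
    assignments C(N, n_case) is at most 20,000 every assignment is
    enumerated and p is the exact tail fraction; otherwise ``n_perm``
    Monte-Carlo permutations are drawn with the add-one correction
    p = (1 + #{|T_perm| >= |T_obs|}) / (B + 1).
    """
    data = _as_frame(z)
    cond = traits.condition.reindex(data.columns).to_numpy()
    case_idx = np.flatnonzero(cond == 1)
    ctrl_idx = np.flatnonzero(cond == 0)
    if case_idx.size < 2 or ctrl_idx.size < 2:
        raise ValueError("permutation test needs >= 2 samples per group")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    x = data.to_numpy(dtype=float)
    n = x.shape[1]
    t_obs = x @ _assignment_weights(n, case_idx)
    n_assign = math.comb(n, case_idx.size)
    if n_assign <= EXHAUSTIVE_LIMIT:
        w = np.column_stack(
            [
                _assignment_weights(n, np.asarray(c))
                for c in combinations(range(n), case_idx.size)
            ]
        )
        t_perm = x @ w  # features x assignments
        if two_sided:
            hits = np.abs(t_perm) >= np.abs(t_obs)[:, None] - 1e-12
        else:
            hits = t_perm >= t_obs[:, None] - 1e-12
        p = hits.sum(axis=1) / n_assign
    else:
        rng = np.random.default_rng(seed)
        w = np.column_stack(
            [
                _assignment_weights(
                    n, rng.choice(n, size=case_idx.size, replace=False)
                )
                for _ in range(n_perm)
            ]
        )
        t_perm = x @ w
        if two_sided:
            hits = np.abs(t_perm) >= np.abs(t_obs)[:, None] - 1e-12
        else:
            hits = t_perm >= t_obs[:, None] - 1e-12
        p = (1.0 + hits.sum(axis=1)) / (n_perm + 1.0)
    return pd.Series(p, index=data.index)


def bh_fdr(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    index = pvalues.index if isinstance(pvalues, pd.Series) else None
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pd.Series(dtype=float) if index is not None else p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return pd.Series(q, index=index) if index is not None else q


def select_features(
    dataset: MergedDataset,
    thresholds: Thresholds = Thresholds(),
    seed: int | None = 0,
) -> tuple[ZScoreMatrix, FilterReport]:
    """Run the whole screening cascade and return survivors' z-scores + audit.

    Filters applied (reported in this order): presence -> IQR -> degenerate
    row exclusion -> log fold change -> permutation test with BH FDR at
    q <= alpha. Every statistic is computed for every feature; the overall
    pass is the conjunction, so no filter's decision depends on another's.
    An empty survivor set is a valid outcome, not an error.
    """
    table = dataset.features
    traits = dataset.traits
    th = thresholds
    z = zscore(table)

    pres_frac = presence_fraction(table)
    pres_pass = pres_frac >= th.min_presence
    iqr = feature_iqr(table)
    iqr_rank = iqr_percentile_rank(table)
    iqr_pass = iqr_rank >= th.iqr_min_percentile
    not_degenerate = ~z.degenerate
    case, ctrl = _split_groups(table.data, traits)
    lfc = log_fold_change(table, traits, th.pseudocount)
    lfc_pass = lfc_filter(lfc, th.lfc_cutoff)
    perm_p = permutation_test(
        z, traits, n_perm=th.n_perm, seed=seed, two_sided=th.two_sided
    )
    q = bh_fdr(perm_p)
    q_pass = q <= th.alpha

    overall = pres_pass & iqr_pass & not_degenerate & lfc_pass & q_pass
    report = pd.DataFrame(
        {
            "kind": table.kind,
            "presence_fraction": pres_frac,
            "presence_pass": pres_pass,
            "iqr": iqr,
            "iqr_percentile_rank": iqr_rank,
            "iqr_pass": iqr_pass,
            "degenerate": z.degenerate,
            "mean_case": case.mean(axis=1),
            "mean_ctrl": ctrl.mean(axis=1),
            "log2_fold_change": lfc,
            "lfc_pass": lfc_pass,
            "perm_p": perm_p,
            "q_value": q,
            "q_pass": q_pass,
            "pass_overall": overall,
        }
    )
    kept = report.index[overall]
    if len(kept) == 0:
        logger.info("screening retained no features")
    filtered = ZScoreMatrix(
        z.values.loc[kept], z.degenerate.loc[kept]
    )
    return filtered, FilterReport(report, th)


def log2_stabilized(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """log2-transformed abundances with a half-minimum pseudocount.

    Variance-stabilizing transform applied before co-expression analysis:
    abundance tables are strongly right-skewed, and Pearson correlations
    on the raw scale are attenuated and outlier-driven. Zeros map to
    log2(pseudocount) with pseudocount = half the smallest non-zero value.
    """
    data = _as_frame(table)
    vals = data.to_numpy()
    nonzero = vals[vals > 0]
    pseudo = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    return np.log2(data + pseudo)
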