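"""Two-group differential statistics on log2 omics matrices.

The differential contract is deliberately generic: a Welch two-sample t
test per feature on log2 abundances, Benjamini–Hochberg adjustment across
all tested features, and strict threshold filters on the linear-scale
fold change and the FDR.  The same contract serves TMT-style proteome
matrices and log-transformed transcript matrices; externally computed
results (e.g. a count-model RNA fit) can be fed through the same TSV
schema instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmicsMatrix",
    "ThresholdSpec",
    "welch_t",
    "differential_test",
    "apply_thresholds",
    "concordance_venn4",
    "read_matrix",
    "read_groups",
    "RNA_THRESHOLDS",
    "PROTEIN_THRESHOLDS",
    "CLINICAL_THRESHOLDS",
]

logger = logging.getLogger(__name__)


@dataclass
class OmicsMatrix:
    """A feature × sample grid of log2 abundances with group labels."""

    values: pd.DataFrame  # features on rows, samples on columns
    group_of: Mapping[str, str]  # sample -> group label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        unlabeled = [s for s in self.values.columns if s not in self.group_of]
        if unlabeled:
            raise ValueError(f"samples without group label: {unlabeled}")
        if self.values.isna().any().any():
            logger.warning(
                "matrix contains %d missing values (pairwise-complete per feature)",
                int(self.values.isna().sum().sum()),
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]


@dataclass(frozen=True)
class ThresholdSpec:
    """Linear-scale fold-change and FDR bounds, strict comparisons."""

    min_abs_fold: float
    max_fdr: float

    def __post_init__(self) -> None:
        if not self.min_abs_fold > 1:
            raise ValueError("min_abs_fold must exceed 1 (linear scale)")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must lie in (0, 1)")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_abs_fold)


#: |fold change| > 4, FDR < 0.01 — transcript-level filter
RNA_THRESHOLDS = ThresholdSpec(min_abs_fold=4.0, max_fdr=0.01)
#: |fold change| > 1.5, FDR < 0.05 — protein-level filter
PROTEIN_THRESHOLDS = ThresholdSpec(min_abs_fold=1.5, max_fdr=0.05)
#: log2 fold change > 1, BH-adjusted p < 0.05 — tumor-vs-normal filter
CLINICAL_THRESHOLDS = ThresholdSpec(min_abs_fold=2.0, max_fdr=0.05)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch two-sample t test; the single shared implementation.

    Group-score comparisons elsewhere in the package route through this
    function so results match bit-for-bit.
    """
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def differential_test(
    m: OmicsMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-feature Welch t on log2 values, B-vs-A, with BH adjustment.

    ``log2fc = mean(group B) − mean(group A)``.  Features with fewer than
    two usable (non-missing) samples in either group get an undefined p
    and are excluded from the BH adjustment; their count is logged.
    Returns a DataFrame indexed by feature with columns ``log2fc``, ``p``,
    ``fdr``, ``n_a``, ``n_b``, ``tested``.
    """
    cols_a = m.samples_in(group_a)
    cols_b = m.samples_in(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"no samples for group {group_a!r} or {group_b!r}")
    va = m.values[cols_a].to_numpy(dtype=float)
    vb = m.values[cols_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(va), axis=1)
    n_b = np.sum(~np.isnan(vb), axis=1)
    log2fc = np.nanmean(vb, axis=1) - np.nanmean(va, axis=1)
    tested = (n_a >= 2) & (n_b >= 2)
    p = np.full(len(m.values), np.nan)
    if tested.any():
        res = stats.ttest_ind(
            vb[tested], va[tested], axis=1, equal_var=False, nan_policy="omit"
        )
        p[tested] = np.asarray(res.pvalue, dtype=float)
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.warning(
            "%d features had <2 usable samples in a group; excluded from BH",
            n_skipped,
        )
    fdr = np.full(len(m.values), np.nan)
    if tested.any():
        fdr[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "n_a": n_a,
            "n_b": n_b,
            "tested": tested,
        },
        index=m.values.index.rename("feature_id"),
    )


def apply_thresholds(
    results: pd.DataFrame, spec: ThresholdSpec
) -> tuple[set[str], set[str]]:
    """Strict-inequality up/down calls: (|log2fc| > log2 bound, fdr < bound)."""
    bound = spec.min_abs_log2fc
    ok = results["fdr"] < spec.max_fdr  # NaN fdr never passes
    up = set(results.index[ok & (results["log2fc"] > bound)])
    down = set(results.index[ok & (results["log2fc"] < -bound)])
    return up, down


def concordance_venn4(
    rna_up: Iterable[str],
    rna_down: Iterable[str],
    prot_up: Iterable[str],
    prot_down: Iterable[str],
) -> dict[str, set[str]]:
    """Four-way mRNA/protein concordance partition.

    Every feature in the union of the four input sets is assigned to
    exactly one region of the four-set diagram; ``concordant_down`` is
    the headline region (down at both the RNA and protein level).
    """
    ru, rd = set(rna_up), set(rna_down)
    pu, pd_ = set(prot_up), set(prot_down)
    if ru & rd:
        raise ValueError(f"features both RNA-up and RNA-down: {sorted(ru & rd)}")
    if pu & pd_:
        raise ValueError(
            f"features both protein-up and protein-down: {sorted(pu & pd_)}"
        )
    regions = {
        "concordant_up": ru & pu,
        "concordant_down": rd & pd_,
        "rna_up_protein_down": ru & pd_,
        "rna_down_protein_up": rd & pu,
        "rna_up_only": ru - pu - pd_,
        "rna_down_only": rd - pu - pd_,
        "protein_up_only": pu - ru - rd,
        "protein_down_only": pd_ - ru - rd,
    }
    return regions


def read_matrix(path) -> pd.DataFrame:
    """Matrix TSV: first column feature ID, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_groups(path) -> dict[str, str]:
    """Two-column TSV mapping sample -> group label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
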