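"""Differential expression and ceRNA coexpression analysis.

The study design is a case/control expression matrix (diabetic-retinopathy
versus normal retina).  Differential expression is called per gene by a
two-sided Welch t-test on log2 values combined with a linear-scale
fold-change gate (defaults p < 0.05 and FC 1.5); functional ceRNA pairs
are screened by Pearson correlation across all samples (default p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Genes x samples of non-negative abundances plus a sample->group map.

    ``values`` rows are genes, columns are samples.  ``groups`` maps every
    sample id to ``"case"`` or ``"control"``.  Missing values are a hard
    error: imputation is out of scope.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        unknown = set(self.groups.values()) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown sample groups {sorted(unknown)}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def require_testable(self) -> None:
        for g in GROUPS:
            if len(self.samples(g)) < 2:
                raise ValidationError(
                    f"group {g!r} has fewer than 2 samples; t-test undefined"
                )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a new matrix with x -> log2(x + pseudocount)."""
    if (m.values.to_numpy() < 0).any():
        raise ValidationError("log2 transform requires non-negative values")
    return ExpressionMatrix(np.log2(m.values + pseudocount), dict(m.groups))


def welch_ttest(x: np.ndarray, y: np.ndarray, equal_var: bool = False):
    """Two-sided t-test along the last axis; rows with zero variance in
    both groups and equal means get t=0, p=1 by convention."""
    t, p = stats.ttest_ind(x, y, axis=-1, equal_var=equal_var)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    bad = ~np.isfinite(p)
    if bad.any():
        eq = np.isclose(
            np.atleast_1d(x.mean(axis=-1)), np.atleast_1d(y.mean(axis=-1))
        )
        t[bad & eq] = 0.0
        p[bad & eq] = 1.0
        p[bad & ~eq] = np.nan
    return t, p


def differential_expression(
    m: ExpressionMatrix,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
    equal_var: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 values + linear fold-change gate.

    Fold change is the linear-scale case/control ratio of group means; a
    gene is significant iff p < ``p_cutoff`` and FC >= ``fc_cutoff`` or
    <= 1/``fc_cutoff``.  A BH-adjusted column is emitted for reference but
    does not drive the flag (the thresholds are on the raw p-value).
    """
    m.require_testable()
    case = m.samples("case")
    ctrl = m.samples("control")
    lin = m.values
    logm = np.log2(lin + pseudocount)
    t, p = welch_ttest(
        logm[case].to_numpy(), logm[ctrl].to_numpy(), equal_var=equal_var
    )
    mean_case = lin[case].mean(axis=1).to_numpy()
    mean_ctrl = lin[ctrl].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctrl > 0, mean_case / mean_ctrl, np.inf)
        log2fc = np.log2(fc)
    padj = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1]
    sig = (p < p_cutoff) & ((fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff))
    return pd.DataFrame(
        {
            "gene": m.values.index,
            "t": t,
            "p": p,
            "p_bh": padj,
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "significant": sig,
        }
    ).set_index("gene")


def coexpression(
    pairs: list[tuple[str, str]],
    m: ExpressionMatrix,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation across all samples for (lncRNA, gene) pairs.

    p-values follow the t transform r*sqrt((n-2)/(1-r^2)) with n-2 df.
    Pairs involving a constant vector get r = NaN and are not significant.
    """
    n = m.values.shape[1]
    if n < 3:
        raise ValidationError("coexpression requires at least 3 samples")
    rows = []
    for lnc, gene in pairs:
        for member in (lnc, gene):
            if member not in m.values.index:
                raise ValidationError(f"{member!r} not in expression matrix")
        x = m.values.loc[lnc].to_numpy(dtype=float)
        y = m.values.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((lnc, gene, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((lnc, gene, r, p, bool(p < p_cutoff)))
    return pd.DataFrame(
        rows, columns=["lncrna", "gene", "r", "p", "significant"]
    )


def read_expression_tsv(matrix_path: str, groups_path: str) -> ExpressionMatrix:
    """Load a genes-as-rows TSV plus a two-column (sample, group) TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values, groups)


def write_expression_tsv(
    m: ExpressionMatrix, matrix_path: str, groups_path: str
) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": list(m.values.columns),
         "group": [m.groups[s] for s in m.values.columns]}
    ).to_csv(groups_path, sep="\t", index=False)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (order preserved)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
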