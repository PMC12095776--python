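"""Replicate-group enrichment statistics for protein abundance tables.

Fold-changes are ratios of linear-scale group means; significance comes
from a two-sample two-tailed Student's t-test, by default computed on
log2-transformed abundances (the usual convention for label-free
quantification, LFQ).  Two uses are covered:

* OOPS RNA-binding-proteome calling: proteins enriched in the RNase+
  eluate over the no-RNase control (fold-change >= 2, p <= 0.05) are
  called RNA-binding proteins (RBPs).
* ChIRP-MS-style capture analysis, where proteins detected exclusively in
  the capture get an artificial control mean of 100 so that their
  fold-change is finite and they can appear on a volcano plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Config, ValidationError


class UndefinedStatisticError(ValueError):
    """Fewer than two usable values in a replicate group."""


@dataclass
class EnrichmentRecord:
    """Per-protein enrichment of a treatment group over a control group."""

    protein_id: str
    treat_values: np.ndarray
    ctrl_values: np.ndarray
    fold_change: float      # treat mean / ctrl mean, linear scale
    log2_fc: float
    p_value: float
    ctrl_imputed: bool = False


def abundance_floor(*value_sets: np.ndarray) -> float:
    """Half the smallest nonzero abundance, used to replace zeros before
    log transformation.  Falls back to 1.0 when everything is zero."""
    pooled = np.concatenate([np.asarray(v, dtype=float).ravel()
                             for v in value_sets])
    nonzero = pooled[pooled > 0]
    return float(nonzero.min()) / 2.0 if nonzero.size else 1.0


def _group_stats(values: np.ndarray, label: str, protein_id: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise UndefinedStatisticError(
            f"{protein_id or 'protein'}: {label} group has fewer than 2 "
            f"finite values")
    if (arr < 0).any():
        raise ValidationError(
            f"{protein_id or 'protein'}: negative abundance in {label} group")
    return arr


def enrichment_test(treat, ctrl, log_transform: bool = True,
                    equal_var: bool = True, floor: float | None = None,
                    protein_id: str = "", ctrl_imputed: bool = False,
                    ) -> EnrichmentRecord:
    """Fold-change and two-tailed t-test p-value for one protein.

    Parameters
    ----------
    treat, ctrl
        Replicate abundances (e.g. RNase+ eluate vs no-RNase control LFQ).
    log_transform
        Run the t-test on log2 abundances (default).  Zeros are replaced
        by ``floor`` (half the smallest nonzero value of the two groups
        when not given) before taking logs.
    equal_var
        Pooled-variance Student's form (default); False gives Welch.

    Notes
    -----
    Two groups that are both constant yield p = 1 when their means are
    equal and p = 0 otherwise, by convention (no within-group variance to
    test against).  The fold-change is always the ratio of raw linear
    means; it is ``inf`` when the control mean is zero.
    """
    t_arr = _group_stats(treat, "treatment", protein_id)
    c_arr = _group_stats(ctrl, "control", protein_id)

    t_mean, c_mean = t_arr.mean(), c_arr.mean()
    if c_mean > 0:
        fc = t_mean / c_mean
    else:
        fc = float("inf") if t_mean > 0 else float("nan")
    with np.errstate(divide="ignore"):
        log2_fc = float(np.log2(fc)) if fc == fc else float("nan")

    if log_transform:
        if floor is None:
            floor = abundance_floor(t_arr, c_arr)
        t_test = np.log2(np.where(t_arr > 0, t_arr, floor))
        c_test = np.log2(np.where(c_arr > 0, c_arr, floor))
    else:
        t_test, c_test = t_arr, c_arr

    if np.ptp(t_test) == 0 and np.ptp(c_test) == 0:
        p = 1.0 if t_test.mean() == c_test.mean() else 0.0
    else:
        p = float(stats.ttest_ind(t_test, c_test, equal_var=equal_var).pvalue)

    return EnrichmentRecord(protein_id=protein_id,
                            treat_values=t_arr, ctrl_values=c_arr,
                            fold_change=float(fc), log2_fc=log2_fc,
                            p_value=p, ctrl_imputed=ctrl_imputed)


def impute_all_zero_controls(ctrl: pd.DataFrame,
                             imputed_mean: float = 100.0,
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """ChIRP-MS zero-control rule.

    Any protein whose control values are *all* zero gets every control
    value set to ``imputed_mean`` (so the group mean equals it), enabling
    a finite fold-change for capture-exclusive proteins.  Groups with at
    least one nonzero value are untouched.

    Returns the adjusted table and a boolean mask of imputed rows.
    """
    mask = (ctrl == 0).all(axis=1)
    out = ctrl.copy().astype(float)
    out.loc[mask, :] = imputed_mean
    return out, mask


def enrichment_table(treat: pd.DataFrame, ctrl: pd.DataFrame,
                     log_transform: bool = True, equal_var: bool = True,
                     impute_zero_ctrl: bool = False,
                     floor: float | None = None,
                     add_bh: bool = False) -> pd.DataFrame:
    """Run :func:`enrichment_test` on every shared protein of two tables.

    Rows are proteins, columns replicates.  A single abundance floor is
    derived from the whole pair of tables so that zero replacement is
    consistent across proteins.  ``impute_zero_ctrl`` applies the ChIRP-MS
    all-zero-control rule first.  ``add_bh`` appends Benjamini-Hochberg
    adjusted p-values as an extra column (the RBP gate itself uses raw p).
    """
    shared = treat.index.intersection(ctrl.index)
    treat = treat.loc[shared]
    ctrl = ctrl.loc[shared]

    imputed = pd.Series(False, index=shared)
    if impute_zero_ctrl:
        ctrl, imputed = impute_all_zero_controls(ctrl)
    if floor is None:
        floor = abundance_floor(treat.to_numpy(), ctrl.to_numpy())

    rows = []
    for pid in shared:
        rec = enrichment_test(treat.loc[pid].to_numpy(),
                              ctrl.loc[pid].to_numpy(),
                              log_transform=log_transform,
                              equal_var=equal_var, floor=floor,
                              protein_id=str(pid),
                              ctrl_imputed=bool(imputed.loc[pid]))
        rows.append((rec.protein_id, rec.fold_change, rec.log2_fc,
                     rec.p_value, rec.ctrl_imputed))
    out = pd.DataFrame(rows, columns=["protein_id", "fold_change", "log2_fc",
                                      "p_value", "ctrl_imputed"])
    out = out.set_index("protein_id")
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    if add_bh:
        from statsmodels.stats.multitest import multipletests
        out["q_value"] = multipletests(out["p_value"].to_numpy(),
                                       method="fdr_bh")[1]
    return out


def call_rbps(table: pd.DataFrame, cfg: Config) -> set[str]:
    """Proteins passing the RBP gate: fold_change >= cfg.oops_fc_min AND
    p_value <= cfg.oops_p_max."""
    ok = (table["fold_change"] >= cfg.oops_fc_min) & \
         (table["p_value"] <= cfg.oops_p_max)
    return set(table.index[ok].astype(str))
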