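"""The GRADR engine: correlate co-sedimentation profiles, filter, rank.

For a query RNA the candidate interactors are the proteins that

1. are called RNA-binding proteins (OOPS RNase+/- fold-change >= 2,
   p <= 0.05),
2. are eligible for the RNA's compartment (detected there in all
   replicates and not predominantly in the opposing compartment), and
3. for nuclear RNAs, are not mitochondrial.

Each candidate is scored by the Pearson correlation between its gradient
sedimentation profile and the RNA's; candidates are sorted by descending
r and those with r >= 0.5 are the predicted interactors.  Pearson r is
invariant to per-profile affine transforms, so correlations computed on
raw linear profiles equal those computed on row-Z-scored profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import Config, GradientMatrix, ValidationError
from .localization import (LocalizationRecord, call_rna_compartment,
                           protein_compartment_eligibility)

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["rna_id", "protein_id", "pearson_r", "oops_fc",
                      "oops_p", "compartment", "passed", "rank"]


class DegenerateProfileError(ValidationError):
    """A constant sedimentation profile has no defined correlation."""


def zscore_profile(profile: Sequence[float]) -> np.ndarray:
    """Row-Z-score one sedimentation profile (mean 0, sd 1 across fractions)."""
    arr = np.asarray(profile, dtype=float)
    if np.ptp(arr) == 0:  # exact range check; std of a constant can be ~1e-16
        raise DegenerateProfileError("constant profile cannot be Z-scored")
    return (arr - arr.mean()) / arr.std()


def profile_pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation between two equal-length profiles."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("profiles have different numbers of fractions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateProfileError("constant profile has undefined "
                                     "correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    return float((xc * yc).sum() / (sx * sy))


@dataclass
class CombinedDataset:
    """Every evidence layer GRADR combines, in one object.

    ``oops`` is the per-protein enrichment table (fold_change, p_value)
    used to report OOPS statistics alongside predictions; ``rbp_ids`` is
    the set passing the RBP gate.  Entities referenced by one layer but
    missing from another are logged and skipped, never imputed.
    """

    rna_profiles: GradientMatrix
    protein_profiles: GradientMatrix
    rbp_ids: set[str]
    localization: dict[str, LocalizationRecord]
    mito_ids: set[str] = field(default_factory=set)
    oops: pd.DataFrame | None = None

    def oops_stats(self, protein_id: str) -> tuple[float, float]:
        if self.oops is not None and protein_id in self.oops.index:
            row = self.oops.loc[protein_id]
            return float(row["fold_change"]), float(row["p_value"])
        return (float("nan"), float("nan"))


def eligible_proteins(ds: CombinedDataset, compartment: str,
                      cfg: Config) -> set[str]:
    """Proteins with a profile that pass the compartment eligibility rule."""
    out = set()
    for pid in ds.protein_profiles.entity_ids:
        rec = ds.localization.get(str(pid))
        if rec is None:
            logger.info("protein %s has no localization record; skipped", pid)
            continue
        if protein_compartment_eligibility(rec, compartment, cfg):
            out.add(str(pid))
    return out


def predict_interactors(rna_id: str, ds: CombinedDataset, cfg: Config,
                        ) -> pd.DataFrame:
    """Rank candidate protein interactors of one RNA.

    Returns the full candidate table (one row per scored protein) sorted
    by descending Pearson r with protein_id as the deterministic
    tie-break; ``passed`` marks rows with r >= cfg.r_min, and ``rank``
    numbers the passing rows 1..k from the top.
    """
    if rna_id not in ds.rna_profiles.entity_ids:
        raise KeyError(f"unknown RNA {rna_id!r}: no gradient profile")
    rec = ds.localization.get(rna_id)
    if rec is None:
        raise ValidationError(f"RNA {rna_id!r} has no localization record")
    compartment = call_rna_compartment(rec, cfg)
    if compartment == "ambiguous":
        raise ValidationError(f"RNA {rna_id!r}: compartment call is ambiguous")

    rna_profile = ds.rna_profiles.profile(rna_id)
    if np.ptp(rna_profile) == 0:
        raise DegenerateProfileError(f"RNA {rna_id!r} has a constant profile")

    candidates = ds.rbp_ids & eligible_proteins(ds, compartment, cfg)
    if compartment == "nuclear":
        candidates -= set(ds.mito_ids)

    rows = []
    for pid in sorted(candidates):
        try:
            r = profile_pearson(rna_profile, ds.protein_profiles.profile(pid))
        except DegenerateProfileError:
            logger.info("protein %s: degenerate profile; pair (%s, %s) "
                        "skipped", pid, rna_id, pid)
            continue
        fc, p = ds.oops_stats(pid)
        rows.append((rna_id, pid, r, fc, p, compartment, r >= cfg.r_min))

    out = pd.DataFrame(rows, columns=PREDICTION_COLUMNS[:-1])
    out = out.sort_values(["pearson_r", "protein_id"],
                          ascending=[False, True], kind="mergesort")
    out = out.reset_index(drop=True)
    out["rank"] = pd.array([i + 1 if ok else None
                            for i, ok in enumerate(out["passed"])],
                           dtype="Int64")
    return out


def interactome_all(ds: CombinedDataset, cfg: Config,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict interactors for every RNA with a profile.

    Returns the long-format prediction table and a per-RNA summary
    (compartment, candidate and passing counts, or the skip reason).
    """
    tables, summary = [], []
    for rna_id in ds.rna_profiles.entity_ids:
        rna_id = str(rna_id)
        try:
            tab = predict_interactors(rna_id, ds, cfg)
        except (ValidationError, KeyError) as exc:
            logger.warning("RNA %s skipped: %s", rna_id, exc)
            summary.append((rna_id, "skipped", 0, 0, str(exc)))
            continue
        tables.append(tab)
        compartment = tab["compartment"].iloc[0] if len(tab) else "n/a"
        summary.append((rna_id, compartment, len(tab),
                        int(tab["passed"].sum()), ""))
    long = (pd.concat(tables, ignore_index=True) if tables
            else pd.DataFrame(columns=PREDICTION_COLUMNS))
    summ = pd.DataFrame(summary, columns=["rna_id", "compartment",
                                          "n_candidates", "n_passed", "note"])
    return long, summ


def interactor_correlation_matrix(protein_ids: Iterable[str],
                                  ds: CombinedDataset,
                                  ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Pairwise profile-correlation matrix plus average-linkage clustering.

    Returns the symmetric Pearson matrix (unit diagonal), the scipy
    linkage on distance 1 - r, and the leaf order (protein ids).
    """
    ids = []
    profiles = []
    for pid in sorted(map(str, set(protein_ids))):
        if pid not in ds.protein_profiles.entity_ids:
            logger.info("protein %s has no profile; excluded from matrix", pid)
            continue
        prof = ds.protein_profiles.profile(pid)
        if np.ptp(prof) == 0:
            logger.info("protein %s: degenerate profile; excluded", pid)
            continue
        ids.append(pid)
        profiles.append(prof)
    if len(ids) < 2:
        raise ValidationError("need at least 2 proteins with non-degenerate "
                              "profiles")
    mat = np.corrcoef(np.asarray(profiles))
    np.fill_diagonal(mat, 1.0)
    corr = pd.DataFrame(mat, index=ids, columns=ids)
    dist = squareform(1.0 - mat, checks=False)
    linkage = hierarchy.linkage(dist, method="average")
    leaves = [ids[i] for i in hierarchy.leaves_list(linkage)]
    return corr, linkage, leaves


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        ld = max(node.dist - node.get_left().dist, 0.0)
        rd = max(node.dist - node.get_right().dist, 0.0)
        return f"({left}:{ld:.6g},{right}:{rd:.6g})"

    return walk(tree) + ";"
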