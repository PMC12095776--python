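"""Cytoplasm/nucleus quantification and compartment calls.

RNA abundances from fractionation RNA-seq are first put on a common scale
using an equal-mass E. coli spike-in: each sample's RPKMs are divided by
the percentage of reads mapping to the spike-in, so samples with less
endogenous RNA (a larger spike share) are scaled down.  Per-entity signal
is then summarised as percent cytoplasmic / percent nuclear per replicate.

Compartment rules:

* RNAs are called cytoplasmic when their mean percent-cytoplasmic signal
  across usable replicates exceeds 50% (configurable); ties go to nuclear.
* A protein is eligible for the cytoplasmic branch of the interactome
  prediction when it is detected (signal > 0) in the cytoplasmic fraction
  in ALL replicates and is NOT >= 60% nuclear in ALL replicates; the
  nuclear rule mirrors this.  The two rules are not a partition - a
  protein near 50/50 can be eligible for both compartments.
* Mitochondrial proteins are removed from nuclear-RNA predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_io import Config, FormatError, ValidationError

COMPARTMENTS = ("cytoplasmic", "nuclear")


# ---------------------------------------------------------------------------
# spike-in normalization
# ---------------------------------------------------------------------------

@dataclass
class SpikeInSample:
    """Uniquely mapping read counts for one fractionation RNA-seq sample."""

    sample_id: str
    human_reads: int
    spike_reads: int

    def __post_init__(self) -> None:
        if self.human_reads < 0 or self.spike_reads < 0:
            raise ValidationError(f"{self.sample_id}: negative read count")

    @property
    def spike_fraction(self) -> float:
        total = self.human_reads + self.spike_reads
        if total == 0:
            raise ValidationError(f"{self.sample_id}: no reads at all")
        return self.spike_reads / total

    @property
    def spike_percent(self) -> float:
        return 100.0 * self.spike_fraction


def read_spikein_table(path) -> dict[str, SpikeInSample]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "human_reads", "spike_reads"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = {}
    for _, row in df.iterrows():
        s = SpikeInSample(sample_id=str(row["sample_id"]),
                          human_reads=int(row["human_reads"]),
                          spike_reads=int(row["spike_reads"]))
        out[s.sample_id] = s
    return out


def write_spikein_table(samples: Mapping[str, SpikeInSample], path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.human_reads, s.spike_reads)
         for s in samples.values()],
        columns=["sample_id", "human_reads", "spike_reads"])
    df.to_csv(path, sep="\t", index=False)


def spikein_normalize(rpkm: pd.DataFrame,
                      samples: Mapping[str, SpikeInSample],
                      mode: str = "divide") -> pd.DataFrame:
    """Scale each sample's RPKM by its E. coli spike-in read percentage.

    ``mode="divide"`` (default): normalized = RPKM / spike_percent, so a
    sample where the fixed-mass spike-in makes up more of the library
    (i.e. less endogenous RNA) is scaled down.  ``mode="multiply"``
    provides the opposite reading.
    """
    if mode not in ("divide", "multiply"):
        raise ValidationError(f"unknown spike-in mode {mode!r}")
    out = rpkm.astype(float).copy()
    for sid in rpkm.columns:
        if sid not in samples:
            raise ValidationError(f"sample {sid!r} has no spike-in record")
        s = samples[sid]
        if s.spike_reads == 0:
            raise ValidationError(
                f"sample {sid!r}: zero spike-in reads, normalization undefined")
        if mode == "divide":
            out[sid] = out[sid] / s.spike_percent
        else:
            out[sid] = out[sid] * s.spike_percent
    return out


# ---------------------------------------------------------------------------
# localization records
# ---------------------------------------------------------------------------

def percent_compartment(cyt: float, nuc: float) -> tuple[float, float]:
    """(percent cytoplasmic, percent nuclear); (nan, nan) when both zero."""
    if cyt < 0 or nuc < 0:
        raise ValidationError("compartment signals must be non-negative")
    total = cyt + nuc
    if total == 0:
        return (math.nan, math.nan)
    pct_cyt = 100.0 * cyt / total
    return (pct_cyt, 100.0 - pct_cyt)


@dataclass
class LocalizationRecord:
    """Per-replicate cytoplasmic and nuclear signal for one entity."""

    entity_id: str
    entity_class: str
    cyt_signal: np.ndarray
    nuc_signal: np.ndarray

    def __post_init__(self) -> None:
        self.cyt_signal = np.asarray(self.cyt_signal, dtype=float).ravel()
        self.nuc_signal = np.asarray(self.nuc_signal, dtype=float).ravel()
        if self.cyt_signal.shape != self.nuc_signal.shape:
            raise ValidationError(
                f"{self.entity_id}: replicate counts differ between "
                f"compartments")
        if (self.cyt_signal < 0).any() or (self.nuc_signal < 0).any():
            raise ValidationError(f"{self.entity_id}: negative signal")

    @property
    def n_replicates(self) -> int:
        return self.cyt_signal.size

    @property
    def pct_cytoplasmic(self) -> np.ndarray:
        """Per-replicate percent cytoplasmic; nan for zero-signal replicates."""
        return np.array([percent_compartment(c, n)[0]
                         for c, n in zip(self.cyt_signal, self.nuc_signal)])

    @property
    def pct_nuclear(self) -> np.ndarray:
        return np.array([percent_compartment(c, n)[1]
                         for c, n in zip(self.cyt_signal, self.nuc_signal)])

    @property
    def mean_pct_cytoplasmic(self) -> float:
        """Mean over replicates with nonzero total signal; nan if none."""
        pct = self.pct_cytoplasmic
        usable = pct[~np.isnan(pct)]
        return float(usable.mean()) if usable.size else math.nan


def localization_records(cyt: pd.DataFrame, nuc: pd.DataFrame,
                         entity_class: str) -> dict[str, LocalizationRecord]:
    """Build records from two replicate tables (entities x replicates).

    Entities present in only one table get zero signal in the other
    compartment (absence of detection).
    """
    if cyt.shape[1] != nuc.shape[1]:
        raise FormatError("cytoplasmic and nuclear tables have different "
                          "replicate counts")
    n_rep = cyt.shape[1]
    all_ids = cyt.index.union(nuc.index)
    out = {}
    for eid in all_ids:
        c = cyt.loc[eid].to_numpy(dtype=float) if eid in cyt.index \
            else np.zeros(n_rep)
        n = nuc.loc[eid].to_numpy(dtype=float) if eid in nuc.index \
            else np.zeros(n_rep)
        out[str(eid)] = LocalizationRecord(entity_id=str(eid),
                                           entity_class=entity_class,
                                           cyt_signal=c, nuc_signal=n)
    return out


def call_rna_compartment(rec: LocalizationRecord, cfg: Config) -> str:
    """'cytoplasmic' | 'nuclear' | 'ambiguous' (no usable replicate)."""
    mean_cyt = rec.mean_pct_cytoplasmic
    if math.isnan(mean_cyt):
        return "ambiguous"
    return "cytoplasmic" if mean_cyt > cfg.rna_cytoplasmic_pct_min else "nuclear"


def protein_compartment_eligibility(rec: LocalizationRecord, compartment: str,
                                    cfg: Config,
                                    expected_replicates: int | None = None,
                                    ) -> bool:
    """Is a protein usable as a candidate interactor in ``compartment``?

    Cytoplasmic rule: detected (signal > 0) in the cytoplasmic fraction in
    ALL replicates, and NOT (percent nuclear >= cfg.opposing_compartment_pct
    in ALL replicates).  Nuclear rule is the mirror image.
    """
    if compartment not in COMPARTMENTS:
        raise ValidationError(f"unknown compartment {compartment!r}")
    if expected_replicates is not None and rec.n_replicates != expected_replicates:
        raise ValidationError(
            f"{rec.entity_id}: expected {expected_replicates} replicates, "
            f"found {rec.n_replicates}")
    if compartment == "cytoplasmic":
        detected = (rec.cyt_signal > 0).all()
        opposing_pct = rec.pct_nuclear
    else:
        detected = (rec.nuc_signal > 0).all()
        opposing_pct = rec.pct_cytoplasmic
    if not detected:
        return False
    # detection in all replicates guarantees nonzero totals -> no nans
    mostly_opposing = bool((opposing_pct >= cfg.opposing_compartment_pct).all())
    return not mostly_opposing


def exclude_mitochondrial(proteins: Iterable[str],
                          mito_list: Iterable[str]) -> set[str]:
    """Set difference; applied only in the nuclear-RNA branch."""
    return set(map(str, proteins)) - set(map(str, mito_list))


def localization_table(records: Mapping[str, LocalizationRecord],
                       cfg: Config) -> pd.DataFrame:
    """Long summary table: per-replicate percents plus the compartment call
    (RNAs) or per-compartment eligibility flags (proteins)."""
    rows = []
    for eid in sorted(records):
        rec = records[eid]
        row: dict = {"entity_id": eid, "entity_class": rec.entity_class,
                     "mean_pct_cytoplasmic": rec.mean_pct_cytoplasmic}
        for i, (pc, pn) in enumerate(zip(rec.pct_cytoplasmic,
                                         rec.pct_nuclear), start=1):
            row[f"pct_cyt_rep{i}"] = pc
            row[f"pct_nuc_rep{i}"] = pn
        if rec.entity_class == "rna":
            row["compartment_call"] = call_rna_compartment(rec, cfg)
        else:
            row["eligible_cytoplasmic"] = protein_compartment_eligibility(
                rec, "cytoplasmic", cfg)
            row["eligible_nuclear"] = protein_compartment_eligibility(
                rec, "nuclear", cfg)
        rows.append(row)
    return pd.DataFrame(rows).set_index("entity_id")
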