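"""Synthetic co-sedimentome generator with planted ground truth.

The generator emulates the structure of the real inputs of the
prediction pipeline without any physical sedimentation modelling:

* RNA-protein complexes are Gaussian peaks over the gradient fractions;
  members of a complex share the peak position and width, so at zero
  noise their profiles correlate perfectly.  Multiplicative log-normal
  noise perturbs every fraction value.
* True RBPs are enriched ``oops_effect``-fold in the simulated RNase+
  OOPS eluate over the no-RNase control; non-RBPs have ratio ~1.
* Every entity lives mainly in one compartment (80-95% of its signal per
  replicate), so compartment calls and eligibility rules are exercised.
* Fractionation RNA-seq samples carry an E. coli spike-in whose read
  share varies between samples; the emitted RPKM tables are *de*-normalized
  by the spike percentage so the pipeline's spike-in normalization
  recovers the true signal.
* A configurable number of mitochondrial RBPs co-sediment with the first
  nuclear complex without being planted interactors, exercising the
  mitochondrial exclusion end to end.

A single integer seed drives one pseudo-random stream; identical specs
and seeds produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, localization
from .core_io import (Config, CountTable, GradientMatrix, ValidationError,
                      write_count_table, write_gradient_matrix, write_id_list)
from .gradr_core import CombinedDataset
from .localization import SpikeInSample, localization_records, spikein_normalize


@dataclass
class ComplexSpec:
    """One planted RNA-protein complex."""

    peak_fraction: float
    peak_width: float
    n_proteins: int
    n_rnas: int
    compartment: str

    def __post_init__(self) -> None:
        if self.peak_width <= 0:
            raise ValidationError("peak_width must be positive")
        if self.compartment not in ("cytoplasmic", "nuclear"):
            raise ValidationError(f"unknown compartment {self.compartment!r}")


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic co-sedimentome.

    Defaults: two well-separated complexes (a cytoplasmic one peaking in
    fraction 5 and a nuclear one in fraction 18, width 1.5 fractions,
    4 proteins and 3 RNAs each), 30 background proteins of which 30% are
    RBPs, two mitochondrial RBPs riding the nuclear peak, 10% log-normal
    noise, 8-fold OOPS enrichment for true RBPs, 3 replicates, spike-in
    shares of 1-5% per sample.
    """

    n_fractions: int = 22
    complexes: list[ComplexSpec] = field(default_factory=lambda: [
        ComplexSpec(5.0, 1.5, 4, 3, "cytoplasmic"),
        ComplexSpec(18.0, 1.5, 4, 3, "nuclear"),
    ])
    n_background_proteins: int = 30
    frac_background_rbp: float = 0.3
    n_mito_rbps: int = 2
    noise_sd: float = 0.1
    oops_effect: float = 8.0
    replicates: int = 3
    spike_fraction_range: tuple[float, float] = (0.01, 0.05)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.complexes = [c if isinstance(c, ComplexSpec) else ComplexSpec(**c)
                          for c in self.complexes]
        if not self.complexes and self.n_background_proteins == 0:
            raise ValidationError("need at least one complex or background "
                                  "protein")
        for c in self.complexes:
            if not 1 <= c.peak_fraction <= self.n_fractions:
                raise ValidationError("peak_fraction outside the gradient")
        if not 0 <= self.frac_background_rbp <= 1:
            raise ValidationError("frac_background_rbp must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.oops_effect <= 1:
            raise ValidationError("oops_effect must be > 1")
        if self.replicates < 2:
            raise ValidationError("need >= 2 replicates for the t-test")
        lo, hi = self.spike_fraction_range
        if not 0 < lo <= hi < 1:
            raise ValidationError("spike_fraction_range must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "spike_fraction_range" in data:
            data["spike_fraction_range"] = tuple(data["spike_fraction_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["spike_fraction_range"] = list(d["spike_fraction_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted facts the pipeline is scored against."""

    interactions: set[tuple[str, str]]
    rbp_ids: set[str]
    compartment_of: dict[str, str]
    mito_ids: set[str]

    @property
    def entity_ids(self) -> set[str]:
        return set(self.compartment_of)


@dataclass
class Simulation:
    """All generated tables plus the ground truth."""

    spec: SimulationSpec
    rna_profiles: GradientMatrix
    protein_profiles: GradientMatrix
    oops_treat: pd.DataFrame
    oops_ctrl: pd.DataFrame
    rna_cyt_rpkm: pd.DataFrame      # raw, pre-spike-normalization
    rna_nuc_rpkm: pd.DataFrame
    spike_samples: dict[str, SpikeInSample]
    protein_cyt: pd.DataFrame
    protein_nuc: pd.DataFrame
    expression: CountTable
    truth: GroundTruth

    def combined_dataset(self, cfg: Config) -> CombinedDataset:
        """Run the evidence-layer preprocessing and assemble the dataset.

        Spike-normalizes the RNA fractionation tables, computes the OOPS
        enrichment table and RBP calls, and builds localization records
        for all entities.
        """
        rna_cyt = spikein_normalize(self.rna_cyt_rpkm, self.spike_samples)
        rna_nuc = spikein_normalize(self.rna_nuc_rpkm, self.spike_samples)
        oops = differential.enrichment_table(self.oops_treat, self.oops_ctrl)
        rbps = differential.call_rbps(oops, cfg)
        loc = localization_records(rna_cyt, rna_nuc, "rna")
        loc.update(localization_records(self.protein_cyt, self.protein_nuc,
                                        "protein"))
        return CombinedDataset(rna_profiles=self.rna_profiles,
                               protein_profiles=self.protein_profiles,
                               rbp_ids=rbps, localization=loc,
                               mito_ids=set(self.truth.mito_ids), oops=oops)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gradient_matrix(self.rna_profiles, out / "rna_profiles.tsv")
        write_gradient_matrix(self.protein_profiles,
                              out / "protein_profiles.tsv")
        self.oops_treat.to_csv(out / "oops_treat.tsv", sep="\t",
                               index_label="entity_id", float_format="%.17g")
        self.oops_ctrl.to_csv(out / "oops_ctrl.tsv", sep="\t",
                              index_label="entity_id", float_format="%.17g")
        self.rna_cyt_rpkm.to_csv(out / "rna_cyt_rpkm.tsv", sep="\t",
                                 index_label="entity_id", float_format="%.17g")
        self.rna_nuc_rpkm.to_csv(out / "rna_nuc_rpkm.tsv", sep="\t",
                                 index_label="entity_id", float_format="%.17g")
        localization.write_spikein_table(self.spike_samples,
                                         out / "spike_samples.tsv")
        self.protein_cyt.to_csv(out / "protein_cyt.tsv", sep="\t",
                                index_label="entity_id", float_format="%.17g")
        self.protein_nuc.to_csv(out / "protein_nuc.tsv", sep="\t",
                                index_label="entity_id", float_format="%.17g")
        write_count_table(self.expression, out / "counts.tsv",
                          out / "rpkm.tsv", out / "samples.tsv")
        write_id_list(self.truth.mito_ids, out / "mito_proteins.txt")
        write_truth(self.truth, out)


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    out = Path(outdir)
    pairs = pd.DataFrame(sorted(truth.interactions),
                         columns=["rna_id", "protein_id"])
    pairs.to_csv(out / "truth_interactions.tsv", sep="\t", index=False)
    ents = pd.DataFrame(
        [(e, truth.compartment_of[e], e in truth.rbp_ids, e in truth.mito_ids)
         for e in sorted(truth.compartment_of)],
        columns=["entity_id", "compartment", "is_rbp", "is_mito"])
    ents.to_csv(out / "truth_entities.tsv", sep="\t", index=False)


def read_truth(outdir: str | Path) -> GroundTruth:
    out = Path(outdir)
    pairs = pd.read_csv(out / "truth_interactions.tsv", sep="\t")
    ents = pd.read_csv(out / "truth_entities.tsv", sep="\t")
    return GroundTruth(
        interactions={(str(r), str(p))
                      for r, p in zip(pairs["rna_id"], pairs["protein_id"])},
        rbp_ids=set(ents.loc[ents["is_rbp"], "entity_id"].astype(str)),
        compartment_of=dict(zip(ents["entity_id"].astype(str),
                                ents["compartment"].astype(str))),
        mito_ids=set(ents.loc[ents["is_mito"], "entity_id"].astype(str)))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _gaussian_profile(rng: np.random.Generator, n_fractions: int, peak: float,
                      width: float, noise_sd: float) -> np.ndarray:
    fr = np.arange(1, n_fractions + 1, dtype=float)
    amp = rng.lognormal(mean=np.log(500.0), sigma=0.5)
    shape = np.exp(-((fr - peak) ** 2) / (2.0 * width ** 2))
    noise = np.exp(rng.normal(0.0, noise_sd, size=n_fractions)) \
        if noise_sd > 0 else 1.0
    return amp * shape * noise


def simulate_cosedimentome(spec: SimulationSpec) -> Simulation:
    """Generate every pipeline input table plus the planted ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    nf, reps = spec.n_fractions, spec.replicates
    frac_cols = [f"F{i:02d}" for i in range(1, nf + 1)]
    rep_cols = [f"rep{i}" for i in range(1, reps + 1)]

    rna_rows: dict[str, np.ndarray] = {}
    prot_rows: dict[str, np.ndarray] = {}
    compartment_of: dict[str, str] = {}
    rbp_ids: set[str] = set()
    mito_ids: set[str] = set()
    interactions: set[tuple[str, str]] = set()

    for ci, cx in enumerate(spec.complexes, start=1):
        rnas = [f"RNA_C{ci}_{i}" for i in range(1, cx.n_rnas + 1)]
        prots = [f"PROT_C{ci}_{j}" for j in range(1, cx.n_proteins + 1)]
        for eid in rnas:
            rna_rows[eid] = _gaussian_profile(rng, nf, cx.peak_fraction,
                                              cx.peak_width, spec.noise_sd)
            compartment_of[eid] = cx.compartment
        for pid in prots:
            prot_rows[pid] = _gaussian_profile(rng, nf, cx.peak_fraction,
                                               cx.peak_width, spec.noise_sd)
            compartment_of[pid] = cx.compartment
            rbp_ids.add(pid)
        interactions.update((r, p) for r in rnas for p in prots)

    for k in range(1, spec.n_background_proteins + 1):
        pid = f"PROT_BG_{k}"
        peak = rng.uniform(1, nf)
        width = rng.uniform(1.0, 3.0)
        prot_rows[pid] = _gaussian_profile(rng, nf, peak, width, spec.noise_sd)
        compartment_of[pid] = str(rng.choice(["cytoplasmic", "nuclear"]))
        if rng.random() < spec.frac_background_rbp:
            rbp_ids.add(pid)

    nuclear_cx = next((c for c in spec.complexes
                       if c.compartment == "nuclear"), None)
    for k in range(1, spec.n_mito_rbps + 1):
        pid = f"PROT_MITO_{k}"
        if nuclear_cx is not None:
            peak, width = nuclear_cx.peak_fraction, nuclear_cx.peak_width
        else:
            peak, width = rng.uniform(1, nf), rng.uniform(1.0, 3.0)
        prot_rows[pid] = _gaussian_profile(rng, nf, peak, width, spec.noise_sd)
        compartment_of[pid] = "nuclear"
        rbp_ids.add(pid)
        mito_ids.add(pid)

    rna_profiles = GradientMatrix(
        pd.DataFrame(rna_rows, index=frac_cols).T, "rna")
    protein_profiles = GradientMatrix(
        pd.DataFrame(prot_rows, index=frac_cols).T, "protein")

    # --- OOPS RNase+/- eluate tables -------------------------------------
    prot_ids = list(prot_rows)
    treat, ctrl = {}, {}
    for pid in prot_ids:
        base = rng.lognormal(mean=np.log(1e5), sigma=0.7)
        effect = spec.oops_effect if pid in rbp_ids else 1.0
        ctrl[pid] = base * np.exp(rng.normal(0, spec.noise_sd, reps)) \
            if spec.noise_sd > 0 else np.full(reps, base)
        treat[pid] = base * effect * np.exp(rng.normal(0, spec.noise_sd, reps)) \
            if spec.noise_sd > 0 else np.full(reps, base * effect)
    oops_treat = pd.DataFrame(treat, index=rep_cols).T
    oops_ctrl = pd.DataFrame(ctrl, index=rep_cols).T

    # --- subcellular fractionation ---------------------------------------
    def loc_tables(ids: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
        cyt, nuc = {}, {}
        for eid in ids:
            base = rng.lognormal(mean=np.log(50.0), sigma=0.5)
            share = rng.uniform(0.80, 0.95, size=reps)
            total = base * (np.exp(rng.normal(0, spec.noise_sd, reps))
                            if spec.noise_sd > 0 else 1.0)
            if compartment_of[eid] == "cytoplasmic":
                cyt[eid], nuc[eid] = total * share, total * (1 - share)
            else:
                cyt[eid], nuc[eid] = total * (1 - share), total * share
        return (pd.DataFrame(cyt, index=rep_cols).T,
                pd.DataFrame(nuc, index=rep_cols).T)

    rna_cyt_true, rna_nuc_true = loc_tables(list(rna_rows))
    protein_cyt, protein_nuc = loc_tables(prot_ids)

    # spike-in: equal-mass E. coli RNA, variable share per sample; the raw
    # RPKM tables are the true signals times the spike percentage, so the
    # divide-mode normalization recovers the truth
    lo, hi = spec.spike_fraction_range
    spike_samples: dict[str, SpikeInSample] = {}
    human_reads = 2_000_000
    for comp in ("cyt", "nuc"):
        for r in rep_cols:
            sid = f"{comp}_{r}"
            sf = rng.uniform(lo, hi)
            spike_reads = int(round(human_reads * sf / (1 - sf)))
            spike_samples[sid] = SpikeInSample(sid, human_reads, spike_reads)

    def denormalize(true_tab: pd.DataFrame, comp: str) -> pd.DataFrame:
        raw = {}
        for r in rep_cols:
            sid = f"{comp}_{r}"
            raw[sid] = true_tab[r] * spike_samples[sid].spike_percent
        return pd.DataFrame(raw, index=true_tab.index)

    rna_cyt_rpkm = denormalize(rna_cyt_true, "cyt")
    rna_nuc_rpkm = denormalize(rna_nuc_true, "nuc")
    protein_cyt.columns = [f"cyt_{r}" for r in rep_cols]
    protein_nuc.columns = [f"nuc_{r}" for r in rep_cols]

    # --- expression count table (for the expressed-RNA filter stage) -----
    conditions = ["untreated", "stimulated"]
    sample_ids = [f"{c}_{r}" for c in conditions for r in rep_cols]
    expr_ids = list(rna_rows) + [f"RNA_LOW_{i}" for i in (1, 2)]
    counts = {}
    for eid in expr_ids:
        lam = 500.0 if not eid.startswith("RNA_LOW") else 3.0
        counts[eid] = rng.poisson(lam, size=len(sample_ids))
    counts_df = pd.DataFrame(counts, index=sample_ids).T
    rpkm_df = counts_df / 50.0
    samples_df = pd.DataFrame(
        {"condition": [s.rsplit("_", 1)[0] for s in sample_ids],
         "replicate": [s.rsplit("_", 1)[1] for s in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id"))
    expression = CountTable(counts=counts_df, rpkm=rpkm_df,
                            samples=samples_df)

    truth = GroundTruth(interactions=interactions, rbp_ids=rbp_ids,
                        compartment_of=compartment_of, mito_ids=mito_ids)
    return Simulation(spec=spec, rna_profiles=rna_profiles,
                      protein_profiles=protein_profiles,
                      oops_treat=oops_treat, oops_ctrl=oops_ctrl,
                      rna_cyt_rpkm=rna_cyt_rpkm, rna_nuc_rpkm=rna_nuc_rpkm,
                      spike_samples=spike_samples, protein_cyt=protein_cyt,
                      protein_nuc=protein_nuc, expression=expression,
                      truth=truth)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_predictions(pred: pd.DataFrame, truth: GroundTruth) -> dict:
    """Precision/recall/F1 of passed (rna, protein) pairs vs planted truth.

    An empty prediction set gives recall 0 and precision reported as 0
    with ``empty_prediction=True``.  Predictions over a universe disjoint
    from the truth's are rejected.
    """
    passed = pred.loc[pred["passed"]] if "passed" in pred.columns else pred
    pred_pairs = {(str(r), str(p))
                  for r, p in zip(passed["rna_id"], passed["protein_id"])}
    pred_entities = {e for pair in pred_pairs for e in pair}
    if pred_entities and not (pred_entities & truth.entity_ids):
        raise ValidationError("prediction and truth refer to disjoint "
                              "entity universes")
    tp = len(pred_pairs & truth.interactions)
    n_true = len(truth.interactions)
    recall = tp / n_true if n_true else 0.0
    empty = len(pred_pairs) == 0
    precision = tp / len(pred_pairs) if pred_pairs else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_predicted": len(pred_pairs), "n_true": n_true,
            "true_positives": tp, "empty_prediction": empty}
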