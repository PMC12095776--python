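"""Shared data model, tabular I/O, configuration, and the expressed-RNA filter.

All tables are UTF-8 TSV with a header row; the first column is always
``entity_id``.  Gradient matrices hold one sedimentation profile per row
(entity x fraction, top of the gradient first); count tables pair raw read
counts with RPKM values and a sample sheet mapping each sample to a
condition and replicate label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ENTITY_CLASSES = ("rna", "protein")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant (negative abundance, ...)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """All numeric thresholds of the prediction pipeline in one place.

    Attributes
    ----------
    oops_fc_min : float
        Minimum RNase+/- elution fold-change for a protein to be called an
        RNA-binding protein (RBP).
    oops_p_max : float
        Maximum t-test p-value for the RBP call.
    r_min : float
        Minimum co-sedimentation Pearson r for a candidate interactor.
    opposing_compartment_pct : float
        A protein is ineligible for a compartment when its signal is at
        least this percentage in the *opposing* compartment in every
        replicate.
    rna_cytoplasmic_pct_min : float
        An RNA is called cytoplasmic when its mean percent-cytoplasmic
        signal strictly exceeds this value; ties go to nuclear.
    rpkm_min : float
        Expressed-RNA filter: RPKM required in all replicates of at least
        one condition.
    min_reads : int
        Expressed-RNA filter: minimum raw read count (per-sample maximum by
        default, see ``reads_rule``).
    reads_rule : str
        ``"max_sample"`` (default) applies ``min_reads`` to the largest
        single-sample count; ``"condition_sum"`` applies it to the largest
        per-condition replicate sum.
    min_hit_bases : int
        BLAST hit retention: minimum matched (identical) bases.
    window_bp : int
        Maximum span of the orthologous conservation window.
    n_fractions : int
        Number of gradient fractions in a sedimentation profile.
    rng_seed : int
        Seed for any stochastic step (the simulator).
    """

    oops_fc_min: float = 2.0
    oops_p_max: float = 0.05
    r_min: float = 0.5
    opposing_compartment_pct: float = 60.0
    rna_cytoplasmic_pct_min: float = 50.0
    rpkm_min: float = 0.5
    min_reads: int = 10
    reads_rule: str = "max_sample"
    min_hit_bases: int = 20
    window_bp: int = 100_000
    n_fractions: int = 22
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("oops_fc_min", "oops_p_max", "r_min",
                     "opposing_compartment_pct", "rna_cytoplasmic_pct_min",
                     "rpkm_min", "min_reads", "min_hit_bases", "window_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Config.{name} must be strictly positive")
        if self.n_fractions < 3:
            raise ValidationError("Config.n_fractions must be >= 3")
        if self.reads_rule not in ("max_sample", "condition_sum"):
            raise ValidationError(
                f"Config.reads_rule must be 'max_sample' or 'condition_sum', "
                f"got {self.reads_rule!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# gradient matrices
# ---------------------------------------------------------------------------

@dataclass
class GradientMatrix:
    """Sedimentation profiles: entities x gradient fractions.

    ``profiles`` is indexed by entity_id; columns are fraction labels in
    gradient order (top to bottom).  Values are non-negative abundances
    (RPKM for RNAs, LFQ intensities for proteins).
    """

    profiles: pd.DataFrame
    entity_class: str

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValidationError(
                f"entity_class must be one of {ENTITY_CLASSES}, "
                f"got {self.entity_class!r}")
        dup = self.profiles.index[self.profiles.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate entity_id: {dup[0]!r}")
        if self.profiles.isna().any().any():
            bad = self.profiles.index[self.profiles.isna().any(axis=1)][0]
            raise FormatError(f"missing fraction value for entity {bad!r}")
        if (self.profiles.values < 0).any():
            bad = self.profiles.index[(self.profiles.values < 0).any(axis=1)][0]
            raise ValidationError(f"negative abundance for entity {bad!r}")

    @property
    def n_fractions(self) -> int:
        return self.profiles.shape[1]

    @property
    def entity_ids(self) -> pd.Index:
        return self.profiles.index

    def profile(self, entity_id: str) -> np.ndarray:
        return self.profiles.loc[entity_id].to_numpy(dtype=float)


def read_gradient_matrix(path: str | Path, entity_class: str) -> GradientMatrix:
    """Read a TSV of sedimentation profiles (first column entity_id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no fraction columns found")
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric fraction column {non_numeric[0]!r}")
    df.index = df.index.astype(str)
    return GradientMatrix(profiles=df, entity_class=entity_class)


def write_gradient_matrix(gm: GradientMatrix, path: str | Path) -> None:
    gm.profiles.to_csv(path, sep="\t", index_label="entity_id",
                       float_format="%.17g")


# ---------------------------------------------------------------------------
# count tables and the expressed-RNA filter
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Raw read counts plus RPKM per entity and sample, with a sample sheet.

    ``counts`` and ``rpkm`` share index (entity_id) and columns (sample_id);
    ``samples`` is indexed by sample_id with ``condition`` and ``replicate``
    columns.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.rpkm.columns):
            raise FormatError("counts and RPKM tables have different samples")
        if not self.counts.index.equals(self.rpkm.index):
            raise FormatError("counts and RPKM tables have different entities")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples missing from sample sheet: {sorted(missing)}")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise FormatError(f"sample sheet lacks required column {col!r}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative read count")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("read counts must be integers")
        if (self.rpkm.to_numpy() < 0).any():
            raise ValidationError("negative RPKM")

    @property
    def entity_ids(self) -> pd.Index:
        return self.counts.index

    def condition_samples(self) -> dict[str, list[str]]:
        """Map condition label -> sample_ids, in sheet order."""
        out: dict[str, list[str]] = {}
        for sid in self.counts.columns:
            out.setdefault(str(self.samples.loc[sid, "condition"]), []).append(sid)
        return out

    def subset(self, entity_ids: Iterable[str]) -> "CountTable":
        idx = self.counts.index.intersection(pd.Index(entity_ids))
        # preserve original row order
        idx = self.counts.index[self.counts.index.isin(idx)]
        return CountTable(self.counts.loc[idx], self.rpkm.loc[idx], self.samples)


def read_count_table(counts_path: str | Path, rpkm_path: str | Path,
                     samples_path: str | Path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    rpkm = pd.read_csv(rpkm_path, sep="\t", index_col=0,
                       float_precision="round_trip")
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    rpkm.index = rpkm.index.astype(str)
    samples.index = samples.index.astype(str)
    return CountTable(counts=counts, rpkm=rpkm, samples=samples)


def write_count_table(ct: CountTable, counts_path: str | Path,
                      rpkm_path: str | Path, samples_path: str | Path) -> None:
    ct.counts.to_csv(counts_path, sep="\t", index_label="entity_id")
    ct.rpkm.to_csv(rpkm_path, sep="\t", index_label="entity_id",
                   float_format="%.17g")
    ct.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def filter_expressed(ct: CountTable, cfg: Config,
                     exempt: Iterable[str] = ()) -> CountTable:
    """Keep reliably detected RNAs.

    An entity is retained iff

    * there is at least one condition in which its RPKM is >= ``cfg.rpkm_min``
      in *all* replicates of that condition, AND
    * its raw read support reaches ``cfg.min_reads`` (largest single-sample
      count by default; largest per-condition replicate sum when
      ``cfg.reads_rule == "condition_sum"``),

    or its id appears in ``exempt`` (always retained).
    """
    exempt = set(exempt)
    if ct.counts.empty:
        return ct

    ok_rpkm = pd.Series(False, index=ct.entity_ids)
    by_cond = ct.condition_samples()
    for _cond, sample_ids in by_cond.items():
        ok_rpkm |= (ct.rpkm[sample_ids] >= cfg.rpkm_min).all(axis=1)

    if cfg.reads_rule == "max_sample":
        ok_reads = ct.counts.max(axis=1) >= cfg.min_reads
    else:
        cond_sums = pd.DataFrame(
            {cond: ct.counts[sids].sum(axis=1) for cond, sids in by_cond.items()})
        ok_reads = cond_sums.max(axis=1) >= cfg.min_reads

    keep = (ok_rpkm & ok_reads) | ct.entity_ids.isin(exempt)
    return CountTable(ct.counts.loc[keep], ct.rpkm.loc[keep], ct.samples)


def compute_rpkm(counts: pd.DataFrame, lengths_bp: Mapping[str, int] | pd.Series,
                 library_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    Library size defaults to the per-sample column sum of ``counts``.
    """
    lengths = pd.Series(lengths_bp, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValidationError(f"missing length for entity {missing!r}")
    if (lengths <= 0).any():
        raise ValidationError("entity lengths must be positive")
    if library_sizes is None:
        libsize = counts.sum(axis=0).astype(float)
    else:
        libsize = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if (libsize <= 0).any():
        raise ValidationError("library sizes must be positive")
    kb = lengths / 1e3
    return counts.div(kb, axis=0).div(libsize / 1e6, axis=1)


def read_id_list(path: str | Path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")
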