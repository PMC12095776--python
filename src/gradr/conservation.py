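"""lncRNA sequence-conservation scoring from BLASTN tabular output.

Given BLASTN hits of a (coding-sequence-clipped) human lncRNA against a
target-species genome:

1. keep hits with at least 20 matched bases
   (``round(align_length * pct_identity / 100)``);
2. find the orthologous locus: the genomic window of at most 100 kb whose
   hits jointly cover the most query bases (synteny hints, when given,
   take precedence among overlapping candidates);
3. score percent base conservation over the query from the hits inside
   that window, weighting each covered position by the best identity of
   any hit covering it (an unweighted covered-bases mode is available).

Input is the standard 12-column NCBI BLAST tabular format (-outfmt 6):
qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Config, FormatError, ValidationError


@dataclass(frozen=True)
class BlastHit:
    """One BLASTN local alignment (1-based inclusive coordinates).

    ``s_start > s_end`` encodes a minus-strand subject hit; query
    coordinates are normalized so that ``q_start <= q_end``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            lo, hi = self.q_end, self.q_start
            object.__setattr__(self, "q_start", lo)
            object.__setattr__(self, "q_end", hi)
        if min(self.q_start, self.s_start, self.s_end) < 1:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: coordinates must be "
                f"positive")
        if self.align_length < 1:
            raise ValidationError("alignment length must be >= 1")
        if not 0 <= self.pct_identity <= 100:
            raise ValidationError("percent identity must be in [0, 100]")

    @property
    def matched_bases(self) -> int:
        """Identical bases in the alignment."""
        return int(round(self.align_length * self.pct_identity / 100.0))

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST -outfmt 6 file; errors carry line numbers."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}")
            try:
                hits.append(BlastHit(
                    query_id=fields[0], subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    q_start=int(fields[6]), q_end=int(fields[7]),
                    s_start=int(fields[8]), s_end=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11])))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def retain_hits(hits: Iterable[BlastHit], cfg: Config,
                mode: str = "matched") -> list[BlastHit]:
    """Hit retention: >= cfg.min_hit_bases matched bases.

    ``mode="matched"`` (default) counts identical bases
    (align_length * identity); ``mode="length"`` uses the raw alignment
    length instead.
    """
    if mode not in ("matched", "length"):
        raise ValidationError(f"unknown retention mode {mode!r}")
    if mode == "matched":
        return [h for h in hits if h.matched_bases >= cfg.min_hit_bases]
    return [h for h in hits if h.align_length >= cfg.min_hit_bases]


def query_coverage(hits: Iterable[BlastHit]) -> int:
    """Total query bases covered by the union of hit query intervals."""
    ivals = sorted((h.q_start, h.q_end) for h in hits)
    covered = 0
    cur_start = cur_end = None
    for start, end in ivals:
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered


@dataclass
class OrthologWindow:
    """The selected orthologous locus for one (query, species) pair."""

    subject_id: str
    start: int          # subject coordinates, window bounds
    end: int
    hits: tuple[BlastHit, ...]
    coverage: int       # query bases covered by hits in the window

    @property
    def span(self) -> int:
        return self.end - self.start


def select_ortholog_window(hits: Sequence[BlastHit], cfg: Config,
                           synteny_hint: tuple[str, int, int] | None = None,
                           ) -> OrthologWindow | None:
    """Pick the <= cfg.window_bp subject window maximizing query coverage.

    Candidate windows are anchored at each hit's subject start: the
    window anchored at hit *h* contains every hit on the same subject
    lying entirely within ``[h.s_lo, h.s_lo + window_bp]``.  Anchoring at
    hit boundaries is sufficient: any optimal window can be slid left
    until its left edge touches a hit without losing hits.

    ``synteny_hint = (subject_id, start, end)`` restricts the choice to
    hint-overlapping candidates whenever at least one exists.  Ties are
    broken by larger coverage, then smaller span, then subject_id, then
    window start.  Returns None when ``hits`` is empty (species scored
    0% downstream).
    """
    hits = list(hits)
    if not hits:
        return None

    by_subject: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)

    candidates: list[OrthologWindow] = []
    for subject, shits in by_subject.items():
        shits = sorted(shits, key=lambda h: (h.s_lo, h.s_hi))
        for anchor in shits:
            lo = anchor.s_lo
            inside = [h for h in shits
                      if h.s_lo >= lo and h.s_hi <= lo + cfg.window_bp]
            if not inside:
                continue
            win = OrthologWindow(
                subject_id=subject,
                start=min(h.s_lo for h in inside),
                end=max(h.s_hi for h in inside),
                hits=tuple(inside),
                coverage=query_coverage(inside))
            candidates.append(win)

    if synteny_hint is not None:
        hint_subj, hint_lo, hint_hi = synteny_hint
        overlapping = [w for w in candidates
                       if w.subject_id == hint_subj
                       and w.start <= hint_hi and w.end >= hint_lo]
        if overlapping:
            candidates = overlapping

    return min(candidates,
               key=lambda w: (-w.coverage, w.span, w.subject_id, w.start))


def percent_conservation(query_length: int, hits: Iterable[BlastHit],
                         identity_weighted: bool = True) -> float:
    """Percent base conservation of the query from the window's hits.

    Each query position covered by at least one hit contributes the best
    (highest) percent identity of any covering hit, divided by 100; the
    score is 100 * summed contributions / query_length, capped at 100.
    With ``identity_weighted=False`` every covered position counts as a
    full conserved base (plain coverage).
    """
    if query_length < 1:
        raise ValidationError("query_length must be >= 1")
    best = np.zeros(query_length)
    for h in hits:
        lo = h.q_start - 1
        hi = min(h.q_end, query_length)
        if lo >= query_length:
            continue
        weight = h.pct_identity / 100.0 if identity_weighted else 1.0
        np.maximum(best[lo:hi], weight, out=best[lo:hi])
    return min(100.0, 100.0 * float(best.sum()) / query_length)


def conservation_table(per_species_hits: Mapping[tuple[str, str],
                                                 Sequence[BlastHit]],
                       query_lengths: Mapping[str, int], cfg: Config,
                       identity_weighted: bool = True,
                       synteny_hints: Mapping[tuple[str, str],
                                              tuple[str, int, int]] | None = None,
                       ) -> pd.DataFrame:
    """Score every (query, species) pair; long-format result table.

    ``per_species_hits`` maps (query_id, species) to its BLAST hits (an
    empty sequence meaning no hit file / no hits, scored 0%).
    """
    synteny_hints = synteny_hints or {}
    rows = []
    for (query_id, species), hits in per_species_hits.items():
        if query_id not in query_lengths:
            raise ValidationError(f"missing query length for {query_id!r}")
        qlen = int(query_lengths[query_id])
        kept = retain_hits(hits, cfg)
        window = select_ortholog_window(
            kept, cfg, synteny_hint=synteny_hints.get((query_id, species)))
        if window is None:
            rows.append((query_id, species, "", np.nan, np.nan, 0.0, 0))
        else:
            pct = percent_conservation(qlen, window.hits,
                                       identity_weighted=identity_weighted)
            rows.append((query_id, species, window.subject_id,
                         window.start, window.end, pct, len(window.hits)))
    return pd.DataFrame(rows, columns=["query_id", "species", "subject_id",
                                       "window_start", "window_end",
                                       "pct_base_conservation",
                                       "n_hits_in_window"])


def species_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species median and quartiles of percent base conservation
    (box-plot summaries)."""
    grouped = table.groupby("species")["pct_base_conservation"]
    out = grouped.agg(n="count", median="median",
                      q1=lambda s: s.quantile(0.25),
                      q3=lambda s: s.quantile(0.75))
    return out.reset_index()
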