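"""Adapter detection, clipping, placement and ligation-junction calling.

The RtcB capture chemistry ligates the adapter's 5'-OH to an RNA 3'-P /
2',3'-cyclic-P terminus, so a read has the layout::

    [target 3' fragment][N x random bases][21-nt adapter core][...]

Finding the core pins down the ligation junction: the last target base
before the random bases is the 3' terminus the ligase acted on.  The
chemistry also fixes orientation — targets are sense-strand, and
antisense placements are rejected.

Placement uses an exhaustive Hamming scan over the transcript set: exact
matches go through a single concatenated-text substring search, and
mismatched placement through a vectorised sliding-window comparison.
A SAM reader is provided as an alternative entry point for alignments
produced externally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, binom_upper_tail
from .types import (
    AdapterSpec,
    DomainAnnotation,
    LigationEvent,
    TranscriptRecord,
    reverse_complement,
)

#: Discard reason codes emitted by the calling pipeline.
REASONS = ("no_adapter", "empty_target", "short_target", "unmapped", "ambiguous", "antisense")


@dataclass(frozen=True)
class AdapterMatch:
    """Leftmost adapter-core occurrence within a read."""

    read_id: str
    core_start: int  # 0-based index of the first core base in the read
    mismatches: int
    target_len: int  # core_start - n_random_5p; < 0 means unusable


@dataclass(frozen=True)
class Placement:
    transcript_id: str
    start: int  # 1-based position of the first placed base
    strand: str  # '+' or '-'
    mismatches: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_adapter(
    read: str, adapter: AdapterSpec = AdapterSpec(), min_core_prefix: int = 12
) -> AdapterMatch | None:
    """Locate the leftmost adapter core in ``read``.

    Substitutions only (Hamming, no indels), at most
    ``adapter.max_mismatches`` of them.  A core truncated by the read
    end is accepted if at least ``min_core_prefix`` bases remain.
    Absence is a value (``None``), not an error.
    """
    if not read:
        raise ValueError("read must be non-empty")
    read = read.upper()
    core = adapter.core
    if adapter.max_mismatches == 0:
        pos = read.find(core)
        if pos != -1:
            return AdapterMatch("", pos, 0, pos - adapter.n_random_5p)
    for start in range(len(read) - min_core_prefix + 1):
        window = read[start : start + len(core)]
        mm = _hamming(window, core[: len(window)])
        if mm <= adapter.max_mismatches:
            return AdapterMatch("", start, mm, start - adapter.n_random_5p)
    return None


def clip_read(
    read: str,
    match: AdapterMatch,
    adapter: AdapterSpec = AdapterSpec(),
    min_target_len: int = 15,
) -> tuple[str | None, str | None]:
    """Remove the adapter (random bases included) and return
    ``(target, reason)`` — exactly one of the two is ``None``.

    The ``n_random_5p`` bases preceding the core belong to the adapter
    oligo and are never counted as target sequence.
    """
    if match.target_len <= 0:
        return None, "empty_target"
    if match.target_len < min_target_len:
        return None, "short_target"
    return read[: match.target_len], None


class TranscriptIndex:
    """Substring index over a transcript set for the Hamming-scan mapper."""

    def __init__(self, transcripts: Sequence[TranscriptRecord]):
        self.transcripts = list(transcripts)
        self.by_id = {t.id: t for t in self.transcripts}
        if len(self.by_id) != len(self.transcripts):
            raise ValueError("duplicate transcript ids")
        self._offsets = []
        pos = 0
        for t in self.transcripts:
            self._offsets.append(pos)
            pos += t.length + 1  # +1 for the separator
        self._text = "\x00".join(t.sequence for t in self.transcripts)
        self._arrays = [
            np.frombuffer(t.sequence.encode(), dtype=np.uint8) for t in self.transcripts
        ]

    def _locate(self, global_pos: int) -> tuple[int, int]:
        """Map a position in the concatenated text to (transcript index,
        0-based local position)."""
        idx = int(np.searchsorted(self._offsets, global_pos, side="right")) - 1
        return idx, global_pos - self._offsets[idx]

    def _find_exact(self, query: str) -> list[tuple[int, int]]:
        hits, start = [], self._text.find(query)
        while start != -1:
            hits.append(self._locate(start))
            start = self._text.find(query, start + 1)
        return hits

    def _find_hamming(self, query: str, max_mm: int) -> list[tuple[int, int, int]]:
        """All (transcript index, local 0-based start, mismatches) with
        Hamming distance <= max_mm."""
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        out = []
        for ti, arr in enumerate(self._arrays):
            if arr.size < q.size:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, q.size)
            mism = (windows != q).sum(axis=1)
            for pos in np.flatnonzero(mism <= max_mm):
                out.append((ti, int(pos), int(mism[pos])))
        return out


def map_clipped(
    seq: str,
    transcripts: Sequence[TranscriptRecord] | TranscriptIndex,
    max_map_mismatches: int = 0,
    with_reason: bool = False,
):
    """Place a clipped target on the transcript set.

    Scans both the forward sequence and its reverse complement; returns
    the unique best :class:`Placement`, or ``None`` when the sequence is
    unmapped or its best placement is tied (multi-mapping reads carry no
    usable junction).  With ``with_reason=True`` returns
    ``(placement, reason)``.
    """
    index = transcripts if isinstance(transcripts, TranscriptIndex) else TranscriptIndex(transcripts)
    seq = seq.upper()
    hits: list[tuple[int, int, str, int]] = []  # (ti, local0, strand, mm)
    if max_map_mismatches == 0:
        for strand, q in (("+", seq), ("-", reverse_complement(seq))):
            for ti, pos in index._find_exact(q):
                hits.append((ti, pos, strand, 0))
    else:
        for strand, q in (("+", seq), ("-", reverse_complement(seq))):
            for ti, pos, mm in index._find_hamming(q, max_map_mismatches):
                hits.append((ti, pos, strand, mm))
    if not hits:
        return (None, "unmapped") if with_reason else None
    best = min(h[3] for h in hits)
    best_hits = [h for h in hits if h[3] == best]
    if len(best_hits) > 1:
        return (None, "ambiguous") if with_reason else None
    ti, pos, strand, mm = best_hits[0]
    placement = Placement(index.transcripts[ti].id, pos + 1, strand, mm)
    return (placement, None) if with_reason else placement


def call_ligation_site(
    placement: Placement,
    clipped_len: int,
    read_id: str = "",
    random_bases: str = "",
) -> LigationEvent:
    """Junction = last target base before the adapter, 1-based.

    The ligation chemistry fixes the sense orientation; a reverse-strand
    placement is antisense to the transcript and cannot carry a genuine
    3'-terminus junction.
    """
    if placement.strand != "+":
        raise ValueError("antisense placement: ligation junctions are sense-strand only")
    return LigationEvent(
        read_id=read_id,
        transcript_id=placement.transcript_id,
        junction=placement.start + clipped_len - 1,
        n_mismatches_mapping=placement.mismatches,
        random_bases=random_bases,
    )


def call_events(
    reads: Iterable[tuple[str, str]],
    transcripts: Sequence[TranscriptRecord] | TranscriptIndex,
    adapter: AdapterSpec = AdapterSpec(),
    min_target_len: int = 15,
    max_map_mismatches: int = 0,
    min_core_prefix: int = 12,
) -> tuple[list[LigationEvent], Counter]:
    """Full calling pipeline: detect adapter, clip, place, call junction.

    Returns accepted events plus a Counter of discard reasons.
    """
    index = transcripts if isinstance(transcripts, TranscriptIndex) else TranscriptIndex(transcripts)
    events: list[LigationEvent] = []
    discarded: Counter = Counter()
    for read_id, seq in reads:
        match = find_adapter(seq, adapter, min_core_prefix=min_core_prefix)
        if match is None:
            discarded["no_adapter"] += 1
            continue
        target, reason = clip_read(seq, match, adapter, min_target_len=min_target_len)
        if target is None:
            discarded[reason] += 1
            continue
        placement, reason = map_clipped(
            target, index, max_map_mismatches=max_map_mismatches, with_reason=True
        )
        if placement is None:
            discarded[reason] += 1
            continue
        if placement.strand != "+":
            discarded["antisense"] += 1
            continue
        random_bases = seq[match.target_len : match.core_start]
        events.append(
            call_ligation_site(placement, len(target), read_id=read_id, random_bases=random_bases)
        )
    return events, discarded


def events_from_sam(
    path: str,
    transcripts: Sequence[TranscriptRecord],
) -> tuple[list[LigationEvent], Counter]:
    """Alternative entry point: take clipped-read placements from a SAM
    file produced by an external aligner.  The junction of a forward
    alignment is its rightmost aligned reference base; reverse-strand
    alignments are rejected as antisense."""
    import pysam

    known = {t.id for t in transcripts}
    events: list[LigationEvent] = []
    discarded: Counter = Counter()
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in known:
                discarded["unmapped"] += 1
                continue
            if aln.is_reverse:
                discarded["antisense"] += 1
                continue
            # pysam reference_end is 0-based exclusive == 1-based inclusive end
            events.append(
                LigationEvent(
                    read_id=aln.query_name,
                    transcript_id=aln.reference_name,
                    junction=int(aln.reference_end),
                    n_mismatches_mapping=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                )
            )
    return events, discarded


# ---------------------------------------------------------------------------
# aggregation and enrichment

def aggregate_events(
    events: Sequence[LigationEvent],
    transcripts: Sequence[TranscriptRecord],
    domains: Sequence[DomainAnnotation] = (),
    dedup: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene and per-domain event tables.

    ``dedup`` collapses events identical in (transcript, junction,
    random-base string) — the random bases act as a UMI.  Domain bounds
    are inclusive, and an event inside two overlapping domains counts
    once in each; the gene table is unaffected by the overlap.
    """
    known = {t.id for t in transcripts}
    for e in events:
        if e.transcript_id not in known:
            raise ValueError(f"event references unknown transcript {e.transcript_id!r}")
    if dedup:
        seen, kept = set(), []
        for e in events:
            key = (e.transcript_id, e.junction, e.random_bases)
            if key not in seen:
                seen.add(key)
                kept.append(e)
        events = kept

    counts = Counter(e.transcript_id for e in events)
    gene_table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["transcript_id", "n_events"],
    )

    rows = []
    per_transcript = Counter(e.transcript_id for e in events)
    for d in domains:
        observed = sum(
            1 for e in events if e.transcript_id == d.transcript_id and d.contains(e.junction)
        )
        rows.append((d.transcript_id, d.name, d.start, d.end, observed, per_transcript[d.transcript_id]))
    domain_table = pd.DataFrame(
        rows, columns=["transcript_id", "domain", "start", "end", "observed", "total"]
    )
    return gene_table, domain_table


def domain_enrichment(
    domain_table: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Length-weighted binomial enrichment of events within each domain.

    Under the null of junctions uniform along the transcript, the count
    in a domain of length L on a transcript of length N with n events is
    Binomial(n, L/N); the upper tail gives the over-representation p,
    BH-adjusted across the domains of each transcript.
    """
    if domain_table.empty:
        return domain_table.assign(p_value=[], p_adjusted=[])
    df = domain_table.copy()
    pvals = []
    for row in df.itertuples():
        tlen = transcript_lengths[row.transcript_id]
        dlen = row.end - row.start + 1
        if dlen > tlen:
            raise ValueError(
                f"domain {row.domain!r} longer than transcript {row.transcript_id!r}"
            )
        if row.total <= 0:
            raise ValueError(f"no events on transcript {row.transcript_id!r}")
        pvals.append(binom_upper_tail(row.observed, row.total, dlen / tlen))
    df["domain_len"] = df["end"] - df["start"] + 1
    df["transcript_len"] = df["transcript_id"].map(transcript_lengths)
    df["p_value"] = pvals
    df["p_adjusted"] = np.nan
    for tid, group in df.groupby("transcript_id"):
        df.loc[group.index, "p_adjusted"] = bh_adjust(group["p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# junction sequence composition

@dataclass
class CompositionResult:
    """Base-frequency matrices around the ligation junction.

    Columns <= 0 are target positions (0 = the 3'-terminal base),
    columns >= 1 the adapter's random 5' bases.  ``information`` is
    2 - H(column) in bits — 0 for a uniform column, 2 for a fixed base.
    """

    target_freq: pd.DataFrame
    adapter_freq: pd.DataFrame
    target_info: pd.Series
    adapter_info: pd.Series
    n_events: int


def _freq_matrix(seqs: list[str], columns) -> tuple[pd.DataFrame, pd.Series]:
    mat = pd.DataFrame(0.0, index=list("ACGT"), columns=columns)
    for s in seqs:
        for col, base in zip(columns, s):
            if base in "ACGT":
                mat.loc[base, col] += 1
    totals = mat.sum(axis=0)
    freq = mat / totals.replace(0, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = freq * np.log2(freq)
    info = 2.0 + plogp.fillna(0.0).sum(axis=0)
    return freq.fillna(0.0), info


def junction_composition(
    events: Sequence[LigationEvent],
    transcripts: Sequence[TranscriptRecord],
    flank: int = 5,
) -> CompositionResult:
    """Sequence composition of the target 3' flank and the adapter's
    random bases — flat frequencies and near-zero information content
    mean the ligase shows no sequence preference."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not events:
        raise ValueError("no events: composition is undefined")
    by_id = {t.id: t for t in transcripts}
    target_cols = list(range(-(flank - 1), 1))
    target_seqs = []
    for e in events:
        seq = by_id[e.transcript_id].sequence
        if e.junction >= flank:
            target_seqs.append(seq[e.junction - flank : e.junction])
    adapter_seqs = [e.random_bases for e in events if e.random_bases]
    target_freq, target_info = _freq_matrix(target_seqs, target_cols)
    n_random = max((len(s) for s in adapter_seqs), default=0)
    adapter_cols = list(range(1, n_random + 1))
    adapter_freq, adapter_info = _freq_matrix(adapter_seqs, adapter_cols)
    return CompositionResult(target_freq, adapter_freq, target_info, adapter_info, len(events))


# ---------------------------------------------------------------------------
# model / results facade

class LigationModel:
    """End-to-end junction calling as a fit-once model.

    Parameters mirror the pipeline knobs; :meth:`fit` runs detection,
    clipping, placement and aggregation and returns a
    :class:`LigationResults`.
    """

    def __init__(
        self,
        reads: Sequence[tuple[str, str]],
        transcripts: Sequence[TranscriptRecord],
        domains: Sequence[DomainAnnotation] = (),
        adapter: AdapterSpec = AdapterSpec(),
    ):
        self.reads = list(reads)
        self.transcripts = list(transcripts)
        self.domains = list(domains)
        self.adapter = adapter
        self.index = TranscriptIndex(self.transcripts)

    def fit(
        self,
        min_target_len: int = 15,
        max_map_mismatches: int = 0,
        min_core_prefix: int = 12,
        dedup: bool = False,
    ) -> "LigationResults":
        events, discarded = call_events(
            self.reads,
            self.index,
            adapter=self.adapter,
            min_target_len=min_target_len,
            max_map_mismatches=max_map_mismatches,
            min_core_prefix=min_core_prefix,
        )
        gene_table, domain_table = aggregate_events(
            events, self.transcripts, self.domains, dedup=dedup
        )
        return LigationResults(self, events, discarded, gene_table, domain_table)


@dataclass
class LigationResults:
    model: LigationModel
    events: list[LigationEvent]
    discarded: Counter
    gene_table: pd.DataFrame
    domain_table: pd.DataFrame
    _enrichment: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_targets(self) -> int:
        return len(self.gene_table)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.read_id, e.transcript_id, e.junction, e.n_mismatches_mapping, e.random_bases)
             for e in self.events],
            columns=["read_id", "transcript_id", "junction", "n_mismatches", "random_bases"],
        )

    def domain_enrichment(self) -> pd.DataFrame:
        if self._enrichment is None:
            lengths = {t.id: t.length for t in self.model.transcripts}
            self._enrichment = domain_enrichment(self.domain_table, lengths)
        return self._enrichment

    def composition(self, flank: int = 5) -> CompositionResult:
        return junction_composition(self.events, self.model.transcripts, flank=flank)

    def summary(self) -> str:
        lines = [
            "Ligation-site mapping summary",
            "=" * 34,
            f"reads in:        {len(self.model.reads)}",
            f"events called:   {self.n_events}",
            f"target genes:    {self.n_targets}",
        ]
        for reason in REASONS:
            if self.discarded.get(reason):
                lines.append(f"discarded ({reason}): {self.discarded[reason]}")
        if not self.domain_table.empty:
            enr = self.domain_enrichment()
            lines.append("")
            lines.append("domain enrichment (binomial upper tail, BH-adjusted):")
            for row in enr.itertuples():
                lines.append(
                    f"  {row.domain:>4}  obs {row.observed:>4}/{row.total:<4}"
                    f"  p={row.p_value:.3g}  p_adj={row.p_adjusted:.3g}"
                )
        return "\n".join(lines)
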