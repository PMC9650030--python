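"""Damage detection by per-gene coverage-shape correlation.

A cleaved transcript loses coverage on one side of the break, so the
shape of its per-base coverage profile changes between conditions even
when total abundance does not.  The statistic is the Pearson correlation
coefficient (PCC) of the two per-position count vectors of each gene:
intact genes correlate near 1, cleaved genes drop.  Genes are ranked by
descending PCC, low-PCC genes are called damaged, and damaged-set
composition is tested for RNA-class over-representation with a
hypergeometric upper tail.

PCC is computed on raw per-position counts: the statistic is invariant
to any positive scaling of either profile, so library-size normalisation
cannot change it.  A constant (or all-zero) profile has undefined PCC
and is excluded from ranking but reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .stats import bh_adjust, hypergeom_upper_tail
from .types import RNA_CLASSES, CoverageProfile, TranscriptRecord


@dataclass(frozen=True)
class GenePCC:
    """Per-gene correlation result; ``pcc`` is NaN when undefined."""

    transcript_id: str
    pcc: float
    mean_cov_a: float
    mean_cov_b: float
    damaged: bool = False
    rank: int | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.pcc)


@dataclass(frozen=True)
class ClassEnrichment:
    rna_class: str
    n_universe: int
    n_class: int
    n_selected: int
    n_selected_in_class: int
    p_value: float
    p_adjusted: float


def load_coverage(
    path: str,
    transcripts: Sequence[TranscriptRecord],
    sample_id: str | None = None,
) -> dict[str, CoverageProfile]:
    """Expand a bedGraph into per-position (window = 1) count vectors.

    Positions absent from the file are 0; intervals must lie within the
    named transcript.  Values are rounded to integer counts.
    """
    by_id = {t.id: t for t in transcripts}
    sample = sample_id if sample_id is not None else str(path)
    vectors = {t.id: np.zeros(t.length, dtype=np.int64) for t in transcripts}
    for chrom, start, end, value in rio.read_bedgraph(path):
        if chrom not in by_id:
            raise ValueError(f"bedGraph interval on unknown transcript {chrom!r}")
        if start < 0 or end > by_id[chrom].length or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) outside transcript {chrom!r} "
                f"(length {by_id[chrom].length})"
            )
        vectors[chrom][start:end] += int(round(value))
    return {tid: CoverageProfile(tid, sample, vec) for tid, vec in vectors.items()}


def gene_pcc(
    prof_a: CoverageProfile,
    prof_b: CoverageProfile,
    min_mean_cov: float = 10.0,
) -> GenePCC:
    """Pearson correlation of two coverage profiles of one gene.

    Undefined (NaN, excluded from ranking) when either vector is
    constant or either mean coverage is below ``min_mean_cov``.
    """
    if prof_a.transcript_id != prof_b.transcript_id:
        raise ValueError(
            f"profiles for different transcripts: "
            f"{prof_a.transcript_id!r} vs {prof_b.transcript_id!r}"
        )
    if len(prof_a) != len(prof_b):
        raise ValueError(
            f"profile length mismatch for {prof_a.transcript_id!r}: "
            f"{len(prof_a)} vs {len(prof_b)}"
        )
    a = np.asarray(prof_a.counts, dtype=float)
    b = np.asarray(prof_b.counts, dtype=float)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.std() == 0 or b.std() == 0 or mean_a < min_mean_cov or mean_b < min_mean_cov:
        pcc = np.nan
    else:
        pcc = float(np.corrcoef(a, b)[0, 1])
        pcc = max(-1.0, min(1.0, pcc))  # guard float round-off at the boundary
    return GenePCC(prof_a.transcript_id, pcc, mean_a, mean_b)


def rank_pcc(results: Sequence[GenePCC]) -> list[GenePCC]:
    """Sort defined entries by descending PCC (ties broken by id) and
    assign ranks 1..n; undefined entries are dropped from the ranking."""
    defined = [r for r in results if r.defined]
    if not defined:
        warnings.warn("no defined PCC values to rank", stacklevel=2)
        return []
    ordered = sorted(defined, key=lambda r: (-r.pcc, r.transcript_id))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def call_damaged(
    results: Sequence[GenePCC],
    pcc_threshold: float = 0.5,
    min_mean_cov: float = 10.0,
) -> list[GenePCC]:
    """Flag defined entries with PCC below the threshold as damaged.

    ``min_mean_cov`` re-screens entries whose means fall below the floor
    (profiles already filtered at computation time pass unchanged).
    """
    if not -1.0 <= pcc_threshold <= 1.0:
        raise ValueError(f"pcc_threshold must lie in [-1, 1], got {pcc_threshold}")
    out = []
    for r in results:
        usable = r.defined and r.mean_cov_a >= min_mean_cov and r.mean_cov_b >= min_mean_cov
        out.append(replace(r, damaged=bool(usable and r.pcc < pcc_threshold)))
    return out


def class_overrepresentation(
    selected: set[str],
    universe: Sequence[TranscriptRecord],
) -> list[ClassEnrichment]:
    """Hypergeometric upper-tail over-representation of each RNA class
    within the selected set, BH-adjusted across classes."""
    if not universe:
        raise ValueError("empty universe")
    ids = {t.id for t in universe}
    stray = selected - ids
    if stray:
        raise ValueError(f"selected ids outside the universe: {sorted(stray)[:5]}")
    n_universe, n_selected = len(universe), len(selected)
    rows = []
    for rna_class in RNA_CLASSES:
        class_ids = {t.id for t in universe if t.rna_class == rna_class}
        k = len(selected & class_ids)
        p = hypergeom_upper_tail(k, n_universe, len(class_ids), n_selected)
        rows.append((rna_class, len(class_ids), k, p))
    adj = bh_adjust([r[3] for r in rows])
    return [
        ClassEnrichment(rna_class, n_universe, n_class, n_selected, k, p, float(q))
        for (rna_class, n_class, k, p), q in zip(rows, adj)
    ]


def overlap_test(set_a: set[str], set_b: set[str], universe_size: int) -> float:
    """Upper-tail probability of an overlap at least as large as
    observed when two sets of these sizes are drawn independently at
    random from the universe."""
    if max(len(set_a), len(set_b)) > universe_size:
        raise ValueError("set larger than universe")
    overlap = len(set_a & set_b)
    return hypergeom_upper_tail(overlap, universe_size, len(set_a), len(set_b))


# ---------------------------------------------------------------------------
# model / results facade

class IntegrityModel:
    """Pairwise damage scan between two coverage samples.

    Three-way designs (e.g. two stress conditions against one reference)
    are run as separate pairwise models; there is no joint model.
    """

    def __init__(
        self,
        profiles_a: Mapping[str, CoverageProfile],
        profiles_b: Mapping[str, CoverageProfile],
        transcripts: Sequence[TranscriptRecord],
    ):
        self.transcripts = list(transcripts)
        missing = [t.id for t in self.transcripts if t.id not in profiles_a or t.id not in profiles_b]
        if missing:
            raise ValueError(f"profiles missing for transcripts: {missing[:5]}")
        self.profiles_a = dict(profiles_a)
        self.profiles_b = dict(profiles_b)

    @classmethod
    def from_bedgraphs(
        cls,
        path_a: str,
        path_b: str,
        transcripts: Sequence[TranscriptRecord],
    ) -> "IntegrityModel":
        return cls(
            load_coverage(path_a, transcripts, sample_id="A"),
            load_coverage(path_b, transcripts, sample_id="B"),
            transcripts,
        )

    def fit(self, pcc_threshold: float = 0.5, min_mean_cov: float = 10.0) -> "IntegrityResults":
        per_gene = [
            gene_pcc(self.profiles_a[t.id], self.profiles_b[t.id], min_mean_cov=min_mean_cov)
            for t in self.transcripts
        ]
        per_gene = call_damaged(per_gene, pcc_threshold=pcc_threshold, min_mean_cov=min_mean_cov)
        ranked = rank_pcc(per_gene) if any(r.defined for r in per_gene) else []
        undefined = [r for r in per_gene if not r.defined]
        return IntegrityResults(self, ranked, undefined, pcc_threshold, min_mean_cov)


@dataclass
class IntegrityResults:
    model: IntegrityModel
    ranked: list[GenePCC]
    undefined: list[GenePCC]
    pcc_threshold: float
    min_mean_cov: float
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def damaged_ids(self) -> set[str]:
        return {r.transcript_id for r in self.ranked if r.damaged}

    @property
    def n_damaged(self) -> int:
        return len(self.damaged_ids)

    def table(self) -> pd.DataFrame:
        """Ranked per-gene table (descending PCC)."""
        if self._table is None:
            self._table = pd.DataFrame(
                [(r.rank, r.transcript_id, r.pcc, r.mean_cov_a, r.mean_cov_b, r.damaged)
                 for r in self.ranked],
                columns=["rank", "transcript_id", "pcc", "mean_cov_a", "mean_cov_b", "damaged"],
            )
        return self._table

    def class_enrichment(self) -> list[ClassEnrichment]:
        """Over-representation of each RNA class among damaged genes."""
        return class_overrepresentation(self.damaged_ids, self.model.transcripts)

    def plot_rank(self, ax=None):
        """Rank-vs-PCC curve (all genes, descending)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.table()
        ax.plot(tab["rank"], tab["pcc"], lw=1)
        ax.axhline(self.pcc_threshold, color="red", ls="--", lw=0.8)
        ax.set_xlabel("gene rank")
        ax.set_ylabel("Pearson correlation of coverage profiles")
        return ax

    def summary(self) -> str:
        lines = [
            "Coverage-correlation damage scan",
            "=" * 34,
            f"genes scored:    {len(self.ranked)}",
            f"undefined PCC:   {len(self.undefined)}",
            f"damaged (PCC < {self.pcc_threshold:g}): {self.n_damaged}",
            "",
            "class over-representation among damaged genes:",
        ]
        for e in self.class_enrichment():
            flag = " *" if e.p_value < 0.05 else ""
            lines.append(
                f"  {e.rna_class:>10}  {e.n_selected_in_class}/{e.n_class}"
                f"  p={e.p_value:.3g}  p_adj={e.p_adjusted:.3g}{flag}"
            )
        return "\n".join(lines)
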