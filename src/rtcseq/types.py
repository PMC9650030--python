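"""Core domain types shared across the pipeline.

Coordinates follow the bioinformatics double convention: all in-memory
positions are 1-based inclusive (the convention of GFF, SAM and the
figures this pipeline emulates), while on-disk BED/bedGraph intervals are
0-based half-open.  Conversion happens only in :mod:`rtcseq.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: RNA classes recognised by the generators and the enrichment tests.
RNA_CLASSES = ("tRNA", "rRNA", "ncRNA", "tmRNA", "CDS", "pseudogene")

#: Names of the eight structural domains of the tmRNA (ssrA): the
#: tRNA-like domain, mRNA-like domain, helices 2 and 5, pseudoknots 1-4.
TMRNA_DOMAINS = ("TLD", "MLD", "H2", "H5", "PK1", "PK2", "PK3", "PK4")

_ALPHABET = set("ACGTUN")


def rna_to_dna(seq: str) -> str:
    """Transcribe an RNA-alphabet string to DNA (U -> T), uppercased."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """A reference RNA: the universe element for every statistic.

    The sequence is stored DNA-normalised (U transcribed to T) so that
    generated FASTA/FASTQ files and string matching share one alphabet.
    """

    id: str
    sequence: str
    rna_class: str

    def __post_init__(self):
        seq = rna_to_dna(self.sequence)
        if not seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"transcript {self.id!r}: illegal characters {sorted(bad)}")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"transcript {self.id!r}: unknown rna_class {self.rna_class!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named structural interval on a transcript, 1-based inclusive."""

    transcript_id: str
    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain {self.name!r} on {self.transcript_id!r}: "
                f"need 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class DamageSpec:
    """Planted cleavage for the coverage generator.

    A fraction ``cleaved_fraction`` of molecules is cut at
    ``cleavage_site``; of the cut molecules, ``retain_5p`` of the
    upstream fragments and ``retain_3p`` of the downstream fragments
    survive in the library.  Expected coverage is therefore multiplied by
    ``1 - f + f * retain_5p`` upstream of the site (inclusive) and
    ``1 - f + f * retain_3p`` downstream.
    """

    transcript_id: str
    cleavage_site: int
    cleaved_fraction: float
    retain_5p: float = 1.0
    retain_3p: float = 0.0

    def __post_init__(self):
        for name in ("cleaved_fraction", "retain_5p", "retain_3p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cleavage_site < 1:
            raise ValueError(f"cleavage_site must be >= 1, got {self.cleavage_site}")


#: The 21-nt invariant core of the RtcB capture adapter; the four 5'
#: bases of the full oligo are random and never counted as target.
ADAPTER_CORE = "TGGAATTGTCGGGTGCCAAGG"


@dataclass(frozen=True)
class AdapterSpec:
    """The ligated capture adapter: N random 5' bases + invariant core."""

    core: str = ADAPTER_CORE
    n_random_5p: int = 4
    max_mismatches: int = 0

    def __post_init__(self):
        if not self.core:
            raise ValueError("adapter core must be non-empty")
        if self.n_random_5p < 0:
            raise ValueError("n_random_5p must be >= 0")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        object.__setattr__(self, "core", rna_to_dna(self.core))


@dataclass
class CoverageProfile:
    """Per-position read counts for one transcript in one sample."""

    transcript_id: str
    sample_id: str
    counts: np.ndarray
    library_size: int | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.library_size is None:
            self.library_size = int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def mean_coverage(self) -> float:
        return float(self.counts.mean())


@dataclass(frozen=True)
class LigationEvent:
    """A called adapter-ligation junction.

    ``junction`` is the 1-based transcript coordinate of the target RNA
    3' terminus to which the adapter was ligated — the last target base
    before the adapter in the read.
    """

    read_id: str
    transcript_id: str
    junction: int
    n_mismatches_mapping: int = 0
    random_bases: str = ""

    def __post_init__(self):
        if self.junction < 1:
            raise ValueError(f"junction must be >= 1, got {self.junction}")


@dataclass
class KineticsSeries:
    """(time, signal) pairs from an induction time course."""

    time: np.ndarray
    signal: np.ndarray
    background: float = 0.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D vectors")
        if len(self.time) < 4:
            raise ValueError("a kinetics series needs at least 4 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.time < 0) or np.any(self.signal < 0):
            raise ValueError("times and signals must be non-negative")

    def __len__(self) -> int:
        return len(self.time)
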