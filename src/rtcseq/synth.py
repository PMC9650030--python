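"""Seeded synthetic data with the statistical structure each analysis
stage assumes, plus machine-readable ground truth for scoring recovery.

The generators emulate, at desk scale, the three kinds of raw input the
pipeline consumes:

* per-position coverage tracks with and without cleavage-induced shape
  changes (for the Pearson-correlation damage statistic);
* sequencing reads of the form target-3'-fragment + 4 random bases +
  21-nt adapter core (for ligation-junction calling);
* quadratic-onset product-accumulation time courses sampled at fixed
  intervals (for the Schleif elongation-speed estimator).

Everything is byte-reproducible given a seed.  All sequence output uses
the DNA alphabet; the printed RNA oligos below are transcribed to DNA on
ingestion by :class:`~rtcseq.types.TranscriptRecord`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ADAPTER_CORE,
    RNA_CLASSES,
    TMRNA_DOMAINS,
    AdapterSpec,
    CoverageProfile,
    DamageSpec,
    DomainAnnotation,
    KineticsSeries,
    TranscriptRecord,
    rna_to_dna,
)

#: tRNA-Glu anticodon stem-loop fragments used as worked examples for
#: junction calling: the 35-mer spans the whole anticodon stem-loop, the
#: 17-mer is its 5' half.
TRNA_GLU_35MER = "ACUCCGAUAUCACGCUUUCACCGUGAUAUCGGAGU"
TRNA_GLU_17MER = "ACUCCGAUAUCACGCUU"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _stable_seed(*parts) -> list[int]:
    """Deterministic cross-run seed sequence from ints and strings."""
    out = []
    for p in parts:
        out.append(p if isinstance(p, (int, np.integer)) else zlib.crc32(str(p).encode()))
    return [int(x) & 0x7FFFFFFF for x in out]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# transcriptome

#: Default fractional layout of the eight tmRNA structural domains.
#: Positions are fractions of transcript length; TLD is the composite
#: 5'+3' tRNA-like domain, so it is split into its two arms here and
#: annotated as one interval covering the 5' arm (annotations may
#: overlap, as on the real molecule).
DEFAULT_TMRNA_LAYOUT: dict[str, tuple[float, float]] = {
    "TLD": (0.00, 0.15),
    "H2": (0.12, 0.22),
    "PK1": (0.20, 0.30),
    "MLD": (0.28, 0.55),
    "PK2": (0.55, 0.65),
    "PK3": (0.65, 0.75),
    "PK4": (0.75, 0.85),
    "H5": (0.85, 1.00),
}


def gen_transcriptome(
    n_per_class: Mapping[str, int],
    length_range: tuple[int, int] = (60, 400),
    seed: int = 0,
    tmrna_layout: Mapping[str, tuple[float, float]] = DEFAULT_TMRNA_LAYOUT,
) -> tuple[list[TranscriptRecord], list[DomainAnnotation]]:
    """Generate random transcripts per RNA class plus the eight-domain
    annotation of the (first) tmRNA-class transcript.

    Returns ``(transcripts, domains)``; IDs are ``<class>_<k>``.
    """
    if not n_per_class or all(v == 0 for v in n_per_class.values()):
        raise ValueError("nothing to generate: empty class map")
    lo, hi = length_range
    if lo < 30 or hi < lo:
        raise ValueError(f"length_range must satisfy 30 <= min <= max, got {length_range}")
    unknown = set(n_per_class) - set(RNA_CLASSES)
    if unknown:
        raise ValueError(f"unknown RNA classes: {sorted(unknown)}")

    rng = np.random.default_rng(_stable_seed(seed, "transcriptome"))
    transcripts: list[TranscriptRecord] = []
    for rna_class in RNA_CLASSES:  # fixed order -> determinism
        for k in range(n_per_class.get(rna_class, 0)):
            length = int(rng.integers(lo, hi + 1))
            transcripts.append(
                TranscriptRecord(f"{rna_class}_{k + 1}", _random_seq(rng, length), rna_class)
            )

    domains: list[DomainAnnotation] = []
    tmrna = next((t for t in transcripts if t.rna_class == "tmRNA"), None)
    if tmrna is not None:
        for name in TMRNA_DOMAINS:
            f0, f1 = tmrna_layout[name]
            start = max(1, int(round(f0 * tmrna.length)) + 1)
            end = min(tmrna.length, max(start, int(round(f1 * tmrna.length))))
            domains.append(DomainAnnotation(tmrna.id, name, start, end))
    return transcripts, domains


# ---------------------------------------------------------------------------
# coverage

def _positional_rate(transcript: TranscriptRecord, depth: float, profile_seed: int) -> np.ndarray:
    """Smooth positive per-position rate with mean ``depth``.

    Smoothed white noise in log-rate (correlation length ~10 nt,
    sd ~0.25 log-units) — non-constant by construction (a constant
    profile has undefined Pearson correlation) but free of
    low-frequency drift, so an intact profile never mimics a truncated
    one.  Depends only on (profile_seed, transcript id), so samples
    generated in separate calls share the intact shape.
    """
    rng = np.random.default_rng(_stable_seed(profile_seed, "rate", transcript.id))
    noise = rng.normal(0.0, 0.8, size=transcript.length)
    kernel = np.ones(9) / 9.0
    smooth = np.convolve(noise, kernel, mode="same")
    rate = np.exp(smooth - smooth.mean())
    return depth * rate / rate.mean()


def gen_coverage(
    transcripts: Sequence[TranscriptRecord],
    depth: float,
    damage: Sequence[DamageSpec] = (),
    noise: str = "poisson",
    seed: int = 0,
    sample_id: str = "S1",
    profile_seed: int = 0,
) -> dict[str, CoverageProfile]:
    """One coverage sample: per-transcript per-position counts.

    Undamaged transcripts follow the shared smooth positional rate; a
    :class:`DamageSpec` multiplies the expected rate by
    ``1 - f + f*retain_5p`` up to the cleavage site (inclusive) and
    ``1 - f + f*retain_3p`` beyond it.  ``noise="poisson"`` draws counts;
    ``noise="none"`` rounds the expectation.
    """
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    if noise not in ("poisson", "none"):
        raise ValueError(f"noise must be 'poisson' or 'none', got {noise!r}")
    by_id = {t.id: t for t in transcripts}
    damage_map: dict[str, DamageSpec] = {}
    for d in damage:
        if d.transcript_id not in by_id:
            raise ValueError(f"damage references unknown transcript {d.transcript_id!r}")
        if d.cleavage_site > by_id[d.transcript_id].length:
            raise ValueError(
                f"cleavage_site {d.cleavage_site} outside transcript "
                f"{d.transcript_id!r} (length {by_id[d.transcript_id].length})"
            )
        damage_map[d.transcript_id] = d

    profiles: dict[str, CoverageProfile] = {}
    for t in transcripts:
        rate = _positional_rate(t, depth, profile_seed)
        d = damage_map.get(t.id)
        if d is not None:
            f = d.cleaved_fraction
            up = 1.0 - f + f * d.retain_5p
            down = 1.0 - f + f * d.retain_3p
            factors = np.where(np.arange(1, t.length + 1) <= d.cleavage_site, up, down)
            rate = rate * factors
        if noise == "poisson":
            rng = np.random.default_rng(_stable_seed(seed, "cov", t.id, sample_id))
            counts = rng.poisson(rate)
        else:
            counts = np.rint(rate).astype(int)
        profiles[t.id] = CoverageProfile(t.id, sample_id, counts)
    return profiles


def expected_coverage(
    transcript: TranscriptRecord,
    depth: float,
    damage: DamageSpec | None = None,
    profile_seed: int = 0,
) -> np.ndarray:
    """Ground-truth expected per-position rate (for scoring)."""
    rate = _positional_rate(transcript, depth, profile_seed)
    if damage is not None:
        f = damage.cleaved_fraction
        up = 1.0 - f + f * damage.retain_5p
        down = 1.0 - f + f * damage.retain_3p
        factors = np.where(
            np.arange(1, transcript.length + 1) <= damage.cleavage_site, up, down
        )
        rate = rate * factors
    return rate


# ---------------------------------------------------------------------------
# adapter-ligated reads

@dataclass
class ReadSet:
    """Generated reads plus the truth table needed to score recovery."""

    reads: list[tuple[str, str]]
    truth: pd.DataFrame  # read_id, has_adapter, transcript_id, junction, random_bases


def gen_ligated_reads(
    transcripts: Sequence[TranscriptRecord],
    sites: Sequence[tuple[str, int]],
    adapter: AdapterSpec = AdapterSpec(),
    n_reads: int = 1000,
    frac_with_adapter: float = 0.7,
    read_len: int = 75,
    fragment_range: tuple[int, int] = (20, 50),
    seed: int = 0,
) -> ReadSet:
    """Simulate an RtcB adapter-capture library.

    Adapter-bearing reads are ``target[(j-k+1)..j] + N*n_random_5p +
    core``, truncated to ``read_len``, where ``j`` is a planted 3'
    terminus drawn from ``sites`` and ``k`` a fragment length drawn from
    ``fragment_range`` (clipped at the transcript 5' end).  The
    remaining reads are adapter-free sense-strand background fragments,
    screened so they contain no detectable adapter.  Exactly
    ``round(frac_with_adapter * n_reads)`` reads carry the adapter.
    """
    from .ligation import find_adapter  # local import: synth is upstream of ligation

    if not 0.0 <= frac_with_adapter <= 1.0:
        raise ValueError(f"frac_with_adapter must lie in [0, 1], got {frac_with_adapter}")
    by_id = {t.id: t for t in transcripts}
    for tid, j in sites:
        if tid not in by_id:
            raise ValueError(f"site references unknown transcript {tid!r}")
        if not 1 <= j <= by_id[tid].length:
            raise ValueError(f"site {j} outside transcript {tid!r}")

    rng = np.random.default_rng(_stable_seed(seed, "reads"))
    n_adapter = int(round(frac_with_adapter * n_reads))
    if n_adapter > 0 and not sites:
        raise ValueError("adapter-bearing reads requested but no sites given")

    reads: list[tuple[str, str]] = []
    rows = []
    k_lo, k_hi = fragment_range
    for i in range(n_adapter):
        tid, j = sites[int(rng.integers(len(sites)))]
        seq = by_id[tid].sequence
        k = min(int(rng.integers(k_lo, k_hi + 1)), j)
        target = seq[j - k : j]
        random_bases = _random_seq(rng, adapter.n_random_5p)
        read = (target + random_bases + adapter.core)[:read_len]
        rid = f"lig_{i + 1}"
        reads.append((rid, read))
        rows.append((rid, True, tid, j, random_bases))

    tids = [t.id for t in transcripts]
    for i in range(n_reads - n_adapter):
        while True:  # redraw until no adapter is detectable, per contract
            tid = tids[int(rng.integers(len(tids)))]
            seq = by_id[tid].sequence
            k = min(int(rng.integers(k_lo, k_hi + 1)), len(seq))
            start = int(rng.integers(0, len(seq) - k + 1))
            frag = seq[start : start + k][:read_len]
            if find_adapter(frag, adapter) is None:
                break
        rid = f"bg_{i + 1}"
        reads.append((rid, frag))
        rows.append((rid, False, tid, -1, ""))

    truth = pd.DataFrame(
        rows, columns=["read_id", "has_adapter", "transcript_id", "junction", "random_bases"]
    )
    return ReadSet(reads, truth)


# ---------------------------------------------------------------------------
# kinetics

def gen_schleif(
    speed: float,
    protein_len: int = 774,
    interval: float = 20.0,
    duration: float = 600.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
) -> KineticsSeries:
    """Product-accumulation time course for a first-wave reporter.

    No full-length protein exists before one ribosome has traversed the
    ORF, so the expected signal is 0 until ``T = protein_len / speed``
    and grows as ``amplitude * (t - T)**2`` afterwards (new ribosomes
    keep initiating, so completion flux ramps linearly and its integral
    is quadratic).  Gaussian noise of sd ``noise_sd`` is added and the
    result floored at 0.  Sampling starts at t = 0 on a fixed grid.
    """
    if speed <= 0:
        raise ValueError(f"speed must be > 0, got {speed}")
    if interval <= 0:
        raise ValueError(f"interval must be > 0, got {interval}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    t = np.arange(0.0, duration + 0.5 * interval, interval)
    T = protein_len / speed
    signal = np.where(t < T, 0.0, amplitude * (t - T) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(_stable_seed(seed, "schleif"))
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return KineticsSeries(t, np.maximum(signal, 0.0))


def gen_fidelity(
    mu_wt: float,
    miscoding_true: float,
    n_rep: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
    reporters: Sequence[str] = ("frameshift", "premature_stop"),
) -> pd.DataFrame:
    """Replicate Miller-unit measurements for wild-type and error
    reporters; error-reporter expectation is ``mu_wt * miscoding_true``.

    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean-preserving parameterisation).
    """
    if mu_wt <= 0:
        raise ValueError(f"mu_wt must be > 0, got {mu_wt}")
    if miscoding_true < 0:
        raise ValueError(f"miscoding_true must be >= 0, got {miscoding_true}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    rng = np.random.default_rng(_stable_seed(seed, "fidelity"))
    sigma2 = np.log1p(noise_cv**2)
    rows = []
    for reporter in ("wildtype", *reporters):
        mean = mu_wt if reporter == "wildtype" else mu_wt * miscoding_true
        for rep in range(1, n_rep + 1):
            if mean == 0 or noise_cv == 0:
                value = mean
            else:
                value = float(
                    np.exp(rng.normal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)))
                )
            rows.append((reporter, rep, value))
    return pd.DataFrame(rows, columns=["reporter", "replicate", "miller_units"])
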