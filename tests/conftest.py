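import pytest
from hypothesis import settings

from rtcseq import synth

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_transcriptome():
    """Mixed-class transcriptome with an annotated tmRNA (seeded)."""
    transcripts, domains = synth.gen_transcriptome(
        {"tRNA": 10, "CDS": 30, "ncRNA": 5, "pseudogene": 4, "tmRNA": 1},
        length_range=(60, 400),
        seed=11,
    )
    return transcripts, domains


@pytest.fixture(scope="session")
def planted_damage_run():
    """200-transcript universe with 20 fully-truncated tRNAs at depth 100,
    noise-free: the reference scenario for damage-detection checks."""
    from rtcseq.types import DamageSpec

    transcripts, _ = synth.gen_transcriptome(
        {"tRNA": 40, "CDS": 140, "ncRNA": 14, "pseudogene": 5, "tmRNA": 1},
        length_range=(60, 400),
        seed=1,
    )
    damaged = [t for t in transcripts if t.rna_class == "tRNA"][:20]
    specs = [DamageSpec(t.id, t.length // 2, 1.0, 1.0, 0.0) for t in damaged]
    prof_a = synth.gen_coverage(transcripts, 100, noise="none", sample_id="A")
    prof_b = synth.gen_coverage(transcripts, 100, specs, noise="none", sample_id="B")
    return transcripts, {t.id for t in damaged}, prof_a, prof_b
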