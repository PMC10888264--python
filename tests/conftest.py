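import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tripscan.align import RepeatHit
from tripscan.reference import builtin_registry
from tripscan.resolve import TypedHit

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(bases, size=n, p=p).tobytes().decode()


def make_hit(
    start,
    end,
    contig="chr",
    strand="+",
    score=100,
    identity=1.0,
    coverage=1.0,
    type_id="A",
    genome_id="g",
) -> RepeatHit:
    return RepeatHit(genome_id, contig, start, end, strand, score, identity, coverage, type_id)


def make_typed_hit(
    start,
    end,
    contig="chr",
    strand="+",
    final_type="A",
    orientation="forward",
    score=100,
    genome_id="g",
) -> TypedHit:
    return TypedHit(
        genome_id=genome_id,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        raw_score=score,
        identity=1.0,
        coverage=1.0,
        candidate_type=final_type,
        final_type=final_type,
        orientation=orientation,
    )


def gotoh_oracle(q: str, s: str, match=2, mismatch=-3, gap_open=5, gap_extend=2) -> int:
    """Plain full-matrix affine-gap local alignment score (reference implementation)."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            sub = match if (qi == s[j - 1] and qi in "ACGT") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
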