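"""Affine-gap local alignment and repeat-copy detection.

The search re-implements a BLASTN-style scan as explicit Smith-Waterman/Gotoh
dynamic programming: match +2 / mismatch -3 substitution scores with an affine
gap model in which a gap of length *k* costs ``gap_open + k * gap_extend``
(defaults 5 and 2, the published search settings).  Candidate regions are
located by exact 12-mer seeding and each candidate window is then aligned with
the full DP matrix, so every reported hit carries its true optimal local score.

Hits are filtered by the family's length-coverage rule: an alignment must
cover at least ``min_coverage`` (default 0.80) of the reference repeat length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "AlignmentParams",
    "LocalAlignment",
    "RepeatHit",
    "reverse_complement",
    "local_align",
    "find_repeats",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# base encoding: A,C,G,T -> 0..3, N/ambiguous -> 4 (mismatches everything,
# including another N)
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))
    except KeyError as exc:
        raise ValueError(f"unknown base {exc.args[0]!r}") from None


def encode(sequence: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"unknown base {bad!r}")
    return codes


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and filtering parameters for the repeat search.

    ``min_score`` of ``None`` means the finder default: half the maximum
    attainable score of the shortest reference (0.5 * match_reward * 146 = 146
    for the bundled family).
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_coverage: float = 0.8
    min_identity: float = 0.0
    min_score: int | None = None
    seed_k: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.mismatch_penalty >= 0 or self.match_reward <= 0:
            raise ValueError("match_reward must be > 0 and mismatch_penalty < 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query against a subject (1-based inclusive spans)."""

    score: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    n_columns: int
    n_matches: int

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class RepeatHit:
    """One retained repeat copy, on forward-strand contig coordinates."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    raw_score: int
    identity: float
    coverage: float
    candidate_type: str

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "RepeatHit") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@njit(cache=False)
def _gotoh_fill(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    m, n = q.size, s.size
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)  # gap in query (consumes subject)
    F = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)  # gap in subject (consumes query)
    best = 0
    bi = 0
    bj = 0
    first_gap = gap_open + gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            h_e = H[i, j - 1] - first_gap
            if h_e > e:
                e = h_e
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            h_f = H[i - 1, j] - first_gap
            if h_f > f:
                f = h_f
            F[i, j] = f
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, bi, bj, q, s, match, mismatch, gap_open, gap_extend):
    """Recover spans and column/match counts from filled Gotoh matrices."""
    first_gap = gap_open + gap_extend
    i, j = bi, bj
    state = "H"
    n_cols = 0
    n_matches = 0
    qe, se = bi, bj
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            if h == H[i - 1, j - 1] + sub:
                n_cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    n_matches += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            n_cols += 1
            if E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            n_cols += 1
            if F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return i + 1, qe, j + 1, se, n_cols, n_matches


def _align_codes(q: np.ndarray, s: np.ndarray, params: AlignmentParams) -> LocalAlignment:
    H, E, F, best, bi, bj = _gotoh_fill(
        q, s, params.match_reward, params.mismatch_penalty, params.gap_open, params.gap_extend
    )
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    qs, qe, ss, se, n_cols, n_matches = _traceback(
        H, E, F, bi, bj, q, s, params.match_reward, params.mismatch_penalty, params.gap_open, params.gap_extend
    )
    return LocalAlignment(int(best), qs, qe, ss, se, n_cols, n_matches)


def local_align(query: str, subject: str, params: AlignmentParams | None = None) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``subject``.

    Spans in the result are 1-based inclusive.  A result with score 0 means no
    positive-scoring local alignment exists.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    params = params or AlignmentParams()
    return _align_codes(encode(query), encode(subject), params)


# ---------------------------------------------------------------------------
# Seeded genome scan
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_clusters(query: str, index: dict[str, list[int]], k: int, qlen: int) -> list[tuple[int, int]]:
    """Subject-position clusters of exact k-mer seed matches.

    Returns a list of (min_subject_pos, max_subject_pos) 0-based seed ranges;
    seeds closer than the query length are merged into one cluster.
    """
    positions: list[int] = []
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if kmer in index:
            positions.extend(index[kmer])
    if not positions:
        return []
    positions.sort()
    clusters = []
    lo = hi = positions[0]
    for p in positions[1:]:
        if p - hi > qlen:
            clusters.append((lo, hi))
            lo = p
        hi = p
    clusters.append((lo, hi))
    return clusters


def _window_hits(
    contig_codes: np.ndarray,
    q_codes: np.ndarray,
    w_start: int,
    w_end: int,
    params: AlignmentParams,
    min_score: int,
    ref_len: int,
    max_copies: int = 8,
) -> list[tuple[int, int, int, float, float]]:
    """All qualifying local alignments inside the window [w_start, w_end) (0-based).

    Repeated alignment with masking of each accepted subject span, so multiple
    copies falling into one merged window are all recovered.
    Returns tuples of (start, end, score, identity, coverage) with 1-based
    inclusive contig coordinates.
    """
    window = contig_codes[w_start:w_end].copy()
    out = []
    for _ in range(max_copies):
        aln = _align_codes(q_codes, window, params)
        if aln.score < min_score:
            break
        coverage = aln.query_span / ref_len
        if coverage >= params.min_coverage and aln.identity >= params.min_identity:
            out.append(
                (
                    w_start + aln.subject_start,
                    w_start + aln.subject_end,
                    aln.score,
                    aln.identity,
                    coverage,
                )
            )
        # mask the aligned span (code 4 mismatches everything) and re-scan
        window[aln.subject_start - 1 : aln.subject_end] = 4
    return out


def find_repeats(
    contigs: dict[str, str],
    registry: dict,
    params: AlignmentParams | None = None,
    genome_id: str = "genome",
) -> list[RepeatHit]:
    """Scan both strands of every contig for copies of every reference type.

    Minus-strand hits are reported on forward-strand contig coordinates with
    ``strand='-'``.  Hits are sorted by (contig, start, end, type).
    """
    params = params or AlignmentParams()
    if params.min_score is not None:
        min_score = params.min_score
    elif registry:
        min_score = int(0.5 * params.match_reward * min(len(r.sequence) for r in registry.values()))
    else:
        min_score = 0
    k = params.seed_k
    hits: list[RepeatHit] = []
    for contig_id, seq in contigs.items():
        seq = seq.upper()
        contig_codes = encode(seq)
        index = _kmer_index(seq, k)
        L = len(seq)
        for ref in registry.values():
            ref_len = len(ref.sequence)
            for strand in ("+", "-"):
                query = ref.sequence if strand == "+" else reverse_complement(ref.sequence)
                q_codes = encode(query)
                seen: set[tuple[int, int]] = set()
                for lo, hi in _seed_clusters(query, index, k, ref_len):
                    w_start = max(0, lo - ref_len)
                    w_end = min(L, hi + k + ref_len)
                    if (w_start, w_end) in seen:
                        continue
                    seen.add((w_start, w_end))
                    for start, end, score, ident, cov in _window_hits(
                        contig_codes, q_codes, w_start, w_end, params, min_score, ref_len
                    ):
                        hits.append(
                            RepeatHit(
                                genome_id=genome_id,
                                contig_id=contig_id,
                                start=start,
                                end=end,
                                strand=strand,
                                raw_score=score,
                                identity=ident,
                                coverage=cov,
                                candidate_type=ref.type_id,
                            )
                        )
    # merged windows can overlap across seed clusters; drop exact duplicates
    unique = {(h.contig_id, h.start, h.end, h.strand, h.candidate_type): h for h in hits}
    return sorted(unique.values(), key=lambda h: (h.contig_id, h.start, h.end, h.candidate_type, h.strand))
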