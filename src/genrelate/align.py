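"""Seed–chain–extend local nucleotide alignment producing HSPs.

This is a self-contained BLASTN-style aligner: exact k-mer seeds on both
strands, per-diagonal maximal-segment extension with an x-drop split rule,
chaining of nearby segments across diagonals, and a banded affine-gap
Smith–Waterman refinement of chained regions.  Raw scores are normalised to
bit scores with the Karlin–Altschul formula ``(lambda * S - ln K) / ln 2``.

Conventions
-----------
* HSP coordinates are 0-based half-open on the forward strand of both the
  query and the subject; ``strand`` records the orientation of the match
  (``-`` means the reverse complement of the query matched the subject).
* A gap of length L scores ``gap_open + L * gap_extend`` (both negative).
* Ambiguous bases (``N``) never match anything, including another ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqs import GenomeSequence, encode, reverse_complement

__all__ = [
    "ScoringScheme",
    "HSP",
    "KmerIndex",
    "index_subject",
    "find_hsps",
    "bit_score",
    "read_alignment_tsv",
]

# Contig spacer inside the concatenated subject array.  Longer than the
# maximum chaining gap so no HSP or chain can bridge two contigs.
_SPACER_LEN = 64


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin–Altschul constants.

    Defaults mirror common BLASTN megablast-style settings: match +2,
    mismatch -3, gap open -5, gap extend -2, lambda 0.625 nats per raw-score
    unit, K 0.41, word size 11, x-drop 20.
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 0.625
    k: float = 0.41
    kmer_size: int = 11
    x_drop: int = 20

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0 < self.k < 1:
            raise ValueError("K must be in (0, 1)")
        if self.kmer_size < 8:
            raise ValueError("kmer_size must be >= 8")
        if self.x_drop <= 0:
            raise ValueError("x_drop must be positive")


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Karlin–Altschul normalised score: ``(lambda*S - ln K) / ln 2`` bits."""
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    return (scheme.lam * raw_score - math.log(scheme.k)) / math.log(2.0)


@dataclass
class HSP:
    """A high-scoring segment pair between a query and a subject contig.

    ``cigar`` is a list of ``(op, length)`` with ops ``M`` (aligned column),
    ``I`` (query base against a gap) and ``D`` (subject base against a gap),
    expressed in the orientation of the match (for ``strand == '-'`` the ops
    walk along the reverse complement of the query).
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    alignment_length: int
    identities: int
    raw_score: int
    bit_score: float
    cigar: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.identities <= self.alignment_length):
            raise ValueError("identities out of range")
        if self.query_end <= self.query_start or self.subject_end <= self.subject_start:
            raise ValueError("end must exceed start")

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.alignment_length

    def rescore(self, query: str, subject: str, scheme: ScoringScheme) -> int:
        """Walk the cigar over the aligned substrings and re-derive raw_score.

        Used to check the coordinate round-trip invariant: the returned value
        must equal ``self.raw_score`` exactly.
        """
        q = query[self.query_start : self.query_end]
        if self.strand == "-":
            q = reverse_complement(q)
        s = subject[self.subject_start : self.subject_end]
        qi = si = 0
        score = 0
        for op, n in self.cigar:
            if op == "M":
                for _ in range(n):
                    a, b = q[qi], s[si]
                    if a == b and a != "N":
                        score += scheme.match_reward
                    else:
                        score += scheme.mismatch_penalty
                    qi += 1
                    si += 1
            elif op == "I":
                score += scheme.gap_open + n * scheme.gap_extend
                qi += n
            elif op == "D":
                score += scheme.gap_open + n * scheme.gap_extend
                si += n
            else:  # pragma: no cover - defensive
                raise ValueError(f"bad cigar op {op!r}")
        if qi != len(q) or si != len(s):
            raise ValueError("cigar does not span the HSP coordinates")
        return score


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer codes of every k-window and a validity mask (no N)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    code = np.zeros(n, np.int64)
    valid = np.ones(n, bool)
    for j in range(k):
        w = arr[j : j + n]
        code = code * 4 + (w & 3)
        valid &= w < 4
    return code, valid


class KmerIndex:
    """Exact-match k-mer index over all contigs of a subject genome.

    Contigs are concatenated with runs of ``N`` spacers; only the forward
    strand is indexed — reverse-complement matches are found by scanning the
    reverse complement of the query (documented choice).  Sequences made only
    of ambiguous bases yield an empty index.
    """

    def __init__(
        self,
        subject: GenomeSequence,
        kmer_size: int,
        max_kmer_occurrences: int = 200,
    ) -> None:
        self.subject = subject
        self.k = kmer_size
        self.max_occ = max_kmer_occurrences
        parts: list[np.ndarray] = []
        self._offsets: list[tuple[int, int, str]] = []  # (start, end, contig)
        pos = 0
        spacer = np.full(_SPACER_LEN, 4, np.uint8)
        for name, seq in subject.iter_contigs():
            if parts:
                parts.append(spacer)
                pos += _SPACER_LEN
            a = encode(seq)
            parts.append(a)
            self._offsets.append((pos, pos + len(a), name))
            pos += len(a)
        self.arr = (
            np.concatenate(parts) if parts else np.empty(0, np.uint8)
        )
        codes, valid = _kmer_codes(self.arr, self.k)
        positions = np.nonzero(valid)[0]
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        codes = codes[order]
        self.positions = positions[order].astype(np.int64)
        self.unique_codes, self.starts, self.counts = np.unique(
            codes, return_index=True, return_counts=True
        )
        if len(self.arr) and self.is_empty:
            import warnings

            warnings.warn(
                f"subject {subject.id!r} yields no indexable {self.k}-mers "
                "(too short or ambiguous bases only)",
                stacklevel=3,
            )

    @property
    def is_empty(self) -> bool:
        return len(self.unique_codes) == 0

    def to_contig(self, start: int, end: int) -> tuple[str, int, int]:
        """Map a [start, end) span in concatenated coordinates to a contig."""
        for c0, c1, name in self._offsets:
            if c0 <= start and end <= c1:
                return name, start - c0, end - c0
        raise ValueError("span crosses a contig boundary")

    def lookup(self, qarr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All seed hits of the query: arrays (query_pos, subject_pos)."""
        if self.is_empty:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qcodes, qvalid = _kmer_codes(qarr, self.k)
        if len(qcodes) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        idx = np.searchsorted(self.unique_codes, qcodes)
        idx_c = np.minimum(idx, len(self.unique_codes) - 1)
        hit = qvalid & (self.unique_codes[idx_c] == qcodes)
        qpos = np.nonzero(hit)[0]
        if len(qpos) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        counts = np.minimum(self.counts[idx_c[qpos]], self.max_occ)
        starts = self.starts[idx_c[qpos]]
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        rep_q = np.repeat(qpos, counts)
        base = np.repeat(starts, counts)
        within = np.arange(total) - np.repeat(
            np.cumsum(counts) - counts, counts
        )
        spos = self.positions[base + within]
        return rep_q, spos


def index_subject(
    subject: GenomeSequence, kmer_size: int, max_kmer_occurrences: int = 200
) -> KmerIndex:
    """Build the k-mer index used by :func:`find_hsps`."""
    return KmerIndex(subject, kmer_size, max_kmer_occurrences)


# ---------------------------------------------------------------------------
# ungapped diagonal segments


def _max_subarray(step: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring contiguous segment (start, end, score) of a step array."""
    cum = np.concatenate(([0], np.cumsum(step, dtype=np.int64)))
    prefmin = np.minimum.accumulate(cum)
    gains = cum[1:] - prefmin[:-1]
    e = int(np.argmax(gains))
    score = int(gains[e])
    end = e + 1
    start = int(np.argmin(cum[:end]))
    return start, end, score


def _diagonal_segments(
    match: np.ndarray, scheme: ScoringScheme
) -> list[tuple[int, int, int, int]]:
    """Maximal scoring segments of one diagonal.

    The diagonal is split wherever a mismatch run alone would exceed the
    x-drop budget; within each piece the single maximal-scoring subsegment is
    taken (so gap-free optima are never truncated by transient dips).
    Returns (start, end, score, n_matches) tuples in diagonal coordinates.
    """
    mr, mp = scheme.match_reward, scheme.mismatch_penalty
    run_split = scheme.x_drop // (-mp) + 1
    mm = ~match
    # boundaries of long mismatch runs
    padded = np.concatenate(([False], mm, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.nonzero(d == 1)[0]
    run_ends = np.nonzero(d == -1)[0]
    long = (run_ends - run_starts) >= run_split
    cut_s = run_starts[long]
    cut_e = run_ends[long]
    pieces: list[tuple[int, int]] = []
    prev = 0
    for a, b in zip(cut_s, cut_e):
        if a > prev:
            pieces.append((prev, a))
        prev = b
    if prev < len(match):
        pieces.append((prev, len(match)))
    out = []
    step_all = np.where(match, mr, mp).astype(np.int64)
    for a, b in pieces:
        s, e, score = _max_subarray(step_all[a:b])
        if e <= s or score <= 0:
            continue
        length = e - s
        nmatch = (score - mp * length) // (mr - mp)
        out.append((a + s, a + e, score, int(nmatch)))
    return out


# ---------------------------------------------------------------------------
# banded affine Smith–Waterman (used to refine chained, gapped regions)


def _banded_sw(
    q: np.ndarray,
    s: np.ndarray,
    dmin: int,
    dmax: int,
    scheme: ScoringScheme,
) -> tuple[int, int, int, int, int, list[tuple[str, int]], int] | None:
    """Local affine alignment of q vs s restricted to diagonals [dmin, dmax].

    Returns (q_start, q_end, s_start, s_end, score, cigar, identities) in
    window coordinates, or None if no positive-scoring alignment exists.
    """
    mr, mp = scheme.match_reward, scheme.mismatch_penalty
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(q), len(s)
    W = dmax - dmin + 1
    NEG = -(10**9)
    H = np.full((n + 1, W), 0, np.int64)
    E = np.full((n + 1, W), NEG, np.int64)  # gap in query (left moves)
    F = np.full((n + 1, W), NEG, np.int64)  # gap in subject (up moves)
    offs = np.arange(W)
    best = (0, -1, -1)  # score, row, band offset
    for i in range(1, n + 1):
        j = i + dmin + offs  # subject column for each band offset, row i
        inb = (j >= 1) & (j <= m)
        sub = np.full(W, NEG, np.int64)
        jj = np.clip(j - 1, 0, m - 1)
        qi = q[i - 1]
        eq = (s[jj] == qi) & (qi < 4) & (s[jj] < 4)
        sub[inb] = np.where(eq[inb], mr, mp)
        diag = H[i - 1] + sub  # same band offset, previous row
        f_prev_h = np.concatenate((H[i - 1][1:], [NEG]))
        f_prev_f = np.concatenate((F[i - 1][1:], [NEG]))
        F[i] = np.maximum(f_prev_h + go + ge, f_prev_f + ge)
        h0 = np.maximum(0, diag)
        h0 = np.maximum(h0, F[i])
        h0[~inb] = NEG
        # E depends on H of the same row; iterate to fixpoint (usually 1-2x)
        h = h0
        for _ in range(8):
            t = h + go - ge * offs
            runmax = np.concatenate(([NEG], np.maximum.accumulate(t)[:-1]))
            e_row = runmax + ge * (offs + 1) - ge  # == runmax + ge*offs? see note
            e_row = runmax + ge * offs
            # e_row[o] = max_{k<o} (h[k] + go + (o-k)*ge)
            h_new = np.maximum(h, e_row)
            h_new[~inb] = NEG
            if np.array_equal(h_new, h):
                E[i] = e_row
                break
            h = h_new
        else:  # pragma: no cover - bounded fixpoint
            E[i] = e_row
        H[i] = h
        row_best = int(h.max(initial=0))
        if row_best > best[0]:
            best = (row_best, i, int(np.argmax(h)))
    score, bi, bo = best
    if score <= 0:
        return None
    # traceback
    cigar_rev: list[str] = []
    ident = 0
    i, o = bi, bo
    state = "H"
    while True:
        j = i + dmin + o
        if state == "H":
            h = H[i][o]
            if h == 0:
                break
            sub_ok = i >= 1 and 1 <= j <= m
            if sub_ok:
                a, b = q[i - 1], s[j - 1]
                msc = mr if (a == b and a < 4) else mp
            if sub_ok and h == H[i - 1][o] + msc:
                cigar_rev.append("M")
                if a == b and a < 4:
                    ident += 1
                i -= 1
                continue
            if h == E[i][o]:
                state = "E"
                continue
            if h == F[i][o]:
                state = "F"
                continue
            break  # pragma: no cover - defensive
        elif state == "E":
            # came from the left: consumes a subject base
            cigar_rev.append("D")
            if o >= 1 and E[i][o] == E[i][o - 1] + ge:
                o -= 1
                continue
            o -= 1
            state = "H"
        else:  # F: consumes a query base
            cigar_rev.append("I")
            if i >= 1 and F[i][o] == F[i - 1][o + 1] + ge:
                i -= 1
                o += 1
                continue
            i -= 1
            o += 1
            state = "H"
    q_start, q_end = i, bi
    s_start, s_end = i + dmin + o, bi + dmin + bo
    # compress cigar
    cigar: list[tuple[str, int]] = []
    for op in reversed(cigar_rev):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return q_start, q_end, s_start, s_end, score, cigar, ident


# ---------------------------------------------------------------------------
# seed -> segments -> chains -> HSPs


def _cluster_segments(
    segs: list[tuple[int, int, int, int, int, int]],
    max_gap: int = 50,
    max_shift: int = 50,
) -> list[list[int]]:
    """Group ungapped segments into chains of nearby, collinear segments.

    Segments are (qs, qe, ss, se, score, nmatch).  Two segments chain when
    both coordinates advance with gaps <= max_gap and the diagonal shift is
    between 1 and max_shift.  Transitive closure, greedy over query order.
    """
    order = sorted(range(len(segs)), key=lambda i: (segs[i][0], segs[i][2]))
    chains: list[list[int]] = []
    for i in order:
        qs, qe, ss, se, _, _ = segs[i]
        placed = False
        for chain in chains:
            lqs, lqe, lss, lse, _, _ = segs[chain[-1]]
            qgap = qs - lqe
            sgap = ss - lse
            shift = abs((ss - qs) - (lss - lqs))
            if (
                -10 <= qgap <= max_gap
                and -10 <= sgap <= max_gap
                and 1 <= shift <= max_shift
                and qe > lqe
                and se > lse
            ):
                chain.append(i)
                placed = True
                break
        if not placed:
            chains.append([i])
    return chains


def _resolve_overlaps(hsps: list[HSP]) -> list[HSP]:
    """Keep only the best HSP among those overlapping on the same diagonal."""
    kept: list[HSP] = []
    for h in sorted(
        hsps, key=lambda x: (-x.raw_score, x.query_start, x.subject_start)
    ):
        clash = False
        for g in kept:
            if g.subject_id != h.subject_id or g.strand != h.strand:
                continue
            dq = h.query_end - h.query_start
            # same-diagonal overlap: query and subject intervals both overlap
            if (
                h.query_start < g.query_end
                and g.query_start < h.query_end
                and h.subject_start < g.subject_end
                and g.subject_start < h.subject_end
            ):
                clash = True
                break
        if not clash:
            kept.append(h)
    return kept


def find_hsps(
    query: str,
    index: KmerIndex,
    scheme: ScoringScheme,
    query_id: str = "query",
    min_raw_score: int | None = None,
) -> list[HSP]:
    """All HSPs of ``query`` against the indexed subject, both strands.

    Exact k-mer seeds are grouped per diagonal, extended into maximal
    ungapped segments, chained across nearby diagonals, and chained regions
    are realigned with a banded affine Smith–Waterman.  The result is sorted
    by bit score (descending), ties broken by (query_start, subject_start).
    """
    if not query:
        raise ValueError("query must be non-empty")
    if min_raw_score is None:
        min_raw_score = scheme.kmer_size * scheme.match_reward
    results: list[HSP] = []
    qlen = len(query)
    for strand in "+-":
        qseq = query if strand == "+" else reverse_complement(query)
        qarr = encode(qseq)
        qpos, spos = index.lookup(qarr)
        if len(qpos) == 0:
            continue
        diags = spos - qpos
        order = np.lexsort((qpos, diags))
        diags, qpos = diags[order], qpos[order]
        uniq, first = np.unique(diags, return_index=True)
        bounds = np.append(first, len(diags))
        segs: list[tuple[int, int, int, int, int, int]] = []
        for di in range(len(uniq)):
            d = int(uniq[di])
            hits = qpos[bounds[di] : bounds[di + 1]]
            # windows: merged seed clusters with margin, clamped to overlap
            q_lo = max(0, -d)
            q_hi = min(len(qarr), len(index.arr) - d)
            if q_hi <= q_lo:
                continue
            windows: list[tuple[int, int]] = []
            margin = 500
            for h in hits:
                a = max(q_lo, int(h) - margin)
                b = min(q_hi, int(h) + index.k + margin)
                if windows and a <= windows[-1][1]:
                    windows[-1] = (windows[-1][0], max(windows[-1][1], b))
                else:
                    windows.append((a, b))
            for a, b in windows:
                qa = qarr[a:b]
                sa = index.arr[a + d : b + d]
                match = (qa == sa) & (qa < 4)
                for s0, s1, score, nmatch in _diagonal_segments(match, scheme):
                    if score < min_raw_score:
                        continue
                    segs.append(
                        (a + s0, a + s1, a + s0 + d, a + s1 + d, score, nmatch)
                    )
        if not segs:
            continue
        chains = _cluster_segments(segs)
        candidates: list[tuple[int, int, int, int, int, int, list]] = []
        for chain in chains:
            members = [segs[i] for i in chain]
            for qs, qe, ss, se, score, nmatch in members:
                cigar = [("M", qe - qs)]
                candidates.append((qs, qe, ss, se, score, nmatch, cigar))
            if len(members) > 1:
                qa_ = min(m[0] for m in members)
                qb_ = max(m[1] for m in members)
                dvals = [m[2] - m[0] for m in members]
                dmin, dmax = min(dvals) - 8, max(dvals) + 8
                if (qb_ - qa_ + 1) * (dmax - dmin + 1) > 2_000_000:
                    continue  # keep the ungapped members; DP window too large
                qwin = qarr[qa_:qb_]
                res = _banded_sw(
                    qwin,
                    index.arr,  # full subject; band confines columns
                    dmin + qa_,
                    dmax + qa_,
                    scheme,
                )
                if res is not None:
                    wqs, wqe, wss, wse, score, cigar, ident = res
                    candidates.append(
                        (qa_ + wqs, qa_ + wqe, wss, wse, score, ident, cigar)
                    )
        for qs, qe, ss, se, score, nmatch, cigar in candidates:
            if score < min_raw_score:
                continue
            try:
                contig, c_ss, c_se = index.to_contig(ss, se)
            except ValueError:
                continue  # spans a spacer: drop (cannot happen for real HSPs)
            if strand == "+":
                fq_s, fq_e = qs, qe
            else:
                fq_s, fq_e = qlen - qe, qlen - qs
            alen = sum(n for _, n in cigar)
            results.append(
                HSP(
                    query_id=query_id,
                    subject_id=contig,
                    query_start=fq_s,
                    query_end=fq_e,
                    subject_start=c_ss,
                    subject_end=c_se,
                    strand=strand,
                    alignment_length=alen,
                    identities=nmatch,
                    raw_score=score,
                    bit_score=bit_score(score, scheme),
                )
            )
            results[-1].cigar = cigar
    results = _resolve_overlaps(results)
    results.sort(key=lambda h: (-h.bit_score, h.query_start, h.subject_start))
    return results


def read_alignment_tsv(path: str | Path, scheme: ScoringScheme) -> list[HSP]:
    """Ingest outfmt-6-like tabular alignments in place of the internal aligner.

    Expected columns (no header): qid, sid, pident, length, qstart, qend,
    sstart, send, bitscore, rawscore — 1-based inclusive coordinates,
    converted on read to 0-based half-open; sstart > send marks a minus-strand
    match.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            qid, sid, pident, length, qs, qe, ss, se, bits, raw = line.split(
                "\t"
            )[:10]
            length = int(length)
            ss, se = int(ss), int(se)
            strand = "+" if se >= ss else "-"
            if strand == "-":
                ss, se = se, ss
            ident = round(float(pident) * length / 100.0)
            hsps.append(
                HSP(
                    query_id=qid,
                    subject_id=sid,
                    query_start=int(qs) - 1,
                    query_end=int(qe),
                    subject_start=ss - 1,
                    subject_end=se,
                    strand=strand,
                    alignment_length=length,
                    identities=ident,
                    raw_score=int(float(raw)),
                    bit_score=float(bits),
                    cigar=[("M", length)],
                )
            )
    hsps.sort(key=lambda h: (-h.bit_score, h.query_start, h.subject_start))
    return hsps
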