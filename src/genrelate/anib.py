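"""Fragment-based average nucleotide identity (ANIb).

The query genome is cut into consecutive, non-overlapping fragments
(1020 nt by default), each fragment is locally aligned against the subject
genome, and the ANIb value is the arithmetic mean of the identity
percentages of the accepted fragments.  A fragment's best HSP is accepted
when its identity fraction and the fraction of the fragment it covers both
clear the acceptance thresholds (30% identity / 70% alignable by default,
the conventional ANIb filters).

When no fragment is accepted the ANIb value is *undefined* — reported as
missing, never as 0 — so that downstream correlations are not corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import HSP, KmerIndex, ScoringScheme, find_hsps, index_subject
from .seqs import GenomeSequence

__all__ = [
    "ANIbParams",
    "Fragment",
    "ANIbResult",
    "fragment_genome",
    "anib",
    "anib_matrix",
]


@dataclass(frozen=True)
class ANIbParams:
    fragment_length: int = 1020
    min_identity_fraction: float = 0.30
    min_alignable_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        for f in (self.min_identity_fraction, self.min_alignable_fraction):
            if not 0 < f <= 1:
                raise ValueError("acceptance fractions must be in (0, 1]")


@dataclass(frozen=True)
class Fragment:
    """A query-genome window with provenance coordinates (0-based half-open)."""

    contig: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ANIbResult:
    query_id: str
    subject_id: str
    n_fragments: int
    n_accepted: int
    anib_percent: float | None  # None == undefined (no accepted fragment)
    per_fragment: list[tuple[int, float | None, bool]] = field(
        default_factory=list
    )  # (fragment index, identity %, accepted)

    @property
    def defined(self) -> bool:
        return self.anib_percent is not None


def fragment_genome(
    genome: GenomeSequence, fragment_length: int = 1020
) -> list[Fragment]:
    """Consecutive non-overlapping windows per contig; remainders discarded."""
    if genome.length == 0:
        raise ValueError("genome is empty")
    frags: list[Fragment] = []
    for name, seq in genome.iter_contigs():
        for start in range(0, len(seq) - fragment_length + 1, fragment_length):
            frags.append(
                Fragment(name, start, start + fragment_length,
                         seq[start : start + fragment_length])
            )
    return frags


def _best_hsp(hsps: list[HSP]) -> HSP | None:
    """Highest bit score; ties broken by lowest subject_start (determinism)."""
    if not hsps:
        return None
    return min(hsps, key=lambda h: (-h.bit_score, h.subject_start, h.query_start))


def anib(
    query: GenomeSequence,
    subject: GenomeSequence,
    params: ANIbParams = ANIbParams(),
    scheme: ScoringScheme = ScoringScheme(),
    subject_index: KmerIndex | None = None,
) -> ANIbResult:
    """Directional ANIb: the query is fragmented, the subject is searched."""
    frags = fragment_genome(query, params.fragment_length)
    if not frags:
        raise ValueError(
            f"no fragment of length {params.fragment_length} fits in "
            f"query {query.id!r}"
        )
    index = subject_index or index_subject(subject, scheme.kmer_size)
    per_fragment: list[tuple[int, float | None, bool]] = []
    accepted: list[float] = []
    for i, frag in enumerate(frags):
        best = _best_hsp(
            find_hsps(frag.sequence, index, scheme, query_id=frag.contig)
        )
        if best is None:
            per_fragment.append((i, None, False))
            continue
        ident_pct = 100.0 * best.identity_fraction
        coverage = (best.query_end - best.query_start) / frag.length
        ok = (
            best.identity_fraction >= params.min_identity_fraction
            and coverage >= params.min_alignable_fraction
        )
        per_fragment.append((i, ident_pct, ok))
        if ok:
            accepted.append(ident_pct)
    anib_percent = sum(accepted) / len(accepted) if accepted else None
    return ANIbResult(
        query_id=query.id,
        subject_id=subject.id,
        n_fragments=len(frags),
        n_accepted=len(accepted),
        anib_percent=anib_percent,
        per_fragment=per_fragment,
    )


def anib_matrix(
    genomes: list[GenomeSequence],
    params: ANIbParams = ANIbParams(),
    scheme: ScoringScheme = ScoringScheme(),
) -> pd.DataFrame:
    """All ordered pairs (ANIb is directional: row = query, column = subject).

    Diagonal entries are self-comparisons (100.0 by construction); undefined
    ANIb values appear as NaN.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in genomes]
    indexes = {g.id: index_subject(g, scheme.kmer_size) for g in genomes}
    table = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for q in genomes:
        for s in genomes:
            res = anib(q, s, params, scheme, subject_index=indexes[s.id])
            table.loc[q.id, s.id] = (
                res.anib_percent if res.defined else float("nan")
            )
    table.index.name = "query"
    table.columns.name = "subject"
    return table
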