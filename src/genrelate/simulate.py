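"""Synthetic genomes, gene families and mortality tables.

The generator produces data with the statistical structure the downstream
analyses assume, so every stage can be exercised without downloads:

* pairs of genomes at a controlled nucleotide divergence with an optional
  indel and rearrangement load,
* categorised gene families (exoenzyme / toxin / NRPS / PKS) whose
  cross-genome conservation decays with the taxonomic-relatedness degree,
* replicated binomial mortality counts per dose group.

Randomness: every operation draws from its own ``numpy`` generator, seeded
deterministically from the spec seed via
``np.random.SeedSequence(seed, spawn_key=(stream,))`` — so each stage is
independently reproducible and identical spec+seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bsr import CATEGORIES, GeneRecord
from .seqs import GenomeSequence, reverse_complement, write_fasta

__all__ = [
    "EvolutionParams",
    "GeneFamilySimSpec",
    "MortalitySimSpec",
    "generate_ancestor",
    "evolve_genome",
    "simulate_gene_families",
    "GeneFamilySimResult",
    "simulate_mortality",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stream indices for SeedSequence spawn keys
_S_ANCESTOR = 0
_S_SUBST = 1
_S_INDEL = 2
_S_REARR = 3
_S_RETAIN = 4
_S_DIVERGE = 5
_S_ASSEMBLE = 6
_S_MORTALITY = 7


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    )


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome evolution


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the genome evolution model.

    substitution_rate: fraction of sites substituted (per-site Bernoulli).
    indel_rate: expected indel events per kb (Poisson).
    indel_length_mean: mean of the geometric indel length, capped at 50 nt.
    rearrangement_count: number of segment moves; each is a translocation,
        or (with probability ``inversion_fraction``) an inversion, i.e. a
        reverse-complemented reinsertion.  The default keeps inversions off
        so that rearrangement-only evolution conserves the residue multiset.
    """

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_length_mean: float = 3.0
    rearrangement_count: int = 0
    inversion_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.indel_rate < 0 or self.indel_length_mean <= 0:
            raise ValueError("indel parameters must be non-negative")
        if self.rearrangement_count < 0:
            raise ValueError("rearrangement_count must be >= 0")
        if not 0 <= self.inversion_fraction <= 1:
            raise ValueError("inversion_fraction must be in [0, 1]")


def generate_ancestor(
    length: int, gc_content: float = 0.5, seed: int = 0, id: str = "ancestor"
) -> GenomeSequence:
    """A random single-contig genome with the requested expected GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = _rng(seed, _S_ANCESTOR)
    return GenomeSequence.from_string(id, _random_seq(rng, length, gc_content))


def _substitute(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Per-site substitution, uniform over the three alternative bases."""
    if rate == 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(len(arr), 4, np.uint8)
    for i, b in enumerate(_BASES):
        code[arr == b] = i
    mask = (rng.random(len(arr)) < rate) & (code < 4)
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        code[mask] = (code[mask] + shift) % 4
        arr[mask] = _BASES[code[mask]]
    return arr.tobytes().decode("ascii"), n


def _apply_indels(
    seq: str, params: EvolutionParams, rng: np.random.Generator
) -> str:
    n_events = int(rng.poisson(params.indel_rate * len(seq) / 1000.0))
    if n_events == 0:
        return seq
    if n_events > len(seq):
        raise ValueError("indel_rate implies more events than sites")
    s = seq
    positions = sorted(
        (int(p) for p in rng.integers(0, len(seq), size=n_events)),
        reverse=True,
    )
    for pos in positions:
        length = min(50, int(rng.geometric(1.0 / params.indel_length_mean)))
        if rng.random() < 0.5:  # insertion
            s = s[:pos] + _random_seq(rng, length) + s[pos:]
        else:  # deletion
            s = s[:pos] + s[pos + length :]
    return s


def _apply_rearrangements(
    seq: str, params: EvolutionParams, rng: np.random.Generator
) -> str:
    s = seq
    for _ in range(params.rearrangement_count):
        if len(s) < 200:
            break
        seg_len = int(rng.integers(100, max(201, len(s) // 20)))
        seg_len = min(seg_len, len(s) - 1)
        start = int(rng.integers(0, len(s) - seg_len))
        segment = s[start : start + seg_len]
        rest = s[:start] + s[start + seg_len :]
        if rng.random() < params.inversion_fraction:
            segment = reverse_complement(segment)
        insert_at = int(rng.integers(0, len(rest) + 1))
        s = rest[:insert_at] + segment + rest[insert_at:]
    return s


def evolve_genome(
    ancestor: GenomeSequence, params: EvolutionParams
) -> tuple[GenomeSequence, float]:
    """Mutated copy of a genome plus the realised substitution fraction.

    Event order is fixed and documented: substitutions, then indels, then
    rearrangements.  The realised divergence is the fraction of ungapped
    (pre-indel) sites whose base was substituted; substitutions never
    rewrite the original base.
    """
    if ancestor.length == 0:
        raise ValueError("ancestor is empty")
    rng_sub = _rng(params.seed, _S_SUBST)
    rng_indel = _rng(params.seed, _S_INDEL)
    rng_rearr = _rng(params.seed, _S_REARR)
    contigs: dict[str, str] = {}
    n_sub_total = 0
    for name, seq in ancestor.iter_contigs():
        s, n_sub = _substitute(seq, params.substitution_rate, rng_sub)
        n_sub_total += n_sub
        s = _apply_indels(s, params, rng_indel)
        s = _apply_rearrangements(s, params, rng_rearr)
        contigs[name] = s
    evolved = GenomeSequence(id=f"{ancestor.id}_evolved", contigs=contigs)
    return evolved, n_sub_total / ancestor.length


# ---------------------------------------------------------------------------
# gene families


@dataclass(frozen=True)
class GeneFamilySimSpec:
    """Categorised gene families whose conservation decays with degree.

    Default gene counts are a desk-scale version of a fungal
    insecticidal-factor repertoire (exoenzymes dominating, then toxins,
    NRPS, PKS); default retention probabilities and divergences follow the
    empirical decay of homolog percentages across relatedness degrees 1-5.
    """

    n_genes_per_category: dict = field(
        default_factory=lambda: {
            "exoenzyme": 24, "toxin": 15, "NRPS": 12, "PKS": 10,
        }
    )
    retention_prob_by_degree: dict = field(
        default_factory=lambda: {1: 0.95, 2: 0.85, 3: 0.50, 4: 0.20, 5: 0.15}
    )
    divergence_by_degree: dict = field(
        default_factory=lambda: {1: 0.04, 2: 0.12, 3: 0.20, 4: 0.30, 5: 0.40}
    )
    gene_length: int = 1000
    spacer_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_genes_per_category:
            raise ValueError("empty category list")
        for cat in self.n_genes_per_category:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
        probs = [
            self.retention_prob_by_degree[d]
            for d in sorted(self.retention_prob_by_degree)
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("retention probabilities must be in [0, 1]")
        if any(b > a for a, b in zip(probs, probs[1:])):
            raise ValueError("retention_prob must be non-increasing in degree")
        for d, rate in self.divergence_by_degree.items():
            if not 0 <= rate < 1:
                raise ValueError(f"divergence for degree {d} out of [0, 1)")


@dataclass
class GeneFamilySimResult:
    genes: list[GeneRecord]
    categories: dict  # gene_id -> category
    reference: GenomeSequence
    genomes: dict  # genome_id -> GenomeSequence (excludes the reference)
    truth: pd.DataFrame  # columns gene_id, genome_id, present

    def write(self, outdir: str | Path) -> dict:
        """Write gene FASTA, per-genome FASTA, category TSV and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        gene_path = outdir / "genes.fasta"
        write_fasta(((g.gene_id, g.sequence) for g in self.genes), gene_path)
        paths["genes"] = gene_path
        cat_path = outdir / "categories.tsv"
        pd.DataFrame(
            {"gene_id": list(self.categories),
             "category": list(self.categories.values())}
        ).to_csv(cat_path, sep="\t", index=False)
        paths["categories"] = cat_path
        ref_path = outdir / f"{self.reference.id}.fasta"
        write_fasta(self.reference, ref_path)
        paths[self.reference.id] = ref_path
        for gid, genome in self.genomes.items():
            p = outdir / f"{gid}.fasta"
            write_fasta(genome, p)
            paths[gid] = p
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        return paths


def simulate_gene_families(
    spec: GeneFamilySimSpec, genomes_by_degree: dict
) -> GeneFamilySimResult:
    """Reference gene set plus homolog-bearing genomes per degree.

    ``genomes_by_degree`` maps degree (1-5) to a list of genome identifiers.
    Every genome retains each reference gene with the degree's retention
    probability; retained homologs are substitution-mutated at the degree's
    divergence.  Genomes are assembled by joining sequences with random
    spacers; the truth table records ground-truth presence for validating
    homology calls.
    """
    for degree, ids in genomes_by_degree.items():
        if degree not in spec.retention_prob_by_degree:
            raise ValueError(f"no retention probability for degree {degree}")
        if not ids:
            raise ValueError(f"degree {degree} has no genomes")
    rng_retain = _rng(spec.seed, _S_RETAIN)
    rng_div = _rng(spec.seed, _S_DIVERGE)
    rng_asm = _rng(spec.seed, _S_ASSEMBLE)

    genes: list[GeneRecord] = []
    for cat in CATEGORIES:
        for i in range(spec.n_genes_per_category.get(cat, 0)):
            genes.append(
                GeneRecord(
                    gene_id=f"{cat}_{i + 1:03d}",
                    category=cat,
                    sequence=_random_seq(rng_asm, spec.gene_length),
                )
            )
    categories = {g.gene_id: g.category for g in genes}

    def assemble(parts: list[str]) -> str:
        chunks = [_random_seq(rng_asm, spec.spacer_length)]
        for p in parts:
            chunks.append(p)
            chunks.append(_random_seq(rng_asm, spec.spacer_length))
        return "".join(chunks)

    reference = GenomeSequence.from_string(
        "reference", assemble([g.sequence for g in genes])
    )
    genomes: dict[str, GenomeSequence] = {}
    rows = []
    for degree in sorted(genomes_by_degree):
        p_keep = spec.retention_prob_by_degree[degree]
        div = spec.divergence_by_degree.get(degree, 0.0)
        for gid in genomes_by_degree[degree]:
            parts = []
            for g in genes:
                present = bool(rng_retain.random() < p_keep)
                rows.append(
                    {"gene_id": g.gene_id, "genome_id": gid,
                     "degree": degree, "present": present}
                )
                if present:
                    hom, _ = _substitute(g.sequence, div, rng_div)
                    parts.append(hom)
            genomes[gid] = GenomeSequence.from_string(gid, assemble(parts))
    truth = pd.DataFrame(rows, columns=["gene_id", "genome_id", "degree",
                                        "present"])
    return GeneFamilySimResult(
        genes=genes,
        categories=categories,
        reference=reference,
        genomes=genomes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# mortality


@dataclass(frozen=True)
class MortalitySimSpec:
    """Replicated binomial mortality counts per dose group.

    Defaults mirror a five-dose injection bioassay plus a buffer control:
    doses in ug per larva, ten larvae per replicate, twelve replicates
    (three technical replicates in each of four independent experiments),
    scored at 21 days.
    """

    doses: tuple = (0.0, 0.70, 1.75, 3.50, 5.25, 7.00)
    true_mortality_by_dose: dict = field(
        default_factory=lambda: {
            0.0: 0.01, 0.70: 0.43, 1.75: 0.38,
            3.50: 0.50, 5.25: 0.64, 7.00: 0.64,
        }
    )
    n_larvae_per_replicate: int = 10
    n_replicates: int = 12
    timepoint: float = 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_larvae_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        for dose in self.doses:
            p = self.true_mortality_by_dose.get(dose)
            if p is None:
                raise ValueError(f"no true mortality for dose {dose}")
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def simulate_mortality(spec: MortalitySimSpec) -> pd.DataFrame:
    """Dose x replicate table of binomial dead counts (reproducible per seed).

    Replicates are labelled with an experiment block (three replicates per
    experiment) that downstream analysis keeps but does not model.
    """
    rng = _rng(spec.seed, _S_MORTALITY)
    rows = []
    for dose in spec.doses:
        p = spec.true_mortality_by_dose[dose]
        for rep in range(spec.n_replicates):
            dead = int(rng.binomial(spec.n_larvae_per_replicate, p))
            rows.append(
                {
                    "dose": dose,
                    "experiment": rep // 3 + 1,
                    "replicate": rep % 3 + 1,
                    "n_larvae": spec.n_larvae_per_replicate,
                    "dead": dead,
                    "timepoint": spec.timepoint,
                }
            )
    return pd.DataFrame(rows)
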