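"""Pipeline orchestration: configuration, staged execution, run report.

Two run modes:

* ``full`` — start from genome/gene FASTA files: ANIb matrix, dDDH, BSR
  homology matrix and per-category percentages, degree encoding, then the
  regression/correlation stage.
* ``stats-only`` — ingest a precomputed relatedness table (such as the
  packaged reference table) and run only the regression/correlation stage;
  the headline statistics are reproducible this way without any genome
  download.

Configuration is a flat ``key = value`` text file; all outputs are TSV with
``#``-prefixed metadata lines, coordinates 0-based half-open.  A JSON run
report lists every table written, the configuration echo and input
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import ScoringScheme
from .anib import ANIbParams, anib_matrix
from .bsr import homology_matrix, percent_homologous, read_categories
from .ddh import DDHParams, ddh
from .relatedness import (
    RGM2184,
    TaxonomyRecord,
    correlation_matrix,
    encode_degree,
    linear_regression,
    read_relatedness_table,
)
from .seqs import GenomeSequence, read_fasta, read_fasta_records

__all__ = ["PipelineConfig", "RunReport", "run_relatedness", "load_config"]

logger = logging.getLogger("genrelate")

_HEADER = "# coordinates: 0-based, half-open\n"


@dataclass
class PipelineConfig:
    mode: str = "full"  # "full" | "stats-only"
    reference_genome: str | None = None
    genomes: list = field(default_factory=list)  # comparison genome FASTAs
    genes: str | None = None  # gene FASTA (reference strain)
    categories: str | None = None  # gene_id -> category TSV
    taxonomy: str | None = None  # strain taxonomy TSV
    relatedness_table: str | None = None  # stats-only input
    output_dir: str = "genrelate_out"
    seed: int = 0
    log_level: str = "INFO"
    anib_params: ANIbParams = field(default_factory=ANIbParams)
    ddh_params: DDHParams = field(default_factory=DDHParams)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def validate(self) -> None:
        if self.mode not in ("full", "stats-only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        needed: list[str] = []
        if self.mode == "full":
            needed = [self.reference_genome, self.genes, self.categories,
                      self.taxonomy, *self.genomes]
        else:
            needed = [self.relatedness_table]
        for p in needed:
            if p is None:
                raise ValueError("missing input path in configuration")
            if not Path(p).exists():
                raise FileNotFoundError(p)


_SCHEME_KEYS = {
    "match_reward": int, "mismatch_penalty": int, "gap_open": int,
    "gap_extend": int, "lam": float, "k": float, "kmer_size": int,
    "x_drop": int,
}
_ANIB_KEYS = {
    "fragment_length": int, "min_identity_fraction": float,
    "min_alignable_fraction": float,
}
_DDH_KEYS = {
    "glm_intercept": float, "glm_slope": float, "min_hsp_bits": float,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file.

    ``genomes`` takes a comma-separated list; scoring/ANIb/dDDH parameters
    use their field names (e.g. ``fragment_length = 1020``).
    """
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    cfg = PipelineConfig()
    scheme_kw, anib_kw, ddh_kw = {}, {}, {}
    for key, value in kv.items():
        if key in _SCHEME_KEYS:
            scheme_kw[key] = _SCHEME_KEYS[key](value)
        elif key in _ANIB_KEYS:
            anib_kw[key] = _ANIB_KEYS[key](value)
        elif key in _DDH_KEYS:
            ddh_kw[key] = _DDH_KEYS[key](value)
        elif key == "genomes":
            cfg.genomes = [v.strip() for v in value.split(",") if v.strip()]
        elif key == "seed":
            cfg.seed = int(value)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    if scheme_kw:
        cfg.scheme = ScoringScheme(**scheme_kw)
    if anib_kw:
        cfg.anib_params = ANIbParams(**anib_kw)
    if ddh_kw:
        cfg.ddh_params = DDHParams(**ddh_kw)
    return cfg


@dataclass
class RunReport:
    version: str
    config: dict
    tables: dict = field(default_factory=dict)  # stage -> output path
    checksums: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> "ok" | reason

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=index)


def _read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for _, row in df.iterrows():
        rec = TaxonomyRecord(
            strain_id=row["strain"], species=row["species"],
            genus=row["genus"], family=row["family"], order=row["order"],
            subphylum=row["subphylum"],
        )
        out[rec.strain_id] = rec
    return out


def _stats_stage(
    table: pd.DataFrame, outdir: Path, report: RunReport
) -> None:
    """Regression of ANIb/dDDH on degree plus the 6x6 correlation matrix."""
    fits = {}
    for var in ("anib", "ddh"):
        sub = table.dropna(subset=["degree", var])
        fit = linear_regression(sub["degree"], sub[var])
        fits[var] = fit
        logger.info(
            "%s ~ degree: slope %.3f r %.3f R^2 %.1f%%",
            var, fit.slope, fit.r, fit.r_squared,
        )
    reg = pd.DataFrame(
        {
            "variable": list(fits),
            "slope": [f.slope for f in fits.values()],
            "intercept": [f.intercept for f in fits.values()],
            "r": [f.r for f in fits.values()],
            "r_squared_pct": [f.r_squared for f in fits.values()],
            "residual_sd": [f.residual_sd for f in fits.values()],
            "n": [f.n for f in fits.values()],
        }
    )
    reg_path = outdir / "regression.tsv"
    _write_tsv(reg, reg_path, index=False)
    report.tables["regression"] = str(reg_path)
    corr = correlation_matrix(table)
    corr_path = outdir / "correlation_matrix.tsv"
    _write_tsv(corr, corr_path)
    report.tables["correlation_matrix"] = str(corr_path)
    table_path = outdir / "relatedness_table.tsv"
    _write_tsv(table, table_path, index=False)
    report.tables["relatedness_table"] = str(table_path)
    report.stages["stats"] = "ok"


def run_relatedness(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; deterministic given the seed.

    Partial failures are recorded per stage and downstream stages that
    depend on the failed output are skipped with an explanation; validation
    failures abort before any stage runs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, config.log_level.upper())
    )
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    report = RunReport(
        version=__version__,
        config={k: str(v) for k, v in config.__dict__.items()},
    )
    try:
        if config.mode == "stats-only":
            for p in [config.relatedness_table]:
                report.checksums[str(p)] = _sha256(p)
            table = read_relatedness_table(
                config.relatedness_table, reference=RGM2184
            )
            _stats_stage(table, outdir, report)
            report.save(outdir / "report.json")
            return report

        for p in [config.reference_genome, config.genes, config.categories,
                  config.taxonomy, *config.genomes]:
            report.checksums[str(p)] = _sha256(p)
        reference = read_fasta(config.reference_genome)
        others = [read_fasta(p) for p in config.genomes]
        taxonomy = _read_taxonomy(config.taxonomy)
        ref_tax = taxonomy[reference.id]

        # ANIb (query = comparison strain, subject = reference)
        mat = anib_matrix([reference, *others], config.anib_params,
                          config.scheme)
        anib_path = outdir / "anib_matrix.tsv"
        _write_tsv(mat, anib_path)
        report.tables["anib_matrix"] = str(anib_path)
        report.stages["anib"] = "ok"

        # dDDH
        ddh_rows = []
        for g in others:
            res = ddh(g, reference, config.scheme, config.ddh_params)
            ddh_rows.append(
                {"a": res.genome_a, "b": res.genome_b,
                 "distance": res.distance, "ddh_percent": res.ddh_percent,
                 "ge70_flag": res.ge70}
            )
        ddh_df = pd.DataFrame(ddh_rows)
        ddh_path = outdir / "ddh.tsv"
        _write_tsv(ddh_df, ddh_path, index=False)
        report.tables["ddh"] = str(ddh_path)
        report.stages["ddh"] = "ok"

        # BSR
        records = read_fasta_records(config.genes)
        categories = read_categories(config.categories)
        from .bsr import GeneRecord

        genes = [
            GeneRecord(gene_id=gid, category=categories[gid], sequence=seq)
            for gid, seq in records
        ]
        bsr_mat = homology_matrix(
            genes, [reference, *others], config.scheme,
            source_genome=reference,
        )
        bsr_path = outdir / "bsr_matrix.tsv"
        _write_tsv(bsr_mat, bsr_path)
        report.tables["bsr_matrix"] = str(bsr_path)
        summaries = percent_homologous(bsr_mat, categories)
        summ_df = pd.DataFrame(
            [
                {"genome": s.genome_id, "category": s.category,
                 "n_genes": s.n_genes, "n_homologs": s.n_homologs,
                 "percent": s.percent}
                for s in summaries
            ]
        )
        summ_path = outdir / "homology_summary.tsv"
        _write_tsv(summ_df, summ_path, index=False)
        report.tables["homology_summary"] = str(summ_path)
        report.stages["bsr"] = "ok"

        # relatedness table: ANIb toward the reference, dDDH, category %
        rows = []
        pct = {
            (s.genome_id, s.category): s.percent for s in summaries
        }
        ddh_by_id = {r["a"]: r for r in ddh_rows}
        for g in others:
            rows.append(
                {
                    "strain": g.id,
                    "degree": encode_degree(ref_tax, taxonomy[g.id]),
                    "anib": mat.loc[g.id, reference.id],
                    "ddh": ddh_by_id[g.id]["ddh_percent"],
                    "exo_pct": pct.get((g.id, "exoenzyme"), np.nan),
                    "toxin_pct": pct.get((g.id, "toxin"), np.nan),
                    "nrps_pct": pct.get((g.id, "NRPS"), np.nan),
                    "pks_pct": pct.get((g.id, "PKS"), np.nan),
                }
            )
        table = pd.DataFrame(rows)
        if len(table) >= 3:
            _stats_stage(table, outdir, report)
        else:
            table_path = outdir / "relatedness_table.tsv"
            _write_tsv(table, table_path, index=False)
            report.tables["relatedness_table"] = str(table_path)
            report.stages["stats"] = (
                "skipped: fewer than 3 comparison strains"
            )
        report.save(outdir / "report.json")
        return report
    finally:
        logger.removeHandler(fh)
        fh.close()
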