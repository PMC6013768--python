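"""Shared file I/O, schema validation, and the pipeline driver.

All tabular formats are tab-separated with a required header line.
Panel coordinates are 1-based (VCF convention). FASTQ may be plain or
gzip-compressed. Every reader validates its schema and reports the
offending line or column; every writer round-trips losslessly through
its reader.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, PassportSeqError, SchemaError
from .panel_design import MirSNP
from .readproc import BarcodePair, SampleRow, SampleSheet, SequencedRead

logger = logging.getLogger("passportseq")

PANEL_COLUMNS = ["snp_id", "ref", "alt", "flank5", "flank3"]
PANEL_OPTIONAL = ["gene", "source", "contig", "position"]
SHEET_COLUMNS = ["sample_id", "role", "cell_line", "replicate", "run", "fwd_barcode", "rev_barcode"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------- panels
def read_panel(path) -> list[MirSNP]:
    """Read a tab-separated variant panel into MirSNP records."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, PANEL_COLUMNS, path)
    snps = []
    for i, row in df.iterrows():
        try:
            snps.append(
                MirSNP(
                    snp_id=row["snp_id"],
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    flank5=row["flank5"],
                    flank3=row["flank3"],
                    gene=row.get("gene") or None,
                    source=row.get("source") or None,
                    contig=row.get("contig", "") or "",
                    position=int(row["position"]) if row.get("position") else 0,
                )
            )
        except PassportSeqError as exc:
            raise SchemaError(f"{path} line {i + 2}: {exc}") from exc
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise SchemaError(f"{path}: duplicate snp_id(s) {dup}")
    return snps


def write_panel(path, snps: Iterable[MirSNP]) -> None:
    rows = [
        {
            "snp_id": s.snp_id,
            "ref": s.ref_allele,
            "alt": s.alt_allele,
            "flank5": s.flank5,
            "flank3": s.flank3,
            "gene": s.gene or "",
            "source": s.source or "",
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def panel_from_vcf(vcf_path, genome_fasta, flank5_len: int = 22, flank3_len: int = 9) -> list[MirSNP]:
    """Build a panel from SNV records of a VCF plus a genome FASTA.

    Flanks are extracted on the plus strand around the 1-based VCF
    position; non-SNV records are skipped with a log message.
    """
    import pysam
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    snps = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or len(alts) != 1 or len(alts[0]) != 1:
                logger.info("skipping non-SNV record %s", rec.id or rec.pos)
                continue
            contig = rec.contig
            pos = rec.pos  # 1-based
            genome_base = str(genome[contig][pos - 1 : pos]).upper()
            if genome_base != rec.ref:
                raise SchemaError(
                    f"{vcf_path}: {rec.id or pos} REF {rec.ref!r} does not match "
                    f"genome base {genome_base!r} at {contig}:{pos}"
                )
            flank5 = str(genome[contig][pos - 1 - flank5_len : pos - 1])
            flank3 = str(genome[contig][pos : pos + flank3_len])
            snps.append(
                MirSNP(
                    snp_id=rec.id or f"{contig}:{pos}",
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    flank5=flank5,
                    flank3=flank3,
                    contig=contig,
                    position=pos,
                )
            )
    return snps


# ----------------------------------------------------------- FASTA/FASTQ
def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA as (id, sequence) pairs; duplicate ids are an error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_mirna_fasta(path):
    """Mature miRNA FASTA (U or T accepted) into MiRNA records."""
    from .seed_scan import MiRNA

    return [MiRNA(name=name, sequence=seq) for name, seq in read_fasta(path)]


def read_fastq(path) -> Iterator[SequencedRead]:
    """Stream a plain or gzipped FASTQ."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield SequencedRead(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                qualities="".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                ),
            )


def write_fastq(path, reads: Iterable[SequencedRead]) -> int:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as handle:
        for read in reads:
            quals = read.qualities or "I" * len(read.bases)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{quals}\n")
            n += 1
    return n


# ---------------------------------------------------------- sample sheet
def read_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, SHEET_COLUMNS, path)
    rows = []
    for i, row in df.iterrows():
        try:
            rows.append(
                SampleRow(
                    sample_id=row["sample_id"],
                    role=row["role"],
                    cell_line=row["cell_line"] or "-",
                    replicate=int(row["replicate"]),
                    run=row["run"],
                    barcode=BarcodePair(row["fwd_barcode"], row["rev_barcode"]),
                )
            )
        except (PassportSeqError, ValueError) as exc:
            raise SchemaError(f"{path} line {i + 2}: {exc}") from exc
    try:
        return SampleSheet(rows)
    except PassportSeqError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_sample_sheet(path, sheet: SampleSheet) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "role": r.role,
            "cell_line": r.cell_line,
            "replicate": r.replicate,
            "run": r.run,
            "fwd_barcode": r.barcode.fwd,
            "rev_barcode": r.barcode.rev,
        }
        for r in sheet
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- counts, results
def read_counts(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise SchemaError(f"{path}: empty count matrix")
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative counts")
    return df


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="fragment_id")


def write_results(path, results: pd.DataFrame) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -------------------------------------------------------------- pipeline
@dataclass
class PipelineConfig:
    out_dir: Path
    panel: Path | None = None
    mirnas: Path | None = None
    fastq: Path | None = None
    sample_sheet: Path | None = None
    counts: Path | None = None
    stages: tuple[str, ...] = ("design", "scan", "demux", "test")
    mode: str = "divide"
    fdr_threshold: float = 0.05
    bh_pool: str = "all"
    max_edits: int = 2
    flank_width: int = 8
    seed: int = 0

    def validate(self) -> None:
        known = {"design", "scan", "demux", "test"}
        bad = set(self.stages) - known
        if bad:
            raise SchemaError(f"unknown stage(s) {sorted(bad)}")
        needs = {
            "design": [("panel", self.panel)],
            "scan": [("panel", self.panel), ("mirnas", self.mirnas)],
            "demux": [("fastq", self.fastq), ("sample_sheet", self.sample_sheet), ("panel", self.panel)],
        }
        if "test" in self.stages:
            if "demux" not in self.stages:
                needs["test"] = [("counts", self.counts), ("sample_sheet", self.sample_sheet)]
            else:
                needs["test"] = []
        for stage in self.stages:
            for name, path in needs.get(stage, []):
                if path is None:
                    raise SchemaError(f"stage {stage!r} requires --{name.replace('_', '-')}")
                if not Path(path).exists():
                    raise SchemaError(f"stage {stage!r}: {name} file {path} does not exist")


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the provenance record.

    design -> scan -> demux -> test, each writing its outputs under
    ``config.out_dir``; a provenance JSON (package version, seeds,
    parameters, input checksums, stage timings) is written alongside.
    """
    from . import __version__, diffex, panel_design, readproc, seed_scan

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "package": "passportseq",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "mode": config.mode,
            "fdr_threshold": config.fdr_threshold,
            "bh_pool": config.bh_pool,
            "max_edits": config.max_edits,
            "flank_width": config.flank_width,
        },
        "inputs": {},
        "stages": [],
    }
    for name in ("panel", "mirnas", "fastq", "sample_sheet", "counts"):
        path = getattr(config, name)
        if path is not None and Path(path).exists():
            provenance["inputs"][name] = {"path": str(path), "sha256_16": _checksum(path)}

    library = None
    counts = None
    sheet = None
    for stage in config.stages:
        t0 = time.monotonic()
        if stage == "design":
            snps = read_panel(config.panel)
            library = panel_design.design_panel(snps)
            library.to_fasta(out / "library.fa")
            pd.DataFrame(panel_design.design_report(library)).to_csv(
                out / "design_report.tsv", sep="\t", index=False
            )
        elif stage == "scan":
            snps = read_panel(config.panel)
            mirnas = read_mirna_fasta(config.mirnas)
            table = seed_scan.scan_panel(snps, mirnas, flank_width=config.flank_width)
            table.to_csv(out / "classifications.tsv", sep="\t", index=False)
        elif stage == "demux":
            if library is None:
                library = panel_design.design_panel(read_panel(config.panel))
            sheet = read_sample_sheet(config.sample_sheet)
            counts, summary = readproc.process_reads(
                read_fastq(config.fastq), library, sheet, max_edits=config.max_edits
            )
            write_counts(out / "counts.tsv", counts)
            summary.to_csv(out / "demux_summary.tsv", sep="\t", index=False)
            qc = readproc.representation_report(counts, sheet)
            qc.per_fragment.to_csv(out / "qc_representation.tsv", sep="\t", index=False)
        elif stage == "test":
            if counts is None:
                counts = read_counts(config.counts)
                sheet = read_sample_sheet(config.sample_sheet)
            results = diffex.run_experiment(
                counts,
                sheet,
                mode=config.mode,
                fdr_threshold=config.fdr_threshold,
                bh_pool=config.bh_pool,
            )
            write_results(out / "results.tsv", results)
            summary = diffex.call_functional(results, config.fdr_threshold)
            venn_rows = [
                {"set": cl, "n_functional": n} for cl, n in summary.per_cell_line.items()
            ]
            venn_rows.append({"set": "union", "n_functional": summary.union})
            for combo, n in summary.intersections.items():
                venn_rows.append({"set": "&".join(combo), "n_functional": n})
            pd.DataFrame(venn_rows).to_csv(out / "venn_summary.tsv", sep="\t", index=False)
        else:  # pragma: no cover - validated earlier
            raise SchemaError(f"unknown stage {stage!r}")
        provenance["stages"].append(
            {"stage": stage, "seconds": round(time.monotonic() - t0, 3)}
        )
        logger.info("stage %s done in %.2fs", stage, time.monotonic() - t0)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return provenance
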