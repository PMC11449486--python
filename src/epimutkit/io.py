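"""Readers and writers for the standard text formats the toolkit speaks.

FASTA (genomes), BED3/BED6+ (tracks, site sets, DMC/DMR output), TSV
matrices (beta values, methylation counts, gene counts, DEG tables) and
JSON (configs, truth sets, reports).  Coordinates are 0-based half-open
internally and on disk (BED convention); TSV files are tab-separated
with a header row and '.' for missing values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import MotifHit
from .expression import CountMatrix, DEGRecord
from .intervals import AnnotationTrack
from .methylation import BetaMatrix, DMCRecord, DMRRecord, MethylCountMatrix

__all__ = [
    "GenomeSequence",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_track",
    "read_sites_bed",
    "write_sites_bed",
    "read_design",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_methyl_counts",
    "write_methyl_counts",
    "read_count_matrix",
    "write_count_matrix",
    "write_dmc_bed",
    "read_dmc_bed",
    "write_dmr_bed",
    "write_deg_table",
    "read_deg_table",
    "read_motif_file",
    "write_motif_hits_bed",
    "dump_json",
]


class BedParseError(ValueError):
    pass


@dataclass
class GenomeSequence:
    """Random-access view of a set of named sequences."""

    seqs: dict[str, str]

    def keys(self):
        return self.seqs.keys()

    def __getitem__(self, chrom: str) -> str:
        if chrom not in self.seqs:
            raise KeyError(f"no such chromosome: {chrom!r}")
        return self.seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"fetch {chrom}:{start}-{end} out of bounds (length {len(seq)})")
        return seq[start:end]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


def read_fasta(path: str | Path) -> GenomeSequence:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeSequence(seqs)


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[tuple]:
    """Parse a BED3+ file; malformed lines are reported with line numbers."""
    out: list[tuple] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{ln}: expected >= 3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(f"{path}:{ln}: non-integer coordinates") from None
            if start < 0:
                raise BedParseError(f"{path}:{ln}: negative start")
            if start >= end:
                raise BedParseError(f"{path}:{ln}: start >= end")
            out.append((chrom, start, end, *parts[3:]))
    return out


def write_bed(path: str | Path, records: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_track(path: str | Path, name: str) -> AnnotationTrack:
    return AnnotationTrack.from_records(name, [(c, s, e) for c, s, e, *_ in read_bed(path)])


def read_sites_bed(path: str | Path) -> list[tuple[str, int]]:
    """Point sites from BED (the start coordinate of each interval)."""
    return [(c, s) for c, s, _e, *_ in read_bed(path)]


def write_sites_bed(path: str | Path, sites: Iterable[tuple[str, int]]) -> None:
    write_bed(path, ((c, p, p + 1) for c, p in sites))


def read_design(path: str | Path) -> dict[str, str]:
    """Sample -> arm map from a two-column TSV (header optional)."""
    design: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>arm'")
            if ln == 1 and parts[1] not in ("treated", "control"):
                continue  # header row
            design[parts[0]] = parts[1]
    if not design:
        raise ValueError(f"no design rows in {path}")
    return design


def _split_matrix_frame(df: pd.DataFrame, design: Mapping[str, str]):
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError("matrix TSV must start with 'chrom' and 'pos' columns")
    samples = [c for c in df.columns[2:]]
    arm = [design[s] for s in samples]
    return df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(dtype=np.int64), samples, arm


def read_beta_matrix(path: str | Path, design: Mapping[str, str]) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t")
    chrom, pos, samples, arm = _split_matrix_frame(df, design)
    return BetaMatrix(chrom, pos, samples, arm, df[samples].to_numpy(dtype=float))


def write_beta_matrix(path: str | Path, betas: BetaMatrix) -> None:
    df = pd.DataFrame({"chrom": betas.chrom, "pos": betas.pos})
    for j, s in enumerate(betas.samples):
        df[s] = betas.values[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_methyl_counts(path: str | Path, design: Mapping[str, str]) -> MethylCountMatrix:
    """Count TSV with paired '<sample>.meth' / '<sample>.cov' columns."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError("matrix TSV must start with 'chrom' and 'pos' columns")
    samples = []
    for c in df.columns[2:]:
        if c.endswith(".meth"):
            samples.append(c[: -len(".meth")])
    for s in samples:
        if f"{s}.cov" not in df.columns:
            raise ValueError(f"missing coverage column for sample {s!r}")
    arm = [design[s] for s in samples]
    meth = df[[f"{s}.meth" for s in samples]].to_numpy(dtype=np.int64)
    cov = df[[f"{s}.cov" for s in samples]].to_numpy(dtype=np.int64)
    return MethylCountMatrix(
        df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(dtype=np.int64),
        samples, arm, meth, cov,
    )


def write_methyl_counts(path: str | Path, counts: MethylCountMatrix) -> None:
    df = pd.DataFrame({"chrom": counts.chrom, "pos": counts.pos})
    for j, s in enumerate(counts.samples):
        df[f"{s}.meth"] = counts.meth[:, j]
        df[f"{s}.cov"] = counts.coverage[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path, design: Mapping[str, str]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError("count TSV must start with a 'gene' column")
    samples = list(df.columns[1:])
    arm = [design[s] for s in samples]
    return CountMatrix(list(df["gene"]), samples, arm, df[samples].to_numpy())


def write_count_matrix(path: str | Path, counts: CountMatrix) -> None:
    df = pd.DataFrame({"gene": counts.genes})
    for j, s in enumerate(counts.samples):
        df[s] = counts.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def _score(fdr: float) -> int:
    return int(min(1000, round(-10 * np.log10(max(fdr, 1e-100)))))


def write_dmc_bed(path: str | Path, records: Iterable[DMCRecord]) -> None:
    """DMC BED6+: name = CpG id, score = round(-10*log10 fdr), then
    strand '.', delta_beta, direction, p, fdr."""
    write_bed(
        path,
        (
            (
                r.chrom, r.pos, r.pos + 1, r.cpg_id, _score(r.fdr), ".",
                f"{r.delta_beta:.6g}", r.direction, f"{r.p_value:.6g}", f"{r.fdr:.6g}",
            )
            for r in records
        ),
    )


def read_dmc_bed(path: str | Path) -> list[DMCRecord]:
    out = []
    for c, s, _e, name, _score_, _strand, delta, direction, p, fdr in read_bed(path):
        delta = float(delta)
        out.append(
            DMCRecord(
                cpg_id=name, chrom=c, pos=s,
                mean_beta_control=float("nan"), mean_beta_treated=float("nan"),
                delta_beta=delta, p_value=float(p), fdr=float(fdr), direction=direction,
            )
        )
    return out


def write_dmr_bed(path: str | Path, records: Iterable[DMRRecord]) -> None:
    write_bed(
        path,
        (
            (
                r.chrom, r.start, r.end, f"dmr_{i}", _score(r.p_value), ".",
                r.n_cpgs, f"{r.p_value:.6g}", f"{r.mean_delta_beta:.6g}",
            )
            for i, r in enumerate(records)
        ),
    )


def write_deg_table(path: str | Path, records: Iterable[DEGRecord]) -> None:
    rows = [
        {
            "gene": r.gene, "log2_fold_change": r.log2_fold_change,
            "p_value": r.p_value, "fdr": r.fdr, "direction": r.direction,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["gene", "log2_fold_change", "p_value", "fdr", "direction"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEGRecord(str(r.gene), float(r.log2_fold_change), float(r.p_value), float(r.fdr), str(r.direction))
        for r in df.itertuples(index=False)
    ]


def read_motif_file(path: str | Path) -> dict[str, str]:
    """Motif file: 'name<TAB>IUPAC' per line."""
    motifs: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'name<TAB>consensus'")
            motifs[parts[0]] = parts[1].upper()
    if not motifs:
        raise ValueError(f"no motifs in {path}")
    return motifs


def write_motif_hits_bed(path: str | Path, hits: Iterable[MotifHit]) -> None:
    write_bed(path, ((h.chrom, h.start, h.end, h.name, 0, h.strand, h.matched) for h in hits))


def dump_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
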