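"""Readers and writers for the flat-file formats the pipeline consumes.

GFF3 is converted between its native 1-based closed coordinates and the
package's internal 0-based half-open convention at this boundary; BED and
bedGraph are already 0-based half-open. Writers emit a canonical form, so
``write(read(write(x)))`` is byte-identical to ``write(x)``.

These parsers are deliberately hand-written line parsers: the pipeline
needs per-record errors with line numbers and byte-exact canonical
round-trips, and the formats are plain TSV.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CoverageTrack,
    Feature,
    GenomeModel,
    Interval,
    Peak,
    ValidationError,
)

logger = logging.getLogger(__name__)

GFF_SOURCE = "merochip"
_CLASS_TO_GFF_TYPE = {"gene": "gene", "repeat": "repeat_region"}
_GFF_TYPE_TO_CLASS = {
    "gene": "gene",
    "mRNA": "gene",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
}


class ParseError(ValidationError):
    """A record failed to parse; carries the path and 1-based line number."""

    def __init__(self, path: str, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _gff_attributes(field: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in field.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_annotation(
    path: str,
    format: Optional[str] = None,
    genome: Optional[GenomeModel] = None,
    default_class: str = "gene",
) -> List[Feature]:
    """Read features from GFF3 or BED (format inferred from the extension).

    GFF3 records must carry an ``ID`` attribute; the feature class is taken
    from the type column (``repeat_region``/``dispersed_repeat`` map to
    ``repeat``, everything gene-like to ``gene``). BED has no class column,
    so ``default_class`` applies. An empty file yields an empty list with a
    warning.
    """
    fmt = (format or ("bed" if path.endswith(".bed") else "gff3")).lower()
    features: List[Feature] = []
    seen_ids = set()
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(cols) < 9:
                        raise ValueError(f"expected 9 GFF3 columns, got {len(cols)}")
                    chrom, _source, gtype, start1, end1, _score, strand, _phase, attrs = cols[:9]
                    start = int(start1) - 1  # 1-based closed -> 0-based half-open
                    end = int(end1)
                    attributes = _gff_attributes(attrs)
                    if "ID" not in attributes:
                        raise ValueError("missing ID attribute")
                    locus_id = attributes["ID"]
                    feature_class = _GFF_TYPE_TO_CLASS.get(gtype, default_class)
                    description = attributes.get("Note")
                elif fmt == "bed":
                    if len(cols) < 3:
                        raise ValueError(f"expected >=3 BED columns, got {len(cols)}")
                    chrom = cols[0]
                    start = int(cols[1])
                    end = int(cols[2])
                    locus_id = cols[3] if len(cols) > 3 else f"feature_{line_no}"
                    strand = cols[5] if len(cols) > 5 else "."
                    feature_class = default_class
                    description = None
                else:
                    raise ValidationError(f"unknown annotation format {fmt!r}")
                if start >= end:
                    raise ValueError(f"start {start} >= end {end}")
                if locus_id in seen_ids:
                    raise ValueError(f"duplicate locus ID {locus_id!r}")
                iv = Interval(chrom, start, end, strand if strand in "+-" else ".")
                if genome is not None:
                    genome.validate_interval(iv)
                features.append(Feature(iv, locus_id, feature_class, description))
                seen_ids.add(locus_id)
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, line_no, str(exc)) from None
    if not features:
        logger.warning("no features parsed from %s", path)
    logger.info("read %d features from %s", len(features), path)
    return features


def write_annotation(features: Sequence[Feature], path: str, format: str = "gff3") -> None:
    """Write features in canonical GFF3 or BED6 form."""
    fmt = format.lower()
    with open(path, "w") as handle:
        if fmt == "gff3":
            handle.write("##gff-version 3\n")
            for f in features:
                iv = f.interval
                attrs = f"ID={f.locus_id}"
                if f.description:
                    attrs += f";Note={f.description}"
                handle.write(
                    f"{iv.chrom}\t{GFF_SOURCE}\t{_CLASS_TO_GFF_TYPE[f.feature_class]}\t"
                    f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand if iv.strand != '.' else '.'}\t.\t{attrs}\n"
                )
        elif fmt == "bed":
            for f in features:
                iv = f.interval
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.locus_id}\t0\t{iv.strand}\n"
                )
        else:
            raise ValidationError(f"unknown annotation format {fmt!r}")


def read_peaks(path: str, replicate_id: str, genome: Optional[GenomeModel] = None) -> List[Peak]:
    """Read peaks from BED3+ (name/score columns optional)."""
    peaks: List[Peak] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if len(cols) < 3:
                    raise ValueError(f"expected >=3 BED columns, got {len(cols)}")
                iv = Interval(cols[0], int(cols[1]), int(cols[2]))
                if genome is not None:
                    genome.validate_interval(iv)
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
                peaks.append(Peak(iv, replicate_id, score))
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, line_no, str(exc)) from None
    logger.info("read %d peaks from %s (replicate %s)", len(peaks), path, replicate_id)
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str) -> None:
    with open(path, "w") as handle:
        for i, p in enumerate(peaks):
            iv = p.interval
            score = "." if p.score is None else f"{p.score:g}"
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t{score}\t.\n")


def read_chrom_sizes(path: str) -> GenomeModel:
    chroms: List[Tuple[str, int]] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            try:
                chroms.append((cols[0], int(cols[1])))
            except (IndexError, ValueError) as exc:
                raise ParseError(path, line_no, str(exc)) from None
    return GenomeModel(chroms)


def write_chrom_sizes(genome: GenomeModel, path: str) -> None:
    with open(path, "w") as handle:
        for chrom, length in genome.chromosomes:
            handle.write(f"{chrom}\t{length}\n")


def read_coverage(path: str, genome: GenomeModel, bin_bp: int) -> CoverageTrack:
    """Bin a bedGraph into fixed-width bins of length-weighted mean value.

    Each bin's value is the mean of the bedGraph values over the bases it
    covers, with uncovered bases contributing 0 — so the binning is
    invariant to splitting a record in two. Negative values and intervals
    outside chromosome bounds are errors.
    """
    track = CoverageTrack.zeros(genome, bin_bp)
    sums = {c: np.zeros_like(v) for c, v in track.data.items()}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            try:
                chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
                if value < 0:
                    raise ValueError(f"negative coverage value {value}")
                iv = Interval(chrom, start, end)
                genome.validate_interval(iv)
            except (IndexError, ValueError, ValidationError) as exc:
                raise ParseError(path, line_no, str(exc)) from None
            vec = sums[chrom]
            first, last = start // bin_bp, (end - 1) // bin_bp
            for b in range(first, last + 1):
                lo = max(start, b * bin_bp)
                hi = min(end, (b + 1) * bin_bp)
                vec[b] += value * (hi - lo)
    for chrom, length in genome.chromosomes:
        widths = np.full(len(sums[chrom]), float(bin_bp))
        if length % bin_bp:
            widths[-1] = length % bin_bp
        track.data[chrom] = sums[chrom] / widths
    return track


def write_bedgraph(track: CoverageTrack, genome: GenomeModel, path: str) -> None:
    """Write a binned track as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w") as handle:
        for chrom, length in genome.chromosomes:
            vec = track.data[chrom]
            b = track.bin_size
            run_start = 0
            for i in range(1, len(vec) + 1):
                if i == len(vec) or vec[i] != vec[run_start]:
                    start = run_start * b
                    end = min(i * b, length)
                    handle.write(f"{chrom}\t{start}\t{end}\t{vec[run_start]:.6g}\n")
                    run_start = i


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_expression(path: str) -> pd.Series:
    """Read an expression TSV (locus_id, fpkm[, fpkm_rep2 ...]) to one FPKM
    per locus; multiple replicate columns are averaged."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("expression table needs locus_id plus >=1 FPKM column")
    values = df.iloc[:, 1:].mean(axis=1)
    if (values < 0).any():
        raise ValidationError("negative FPKM")
    series = pd.Series(values.values, index=df.iloc[:, 0].astype(str), name="fpkm")
    if series.index.duplicated().any():
        raise ValidationError("duplicate locus IDs in expression table")
    return series


def write_expression(fpkm: pd.Series, path: str) -> None:
    df = pd.DataFrame({"locus_id": fpkm.index, "fpkm": ["%.6g" % v for v in fpkm.values]})
    df.to_csv(path, sep="\t", index=False)


def read_go_table(path: str):
    """Read a GO map TSV (locus_id, term_id, term_name, subontology)."""
    from .go import GOAnnotationMap

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "term_id", "term_name", "subontology"}
    if not required.issubset(df.columns):
        raise ValidationError(f"GO table needs columns {sorted(required)}")
    gene_terms: Dict[str, set] = {}
    term_meta: Dict[str, Tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        gene_terms.setdefault(row.locus_id, set()).add(row.term_id)
        term_meta[row.term_id] = (row.term_name, row.subontology)
    return GOAnnotationMap(gene_terms, term_meta)


def write_go_table(go_map, path: str) -> None:
    rows = []
    for locus in sorted(go_map.gene_terms):
        for term in sorted(go_map.gene_terms[locus]):
            name, sub = go_map.term_meta[term]
            rows.append((locus, term, name, sub))
    pd.DataFrame(rows, columns=["locus_id", "term_id", "term_name", "subontology"]).to_csv(
        path, sep="\t", index=False
    )
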