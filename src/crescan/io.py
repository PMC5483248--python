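"""File formats: FASTA, site lists, matrix TSV/JASPAR, gene tables, BED.

Conventions
-----------
* Internal coordinates are 1-based inclusive; BED export/import converts
  to/from 0-based half-open.
* Matrix TSV: header row ``pos A C G T`` followed by one row per position.
  A transposed layout (four rows labelled A/C/G/T, one column per position)
  is auto-detected on read.  Round-trips are exact to 6 decimals.
* JASPAR count matrices are read through Bio.motifs for interoperability.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .motif import (
    ALPHABET,
    BackgroundModel,
    CountMatrix,
    FrequencyMatrix,
    Pssm,
    SiteCollection,
    ValidationError,
)
from .scan import GenomeSequence, HitTable, ScoredWindow

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_sites",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "read_jaspar_counts",
    "read_features",
    "write_bed",
    "read_bed_hits",
    "write_run_config",
    "read_run_config",
]

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


def read_fasta(path) -> list[GenomeSequence]:
    """Read DNA records in file order, uppercased.

    RNA (U) and characters outside the IUPAC DNA alphabet are rejected —
    this reader is for genomes and DNA sites only.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} contains non-DNA character(s) {sorted(bad)}"
            )
        out.append(GenomeSequence(identifier=rec.id, sequence=seq))
    return out


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_sites(path, source_label: str | None = None) -> SiteCollection:
    """Read aligned binding sites from FASTA or plain text.

    Plain text: one site per line; blank lines and ``#`` comments ignored.
    The format is sniffed from the first non-blank character ('>' = FASTA).
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    label = source_label if source_label is not None else str(path)
    if stripped.startswith(">"):
        recs = list(SeqIO.parse(_io.StringIO(text), "fasta"))
        return SiteCollection([str(r.seq) for r in recs], source_label=label)
    sites = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            sites.append(line)
    return SiteCollection(sites, source_label=label)


def write_matrix_tsv(matrix: np.ndarray, path, decimals: int = 6) -> None:
    """Write a 4 x k matrix as TSV with header ``pos A C G T``."""
    m = np.asarray(matrix, float)
    if m.shape[0] != 4 or m.ndim != 2:
        raise ValidationError(f"matrix must be 4 x k, got {m.shape}")
    df = pd.DataFrame(m.T, columns=list(ALPHABET))
    df.insert(0, "pos", np.arange(1, m.shape[1] + 1))
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{decimals}f")


def read_matrix_tsv(path) -> np.ndarray:
    """Read a 4 x k matrix from TSV, auto-detecting orientation.

    Accepts the native layout (header ``pos A C G T``, one row per
    position) and a transposed one (four rows whose first field is the base
    letter, one column per position, with or without a header line).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    first_row = [str(x).strip() for x in df.iloc[0]]
    first_col = [str(x).strip().upper() for x in df.iloc[:, 0]]
    if [c.upper() for c in first_row[:5]] == ["POS", "A", "C", "G", "T"] or (
        first_row[0].lower() in ("pos", "position")
    ):
        body = df.iloc[1:]
        header = [c.upper() for c in first_row]
        try:
            cols = [header.index(b) for b in ALPHABET]
        except ValueError:
            raise ValidationError(f"{path}: header lacks A/C/G/T columns") from None
        m = body.iloc[:, cols].to_numpy(dtype=float).T
    elif set(first_col[:4]) == set(ALPHABET) or set(first_col) >= set(ALPHABET):
        start = 1 if first_col[0] not in ALPHABET else 0
        rows = {}
        for _, row in df.iloc[start:].iterrows():
            base = str(row.iloc[0]).strip().upper()
            if base in ALPHABET:
                rows[base] = row.iloc[1:].dropna().to_numpy(dtype=float)
        if set(rows) != set(ALPHABET):
            raise ValidationError(f"{path}: transposed matrix missing base rows")
        m = np.vstack([rows[b] for b in ALPHABET])
    else:
        raise ValidationError(f"{path}: unrecognised matrix layout")
    if m.shape[0] != 4 or m.shape[1] < 1:
        raise ValidationError(f"{path}: parsed matrix has shape {m.shape}")
    return m


def read_jaspar_counts(path) -> CountMatrix:
    """Read a JASPAR-format count matrix (via Bio.motifs)."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float)
    colsums = counts.sum(axis=0)
    n = int(round(colsums[0]))
    if not np.allclose(colsums, n):
        raise ValidationError(f"{path}: JASPAR columns sum unevenly: {colsums}")
    return CountMatrix(counts=counts.astype(np.int64), n_sites=n)


def load_pssm(path, background: BackgroundModel | None = None) -> Pssm:
    """Load a pre-built log-odds matrix (e.g. a published PSSM) from TSV."""
    w = read_matrix_tsv(path)
    return Pssm(w=w, background=background or BackgroundModel.uniform())


def read_features(path) -> pd.DataFrame:
    """Read a gene table from BED or GFF3.

    Returns a DataFrame with columns contig, start, end (1-based inclusive),
    strand, name.  GFF3 rows are filtered to gene/CDS features; the name
    comes from the ``Name``, ``ID`` or ``gene_id`` attribute.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff"):
        rows = []
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2].lower() not in ("gene", "cds"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene_id") or "."
            rows.append(
                dict(contig=f[0], start=int(f[3]), end=int(f[4]), strand=f[6], name=name)
            )
        if not rows:
            raise ValidationError(f"{path}: no gene/CDS features found")
        return pd.DataFrame(rows)
    # BED: 0-based half-open -> 1-based inclusive
    rows = []
    for line in text.splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValidationError(f"{path}: malformed BED line {line!r}")
        rows.append(
            dict(
                contig=f[0],
                start=int(f[1]) + 1,
                end=int(f[2]),
                strand=f[5] if len(f) > 5 else "+",
                name=f[3] if len(f) > 3 else ".",
            )
        )
    if not rows:
        raise ValidationError(f"{path}: empty feature table")
    return pd.DataFrame(rows)


def write_bed(hits: HitTable, path, name_prefix: str = "hit") -> None:
    """Write hits as BED6.

    Coordinates convert from internal 1-based inclusive to BED's 0-based
    half-open.  The BED score column carries the bit score rounded to 2
    decimals directly (no 0-1000 rescaling), documented here because BED
    consumers sometimes expect the capped convention.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# crescan hits; threshold={hits.threshold:g}; "
            "score column = PSSM bits (2 dp)\n"
        )
        for i, h in enumerate(hits, 1):
            fh.write(
                f"{h.contig}\t{h.start - 1}\t{h.end}\t{name_prefix}{i}\t"
                f"{h.score:.2f}\t{h.strand}\n"
            )


def read_bed_hits(path) -> HitTable:
    """Read a BED6 file written by :func:`write_bed` back into a HitTable."""
    hits = []
    threshold = -float("inf")
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "threshold=" in line:
                token = line.split("threshold=")[1].split(";")[0]
                threshold = float(token)
            continue
        if not line.strip():
            continue
        f = line.split("\t")
        hits.append(
            ScoredWindow(f[0], int(f[1]) + 1, int(f[2]), f[5], float(f[4]))
        )
    return HitTable(hits=hits, threshold=threshold)


def write_run_config(path, config: dict) -> None:
    """Serialise a run configuration as flat ``key=value`` lines."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key}={config[key]}\n")


def read_run_config(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#") and "=" in line:
            key, value = line.split("=", 1)
            out[key] = value
    return out
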