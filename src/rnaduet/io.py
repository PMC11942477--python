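"""Readers and writers for the formats the tool touches.

FASTA (via Biopython), "vienna" files (FASTA-style records with a
dot-bracket line), CT and BPSEQ structure files, and two-column label
TSVs. Internal coordinates are 0-based; CT/BPSEQ are 1-based at the file
boundary. Malformed input is rejected, never silently repaired.
"""

from __future__ import annotations

import csv
from typing import Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import RnaSequence
from .structure import PairMatrix, parse_dotbracket, render_dotbracket


def read_fasta(path) -> List[Tuple[str, RnaSequence]]:
    """Order-preserving list of (id, normalized sequence)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        out.append((rec.id, RnaSequence(str(rec.seq))))
    return out


def write_fasta(records: Iterable[Tuple[str, RnaSequence]], path) -> None:
    seqs = [SeqRecord(Seq(seq.bases), id=rid, description="")
            for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_vienna(path) -> List[Tuple[str, RnaSequence, PairMatrix]]:
    """Read >id / sequence / dot-bracket triples."""
    out = []
    with open(path) as f:
        lines = [ln.rstrip("\n") for ln in f if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"truncated record {lines[i]!r}")
        rid = lines[i][1:].split()[0]
        seq = RnaSequence(lines[i + 1])
        pm = parse_dotbracket(lines[i + 2])
        if pm.L != len(seq):
            raise ValueError(f"structure/sequence length mismatch in {rid!r}")
        out.append((rid, seq, pm))
        i += 3
    return out


def write_vienna(records: Iterable[Tuple[str, RnaSequence, PairMatrix]],
                 path) -> None:
    with open(path, "w") as f:
        for rid, seq, pm in records:
            f.write(f">{rid}\n{seq.bases}\n{render_dotbracket(pm)}\n")


def read_ct(path) -> Tuple[RnaSequence, PairMatrix]:
    """Canonical 6-column CT: index, base, prev, next, partner, index."""
    with open(path) as f:
        lines = [ln.split() for ln in f if ln.strip()]
    header = lines[0]
    try:
        L = int(header[0])
    except (ValueError, IndexError):
        raise ValueError("CT header must start with the sequence length")
    body = lines[1 : 1 + L]
    if len(body) != L:
        raise ValueError(f"CT body has {len(body)} rows, header says {L}")
    bases = []
    partner = {}
    for row in body:
        if len(row) != 6:
            raise ValueError(f"CT row must have 6 columns, got {len(row)}")
        pos, base, _, _, mate, _ = row
        pos, mate = int(pos), int(mate)
        if not (1 <= pos <= L) or not (0 <= mate <= L):
            raise ValueError(f"CT index out of range in row {row}")
        bases.append(base)
        if mate:
            partner[pos] = mate
    _check_reciprocal(partner)
    pairs = {(min(i, j) - 1, max(i, j) - 1) for i, j in partner.items()}
    return RnaSequence("".join(bases)), PairMatrix(L, pairs)


def read_bpseq(path) -> Tuple[RnaSequence, PairMatrix]:
    """BPSEQ: one '<pos> <base> <partner>' row per position, 1-based."""
    with open(path) as f:
        rows = [ln.split() for ln in f
                if ln.strip() and not ln.startswith("#")]
    L = len(rows)
    bases = []
    partner = {}
    for n, row in enumerate(rows, start=1):
        if len(row) != 3:
            raise ValueError(f"BPSEQ row must have 3 columns, got {row}")
        pos, base, mate = int(row[0]), row[1], int(row[2])
        if pos != n:
            raise ValueError(f"BPSEQ positions must be consecutive; got {pos} at row {n}")
        if not (0 <= mate <= L):
            raise ValueError(f"BPSEQ partner {mate} out of range")
        bases.append(base)
        if mate:
            partner[pos] = mate
    _check_reciprocal(partner)
    pairs = {(min(i, j) - 1, max(i, j) - 1) for i, j in partner.items()}
    return RnaSequence("".join(bases)), PairMatrix(L, pairs)


def _check_reciprocal(partner: dict) -> None:
    for i, j in partner.items():
        if i == j:
            raise ValueError(f"position {i} pairs with itself")
        if partner.get(j) != i:
            raise ValueError(f"non-reciprocal pairing {i} -> {j}")


def read_labels(path) -> List[Tuple[str, str]]:
    """Two-column TSV: record id, class label."""
    out = []
    with open(path) as f:
        for row in csv.reader(f, delimiter="\t"):
            if not row:
                continue
            if len(row) < 2:
                raise ValueError(f"label row needs 2 columns: {row}")
            out.append((row[0], row[1]))
    return out


def write_labels(labels: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        for rid, label in labels:
            w.writerow([rid, label])
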