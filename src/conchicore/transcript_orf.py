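"""Contigs to candidate proteins: six-frame translation, ORF calling, assembly stats.

Transcriptome contigs from a mantle-tissue assembly are short (a few hundred
bp on average) and mostly partial CDS, so ORFs are called as stop-delimited
stretches by default rather than requiring an initiator methionine; a config
flag switches to Met-initiated ORFs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Seq import Seq
from Bio import SeqIO

FRAMES = (1, 2, 3, -1, -2, -3)

_VALID_NT = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class Contig:
    """A nucleotide contig with optional read-mapping evidence."""

    id: str
    sequence: str
    mapped_read_count: Optional[int] = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"contig {self.id}: empty sequence")
        if not _VALID_NT.match(seq):
            bad = next(i for i, c in enumerate(seq) if c not in "ACGTN")
            raise ValueError(
                f"contig {self.id}: non-IUPAC character {seq[bad]!r} at position {bad}"
            )
        if self.mapped_read_count is not None and self.mapped_read_count < 0:
            raise ValueError(f"contig {self.id}: negative mapped_read_count")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranslatedFrame:
    contig_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    aa_sequence: str  # includes '*' stop symbols


@dataclass(frozen=True)
class Orf:
    contig_id: str
    frame: int
    start: int  # 0-based aa offset within the frame, half-open
    end: int
    aa_sequence: str

    @property
    def id(self) -> str:
        sign = "+" if self.frame > 0 else ""
        return f"{self.contig_id}|{sign}{self.frame}|{self.start}-{self.end}"


def parse_orf_id(orf_id: str) -> tuple[str, int, int, int]:
    """Split an ORF id of the form ``contig|+1|start-end`` back into fields."""
    contig_id, frame_s, span = orf_id.rsplit("|", 2)
    start_s, end_s = span.split("-")
    return contig_id, int(frame_s), int(start_s), int(end_s)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    max_len: int
    mean_len: float
    n50: int


def six_frame_translate(contig: Contig, genetic_code: int | str = 1) -> list[TranslatedFrame]:
    """Translate a contig in all six reading frames.

    Reverse frames translate the reverse complement. Trailing partial codons
    are dropped, so frame k of an L-bp contig yields floor((L-k+1)/3) residues.
    Codons containing N translate to 'X'.
    """
    fwd = Seq(contig.sequence)
    rev = fwd.reverse_complement()
    out = []
    for frame in FRAMES:
        src = fwd if frame > 0 else rev
        offset = abs(frame) - 1
        sub = src[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(sub.translate(table=genetic_code))
        out.append(TranslatedFrame(contig.id, frame, aa))
    return out


def find_orfs(
    frames: Iterable[TranslatedFrame],
    min_orf_len: int = 100,
    require_met: bool = False,
) -> list[Orf]:
    """Report ORFs of at least ``min_orf_len`` residues in every frame.

    Default mode reports every maximal stop-free stretch (open-ended ORFs,
    appropriate for fragmented contigs lacking a start codon). With
    ``require_met`` each stretch is trimmed to start at its first methionine.
    The strict reading of "longer than 100 aa" is obtained with
    ``min_orf_len=101``.
    """
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    frame_order = {f: i for i, f in enumerate(FRAMES)}
    orfs: list[Orf] = []
    for fr in frames:
        pos = 0
        for stretch in fr.aa_sequence.split("*"):
            start, seq = pos, stretch
            if require_met:
                m = seq.find("M")
                if m == -1:
                    seq = ""
                else:
                    start, seq = start + m, seq[m:]
            if len(seq) >= min_orf_len:
                orfs.append(Orf(fr.contig_id, fr.frame, start, start + len(seq), seq))
            pos += len(stretch) + 1
    orfs.sort(key=lambda o: (o.contig_id, frame_order[o.frame], o.start))
    return orfs


def assembly_stats(contigs: list[Contig]) -> AssemblyStats:
    """Contig count, max/mean length and N50 of an assembly."""
    if not contigs:
        raise ValueError("assembly_stats requires at least one contig")
    lengths = sorted((c.length for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if 2 * acc >= total:
            n50 = L
            break
    return AssemblyStats(
        n_contigs=len(lengths),
        max_len=lengths[0],
        mean_len=total / len(lengths),
        n50=n50,
    )


def fpkm(mapped_read_count: int, length_bp: int, total_mapped_reads: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    if mapped_read_count == 0:
        return 0.0
    return mapped_read_count / ((length_bp / 1e3) * (total_mapped_reads / 1e6))


def read_contigs_fasta(path) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_orfs_fasta(orfs: Iterable[Orf], path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.id}\n{orf.aa_sequence}\n")
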