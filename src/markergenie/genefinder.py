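"""Six-frame ORF extraction and translation from assembled contigs.

Assembled (meta)transcriptome contigs are frequently fragmentary, so open
reading frames are called stop-to-stop in all six frames without requiring
an initiator codon; requiring ATG would drop genuine gene fragments.
Translation uses the bacterial/archaeal genetic code (NCBI table 11) by
default; codons containing ``N`` translate to ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio.Data import CodonTable

from .errors import ValidationError

STOP = "*"
_NT = set("ACGTN")

#: default minimum ORF length in amino acids
DEFAULT_MIN_AA_LEN = 30
DEFAULT_TABLE = 11

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_map(table_id: int) -> tuple[dict[str, str], frozenset[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(tbl.forward_table), frozenset(tbl.stop_codons)


@dataclass
class Contig:
    """One assembled nucleotide sequence from one sample."""

    contig_id: str
    sample_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def validate(self) -> None:
        if not self.seq:
            raise ValidationError(f"{self.contig_id}: empty sequence")
        bad = set(self.seq) - _NT
        if bad:
            raise ValidationError(f"{self.contig_id}: invalid nucleotides {sorted(bad)}")


@dataclass
class Orf:
    """A translated open reading frame.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the
    *forward* strand of the contig regardless of ``strand``; ``frame`` is
    the reading frame (0–2) on the strand the ORF was read from.
    """

    orf_id: str
    contig_id: str
    strand: str  # '+' or '-'
    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str

    def validate(self) -> None:
        span = self.nt_end - self.nt_start
        if span <= 0 or span % 3:
            raise ValidationError(f"{self.orf_id}: nt span {span} not a positive multiple of 3")
        if len(self.aa_seq) != span // 3:
            raise ValidationError(f"{self.orf_id}: aa length does not match nt span")
        if STOP in self.aa_seq:
            raise ValidationError(f"{self.orf_id}: aa_seq contains a stop symbol")
        if self.strand not in "+-":
            raise ValidationError(f"{self.orf_id}: bad strand {self.strand!r}")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(codon_seq: str, table: int = DEFAULT_TABLE) -> str:
    """Translate a nucleotide string whose length is a multiple of 3.

    Stop codons become ``*``; any codon containing ``N`` becomes ``X``.
    """
    seq = codon_seq.upper()
    if len(seq) % 3:
        raise ValidationError(f"sequence length {len(seq)} not divisible by 3")
    fwd, stops = _codon_map(table)
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in stops:
            out.append(STOP)
        elif codon in fwd:
            out.append(fwd[codon])
        else:
            out.append("X")  # ambiguous (contains N)
    return "".join(out)


def six_frame_orfs(
    contig: Contig,
    min_aa_len: int = DEFAULT_MIN_AA_LEN,
    table: int = DEFAULT_TABLE,
) -> list[Orf]:
    """All maximal stop-free translated stretches in all six frames.

    Stretches run stop-to-stop (sequence ends count as boundaries) and are
    kept when their translation is at least ``min_aa_len`` residues.
    Coordinates are reported on the forward strand; ordering is
    deterministic by ``(nt_start, strand, frame)`` with ordinal ids.
    """
    contig.validate()
    if min_aa_len < 1:
        raise ValidationError("min_aa_len must be >= 1")
    L = len(contig.seq)
    found: list[tuple[int, str, int, int, str]] = []  # nt_start, strand, frame, nt_end, aa
    for strand in "+-":
        seq = contig.seq if strand == "+" else revcomp(contig.seq)
        for frame in range(3):
            ncod = (L - frame) // 3
            if ncod < min_aa_len:
                continue
            aa = translate(seq[frame:frame + 3 * ncod])
            start_cod = 0
            for k, ch in enumerate(aa + STOP):
                if ch == STOP:
                    if k - start_cod >= min_aa_len:
                        s = frame + 3 * start_cod
                        e = frame + 3 * k
                        if strand == "-":
                            s, e = L - e, L - s
                        found.append((s, strand, frame, e, aa[start_cod:k]))
                    start_cod = k + 1
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    orfs = []
    for n, (s, strand, frame, e, aa) in enumerate(found, start=1):
        orf = Orf(
            orf_id=f"{contig.contig_id}_orf{n}",
            contig_id=contig.contig_id,
            strand=strand,
            frame=frame,
            nt_start=s,
            nt_end=e,
            aa_seq=aa,
        )
        orf.validate()
        orfs.append(orf)
    return orfs


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing
# ---------------------------------------------------------------------------

def read_contigs_fasta(stream: TextIO, sample_id: str) -> list[Contig]:
    """Read a multi-FASTA of contigs for one sample."""
    from Bio import SeqIO

    contigs = []
    for rec in SeqIO.parse(stream, "fasta"):
        c = Contig(contig_id=rec.id, sample_id=sample_id, seq=str(rec.seq))
        c.validate()
        contigs.append(c)
    return contigs


def orfs_to_fasta(orfs: Iterable[Orf]) -> str:
    out = []
    for o in orfs:
        out.append(f">{o.orf_id} {o.contig_id}:{o.nt_start}-{o.nt_end}({o.strand})")
        out.append(o.aa_seq)
    return "\n".join(out) + ("\n" if out else "")


def orfs_to_tsv(orfs: Iterable[Orf]) -> str:
    lines = ["orf_id\tcontig_id\tstrand\tframe\tnt_start\tnt_end\taa_len"]
    for o in orfs:
        lines.append(
            f"{o.orf_id}\t{o.contig_id}\t{o.strand}\t{o.frame}\t"
            f"{o.nt_start}\t{o.nt_end}\t{len(o.aa_seq)}"
        )
    return "\n".join(lines) + "\n"
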