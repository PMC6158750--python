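"""Input/output for the standard formats the pipeline consumes and emits.

Reads: redundant (or count-collapsed) FASTA small-RNA / degradome libraries,
transcriptome FASTA, GFF3 + genome transcript extraction.  Writes: the final
results CSV.  All sequences are normalised to uppercase DNA (U -> T) on the
way in; one internal alphabet everywhere.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_CHARS = set("ACGTUNRYSWKMBDHV")  # IUPAC nucleotide letters
# trailing "-<count>" or "(x<count>)" on a FASTA header names an abundance
_COUNT_TAG = re.compile(r"(?:-(\d+)|\(x(\d+)\))\s*$")


@dataclass
class ReadLibrary:
    """A collapsed sequencing-read library.

    records maps unique uppercase DNA sequence -> abundance (>= 1);
    total_abundance is kept equal to the sum of abundances.
    """

    name: str
    records: dict[str, int] = field(default_factory=dict)

    @property
    def total_abundance(self) -> int:
        return sum(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def add(self, sequence: str, abundance: int = 1) -> None:
        if abundance < 1:
            raise ValueError("abundance must be >= 1")
        self.records[sequence] = self.records.get(sequence, 0) + abundance


@dataclass(frozen=True)
class Transcript:
    """A reference (messenger RNA) sequence."""

    id: str
    sequence: str
    source: str = "fasta"  # "fasta" | "gff3"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _check_alphabet(seq: str, record_id: str) -> None:
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-IUPAC characters: {sorted(bad)}"
        )


def read_redundant_fasta(path: str | Path, name: str | None = None) -> ReadLibrary:
    """Read a redundant FASTA read file and collapse identical sequences.

    Each record counts one copy unless its header carries a trailing
    ``-<count>`` or ``(x<count>)`` tag, in which case that count is used —
    both the fully redundant and the pre-collapsed dialects common in sRNA
    labs are accepted.
    """
    path = Path(path)
    lib = ReadLibrary(name=name or path.stem)
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(str(rec.seq))
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} is empty")
        _check_alphabet(seq, rec.id)
        m = _COUNT_TAG.search(rec.description.split()[0] if rec.description else rec.id)
        count = int(m.group(1) or m.group(2)) if m else 1
        lib.add(seq, count)
        n_records += 1
    if n_records == 0:
        raise ValueError(f"no reads found in {path}")
    return lib


def read_transcriptome_fasta(path: str | Path) -> list[Transcript]:
    """Read a transcriptome FASTA; order preserved, ids must be unique."""
    path = Path(path)
    transcripts: list[Transcript] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(str(rec.seq))
        _check_alphabet(seq, rec.id)
        transcripts.append(Transcript(id=rec.id, sequence=seq, source="fasta"))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = [tid for tid, n in seen.items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate transcript ids in {path}: {dupes}")
    if not transcripts:
        raise ValueError(f"no transcripts found in {path}")
    return transcripts


def extract_transcripts_gff3(
    gff3: str | Path,
    genome: str | Path,
    include_utrs: bool = True,
) -> list[Transcript]:
    """Extract spliced transcript sequences from a GFF3 annotation + genome.

    Per mRNA feature, exon sub-features (with UTRs) or CDS sub-features
    (without) are concatenated in genomic order; minus-strand transcripts are
    reverse-complemented.  GFF3 coordinates are 1-based inclusive.
    """
    import gffutils

    from .encoding import reverse_complement

    chromosomes = {
        rec.id: _normalise(str(rec.seq)) for rec in SeqIO.parse(str(genome), "fasta")
    }
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    child_type = "exon" if include_utrs else "CDS"
    transcripts: list[Transcript] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        if mrna.seqid not in chromosomes:
            raise ValueError(f"unknown seqid {mrna.seqid!r} (not in genome FASTA)")
        chrom = chromosomes[mrna.seqid]
        parts = sorted(
            db.children(mrna, featuretype=child_type), key=lambda f: f.start
        )
        if not parts:
            logger.warning(
                "mRNA %s has no %s children; skipped", mrna.id, child_type
            )
            continue
        seq = "".join(chrom[p.start - 1 : p.end] for p in parts)
        if mrna.strand == "-":
            seq = reverse_complement(seq)
        transcripts.append(Transcript(id=mrna.id, sequence=seq, source="gff3"))
    return transcripts


#: column order of the results CSV
CSV_COLUMNS = [
    "srna_name",
    "srna_sequence",
    "srna_abundance_raw",
    "srna_abundance_norm",
    "transcript_id",
    "cleavage_position",
    "category",
    "peak_abundance_raw",
    "peak_abundance_weighted",
    "peak_abundance_norm",
    "alignment_score",
    "duplex",
    "mfe",
    "mfe_ratio",
    "p_value",
]


def write_results_csv(results: Iterable, path: str | Path) -> None:
    """Write predicted interactions to CSV.

    Rows are sorted by (transcript id, cleavage position, sRNA sequence) so
    repeated runs produce byte-identical files.
    """
    rows = sorted(
        results,
        key=lambda r: (r.transcript_id, r.cleavage_position, r.srna_sequence),
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in rows:
            writer.writerow(r.as_row())
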