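"""Stop-codon contexts (SCCs) of MeCP2 nonsense variants and reporter design.

A nonsense mutation replaces a sense codon with a premature termination
codon (PTC).  How readily the ribosome reads through that PTC depends on
the stop codon itself and its flanking nucleotides — the stop codon
context, taken here as the 10 nt upstream, the stop, and the 10 nt
downstream (a 23-nt window, positions -10..+13, where +4 is the first
base 3' of the stop).  This module represents such contexts, extracts
them from a coding sequence, classifies them, and designs the annealed
oligonucleotide duplexes used to insert an SCC between the RFP and GFP
halves of the dual reporter.

The packaged variant table covers the 14 pathogenic MeCP2 nonsense
mutations analysed by the assay.  Only fields explicitly documented for
each variant are marked ``stated``; flanking sequences that are not
documented are left empty and flagged ``unverified``, and one stop class
that is implied only by the published 2/6/6 class partition is flagged
``inferred-by-count``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

from .errors import BoundsError, ContextError, FormatError

STOP_CODONS_DNA = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _norm_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.strip().upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _to_rna(seq: str) -> str:
    return seq.replace("T", "U")


@dataclass
class SCCRecord:
    """One variant's stop-codon context.

    ``upstream``/``downstream`` are 10-nt DNA strings when known and may
    be ``None`` for packaged variants whose flanks are undocumented.
    ``plus_four`` is the base immediately 3' of the stop; when
    ``downstream`` is present it must equal its first base.
    """

    variant_name: str
    stop_codon: str
    upstream: str | None = None
    downstream: str | None = None
    plus_four: str | None = None
    cdna_codon_index: int | None = None
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stop_codon = _norm_dna(self.stop_codon)
        if self.stop_codon not in STOP_CODONS_DNA:
            raise ContextError(
                f"{self.variant_name}: {self.stop_codon!r} is not a stop codon"
            )
        if self.upstream is not None:
            self.upstream = _norm_dna(self.upstream)
            if len(self.upstream) != 10:
                raise ValueError(f"{self.variant_name}: upstream must be 10 nt")
        if self.downstream is not None:
            self.downstream = _norm_dna(self.downstream)
            if len(self.downstream) != 10:
                raise ValueError(f"{self.variant_name}: downstream must be 10 nt")
            if self.plus_four is None:
                self.plus_four = self.downstream[0]
        if self.plus_four is not None:
            self.plus_four = _norm_dna(self.plus_four)
            if self.downstream is not None and self.plus_four != self.downstream[0]:
                raise ValueError(
                    f"{self.variant_name}: plus_four disagrees with downstream[0]"
                )

    @property
    def stop_class(self) -> str:
        """Stop codon class in RNA letters: UAA, UAG or UGA."""
        return _to_rna(self.stop_codon)

    @property
    def plus_four_rna(self) -> str | None:
        return _to_rna(self.plus_four) if self.plus_four else None

    @property
    def residue(self) -> int | None:
        """PTC codon position, equal to the truncated residue number."""
        return self.cdna_codon_index

    @property
    def insert_core(self) -> str:
        """The 23-nt SCC window (-10..+13).  Requires known flanks."""
        if self.upstream is None or self.downstream is None:
            raise ValueError(f"{self.variant_name}: flanking sequence unknown")
        return self.upstream + self.stop_codon + self.downstream


def extract_scc(cds: str, ptc_codon_index: int, variant_name: str = "") -> SCCRecord:
    """Cut the -10..+13 window around the stop codon at a 1-based codon index.

    Raises ContextError if the codon there is not a stop, BoundsError if
    fewer than 10 nt flank the codon on either side.
    """
    cds = _norm_dna("".join(cds.split()))
    start = 3 * (ptc_codon_index - 1)
    if start < 10 or len(cds) < start + 13:
        raise BoundsError(
            f"SCC window for codon {ptc_codon_index} exceeds sequence bounds"
        )
    codon = cds[start : start + 3]
    if codon not in STOP_CODONS_DNA:
        raise ContextError(
            f"codon {ptc_codon_index} is {codon!r}, not a stop codon"
        )
    return SCCRecord(
        variant_name=variant_name or f"codon{ptc_codon_index}",
        stop_codon=codon,
        upstream=cds[start - 10 : start],
        downstream=cds[start + 3 : start + 13],
        cdna_codon_index=ptc_codon_index,
    )


def classify_stop(scc: SCCRecord) -> str:
    """Return the stop class (UAA/UAG/UGA) of a context record."""
    return scc.stop_class


class VariantTable:
    """Ordered collection of SCCRecords with unique variant names."""

    def __init__(self, records: list[SCCRecord]):
        names = [r.variant_name for r in records]
        if len(set(names)) != len(names):
            raise ValueError("variant names must be unique")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SCCRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> SCCRecord:
        for rec in self.records:
            if rec.variant_name == name or rec.variant_name == f"p.{name}":
                return rec
        raise KeyError(name)


def class_counts(table: VariantTable) -> dict[str, int]:
    """Count records per stop class; classes absent from the table map to 0."""
    counts = {"UAA": 0, "UAG": 0, "UGA": 0}
    for rec in table:
        counts[rec.stop_class] += 1
    return counts


# --- reporter insert design -------------------------------------------------

#: 5' overhangs produced by the two enzymes that open the reporter vector.
#: BspEI cuts T^CCGGA leaving a 5'-CCGG overhang; BstEII cuts G^GTNACC
#: leaving a 5'-GTNAC overhang (N set by the vector site).
BSPEI_SITE = "TCCGGA"
BSTEII_SITE = "GGTNACC"


@dataclass(frozen=True)
class OligoPair:
    """Annealed sense/antisense oligos with sticky 5' ends.

    ``sense`` carries the 4-nt BspEI-compatible overhang at its 5' end;
    ``antisense`` carries the 5-nt BstEII-compatible overhang.
    """

    sense: str
    antisense: str
    sense_overhang_len: int = 4
    antisense_overhang_len: int = 5

    @property
    def duplex_sense(self) -> str:
        return self.sense[self.sense_overhang_len :]

    @property
    def duplex_antisense(self) -> str:
        return self.antisense[self.antisense_overhang_len :]


def design_reporter_insert(scc: SCCRecord, bstEII_n: str = "A") -> OligoPair:
    """Design the annealed oligo duplex carrying an SCC into the reporter.

    Ligation of the pair into a BspEI/BstEII-opened vector reconstitutes
    both recognition sites around the 23-nt SCC core.  ``bstEII_n`` is
    the degenerate base of the vector's BstEII site (GGTNACC).
    """
    core = scc.insert_core
    n = _norm_dna(bstEII_n)
    sense = "CCGGA" + core + "G"
    antisense = "GT" + reverse_complement(n) + "AC" + reverse_complement("A" + core + "G")
    return OligoPair(sense=sense, antisense=antisense)


# --- I/O ---------------------------------------------------------------------

_CSV_FIELDS = [
    "variant_name",
    "upstream",
    "stop_codon",
    "downstream",
    "plus_four",
    "cdna_codon_index",
    "stop_class_provenance",
    "plus_four_provenance",
]


def read_variant_table(path: str | Path) -> VariantTable:
    """Read a variant table CSV (see ``data/mecp2_variants.csv`` for layout)."""
    records = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "variant_name" not in reader.fieldnames:
            raise FormatError(f"{path}: missing variant_name column")
        for row in reader:
            flags = {}
            for key in ("stop_class_provenance", "plus_four_provenance"):
                if row.get(key):
                    flags[key] = row[key]
            records.append(
                SCCRecord(
                    variant_name=row["variant_name"],
                    stop_codon=row["stop_codon"],
                    upstream=row.get("upstream") or None,
                    downstream=row.get("downstream") or None,
                    plus_four=row.get("plus_four") or None,
                    cdna_codon_index=(
                        int(row["cdna_codon_index"])
                        if row.get("cdna_codon_index")
                        else None
                    ),
                    flags=flags,
                )
            )
    return VariantTable(records)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for rec in table:
            writer.writerow(
                {
                    "variant_name": rec.variant_name,
                    "upstream": rec.upstream or "",
                    "stop_codon": rec.stop_codon,
                    "downstream": rec.downstream or "",
                    "plus_four": rec.plus_four or "",
                    "cdna_codon_index": rec.cdna_codon_index or "",
                    "stop_class_provenance": rec.flags.get("stop_class_provenance", ""),
                    "plus_four_provenance": rec.flags.get("plus_four_provenance", ""),
                }
            )


def load_packaged_variants() -> VariantTable:
    """The 14 pathogenic MeCP2 nonsense variants shipped with the package."""
    ref = resources.files("trquant").joinpath("data/mecp2_variants.csv")
    with resources.as_file(ref) as path:
        return read_variant_table(path)


def read_cds_fasta(path: str | Path) -> str:
    """Read a single coding sequence from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(f"{path}: expected a single CDS, found {len(records)}")
    return _norm_dna(str(records[0].seq))


def expected_class_partition() -> Mapping[str, int]:
    """Published class partition of the 14-variant panel: 2 UAA, 6 UAG, 6 UGA."""
    return {"UAA": 2, "UAG": 6, "UGA": 6}
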