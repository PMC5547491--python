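"""Reference sequences, read handling, and alignment-free variant calling.

Variant reads are compared position-by-position against a user-supplied
wild-type sequence.  Reads must have the same length and start point as the
reference; reads of a different length are rejected rather than aligned, so
this mode cannot call insertions or deletions.  Barcoded libraries are
supported through a many-to-one barcode-to-variant map.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, TextIO, Union

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

WILD_TYPE_LABEL = "_wt"

_VALID_BASES = frozenset("ACGT")

#: codon -> amino acid (one letter), stop as '*'
_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def _aa3(aa: str) -> str:
    """Three-letter amino-acid code, with 'Ter' for stop."""
    return "Ter" if aa == "*" else seq3(aa)


@dataclass(frozen=True)
class ReferenceSequence:
    """Wild-type nucleotide sequence and the coordinate frame for calling.

    Parameters
    ----------
    sequence
        Uppercase DNA (A/C/G/T only).
    is_coding
        If True, amino-acid changes are derived per codon using the
        standard genetic code.
    frame_offset
        0-based offset of the first complete codon within `sequence`.
    position_offset
        Integer added to reported nucleotide positions (for sequencing a
        window inside a larger gene).
    """

    sequence: str
    is_coding: bool = False
    frame_offset: int = 0
    position_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"reference contains invalid bases: {sorted(bad)}")
        if self.is_coding and (len(self.sequence) - self.frame_offset) % 3 != 0:
            raise ValueError(
                "coding reference length minus frame_offset must be a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def protein(self) -> str:
        """Translate the coding portion (one-letter codes, '*' = stop)."""
        if not self.is_coding:
            raise ValueError("reference is not coding")
        cds = self.sequence[self.frame_offset :]
        return "".join(_CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: bases (may contain N) and per-base Phred scores."""

    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, order=True)
class Substitution:
    position: int  # 1-based, after position_offset
    ref_base: str
    alt_base: str

    def label(self) -> str:
        return f"c.{self.position}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class VariantKey:
    """An ordered set of nucleotide substitutions relative to the reference.

    An empty substitution list is the wild-type sentinel, labelled ``_wt``.
    """

    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("substitution positions must be strictly increasing")

    @property
    def is_wild_type(self) -> bool:
        return not self.substitutions

    @property
    def label(self) -> str:
        if self.is_wild_type:
            return WILD_TYPE_LABEL
        return ", ".join(s.label() for s in self.substitutions)

    def __str__(self) -> str:
        return self.label

    def apply_to(self, ref: ReferenceSequence) -> str:
        """Reconstruct the full variant sequence from the reference."""
        seq = list(ref.sequence)
        for sub in self.substitutions:
            idx = sub.position - 1 - ref.position_offset
            if not 0 <= idx < len(seq):
                raise ValueError(f"substitution {sub.label()} outside reference")
            if seq[idx] != sub.ref_base:
                raise ValueError(
                    f"reference base mismatch at {sub.position}: "
                    f"expected {sub.ref_base}, found {seq[idx]}"
                )
            seq[idx] = sub.alt_base
        return "".join(seq)


def protein_label(key: VariantKey, ref: ReferenceSequence) -> str:
    """HGVS-like protein-level label (e.g. ``p.Ile117Ter``) for a variant.

    Multiple changed codons are joined with ``, ``; synonymous codon changes
    are reported as ``p.Xxx<n>=``.  Returns ``_wt`` for the wild-type key.
    """
    if not ref.is_coding:
        raise ValueError("protein labels require a coding reference")
    if key.is_wild_type:
        return WILD_TYPE_LABEL
    variant_seq = key.apply_to(ref)
    wt_protein = ref.protein()
    cds = variant_seq[ref.frame_offset :]
    changes = []
    for codon_i in range(len(wt_protein)):
        alt_codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_aa = _CODON_TABLE[alt_codon]
        ref_aa = wt_protein[codon_i]
        ref_codon = ref.sequence[ref.frame_offset :][codon_i * 3 : codon_i * 3 + 3]
        if alt_codon == ref_codon:
            continue
        pos = codon_i + 1
        if alt_aa == ref_aa:
            changes.append(f"p.{_aa3(ref_aa)}{pos}=")
        else:
            changes.append(f"p.{_aa3(ref_aa)}{pos}{_aa3(alt_aa)}")
    return ", ".join(changes)


class BarcodeMap:
    """Many-to-one mapping from barcode strings to variant labels."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._map

    def get(self, barcode: str) -> Optional[str]:
        return self._map.get(barcode)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "BarcodeMap":
        """Read a 2-column TSV (barcode, variant label)."""
        mapping: dict[str, str] = {}
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                barcode, variant = parts
                if barcode in mapping and mapping[barcode] != variant:
                    raise ValueError(
                        f"{path}:{lineno}: barcode {barcode} maps to multiple variants"
                    )
                mapping[barcode] = variant
        return cls(mapping)


def filter_read(read: ReadRecord, min_quality: int = 20) -> bool:
    """Accept a read only if every base quality >= min_quality and no base is N.

    Empty reads are rejected as degenerate.
    """
    if len(read) == 0:
        return False
    if "N" in read.bases:
        return False
    return all(q >= min_quality for q in read.qualities)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(read: ReadRecord) -> ReadRecord:
    return ReadRecord(
        read.bases.translate(_COMPLEMENT)[::-1], tuple(reversed(read.qualities))
    )


def merge_paired_reads(fwd: ReadRecord, rev: ReadRecord) -> ReadRecord:
    """Merge fully overlapping paired-end reads over the variable region.

    ``rev`` must already be reverse-complemented into the forward frame and
    cover the same positions as ``fwd``.  At each position the base with the
    higher quality wins and the merged quality is the max of the two; on a
    disagreement with equal qualities the position is set to N (quality 0) so
    that ambiguity flows into the N filter rather than a silent call.
    """
    if len(fwd) != len(rev):
        raise ValueError("paired reads must fully overlap the variable region")
    if len(fwd) == 0:
        raise ValueError("cannot merge empty reads")
    bases = []
    quals = []
    for bf, qf, br, qr in zip(fwd.bases, fwd.qualities, rev.bases, rev.qualities):
        if bf == br:
            bases.append(bf)
            quals.append(max(qf, qr))
        elif qf > qr:
            bases.append(bf)
            quals.append(qf)
        elif qr > qf:
            bases.append(br)
            quals.append(qr)
        else:
            bases.append("N")
            quals.append(0)
    return ReadRecord("".join(bases), tuple(quals))


class LengthMismatchError(ValueError):
    """Read length differs from the reference (indels cannot be called)."""


def call_variant(read: ReadRecord, ref: ReferenceSequence) -> VariantKey:
    """Call a variant by position-wise comparison against the reference.

    The read must have the same length and start point as the reference.
    Returns the wild-type sentinel when the read matches exactly.
    """
    if len(read) != len(ref):
        raise LengthMismatchError(
            f"read length {len(read)} != reference length {len(ref)}"
        )
    subs = tuple(
        Substitution(i + 1 + ref.position_offset, rb, ab)
        for i, (rb, ab) in enumerate(zip(ref.sequence, read.bases))
        if rb != ab
    )
    return VariantKey(subs)


@dataclass
class CountingStats:
    """Per-stream read accounting; total == counted + sum of rejections."""

    total: int = 0
    counted: int = 0
    rejected_quality: int = 0
    rejected_length: int = 0
    rejected_unmapped: int = 0

    @property
    def rejected(self) -> int:
        return self.rejected_quality + self.rejected_length + self.rejected_unmapped


def count_reads(
    reads: Iterable[ReadRecord],
    ref: Optional[ReferenceSequence] = None,
    barcode_map: Optional[BarcodeMap] = None,
    min_quality: int = 20,
) -> tuple[Counter, CountingStats]:
    """Count variants (or barcode-mapped variants) in a stream of reads.

    In direct mode (``ref`` given) each accepted read is called against the
    reference; reads of the wrong length go to the length-rejection tally.
    In barcode mode (``barcode_map`` given) each accepted read is looked up
    in the map; unmapped barcodes are tallied separately and excluded.

    Returns (variant label -> count, rejection statistics).
    """
    if (ref is None) == (barcode_map is None):
        raise ValueError("exactly one of ref or barcode_map must be given")
    counts: Counter = Counter()
    stats = CountingStats()
    for read in reads:
        stats.total += 1
        if not filter_read(read, min_quality):
            stats.rejected_quality += 1
            continue
        if barcode_map is not None:
            variant = barcode_map.get(read.bases)
            if variant is None:
                stats.rejected_unmapped += 1
                continue
            counts[variant] += 1
        else:
            try:
                key = call_variant(read, ref)
            except LengthMismatchError:
                stats.rejected_length += 1
                continue
            counts[key.label] += 1
        stats.counted += 1
    return counts, stats


def _open_text(path: Union[str, Path]) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream reads from a (optionally gzipped) Sanger Phred+33 FASTQ file."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                str(record.seq).upper(),
                tuple(record.letter_annotations["phred_quality"]),
            )


def read_fastq_pairs(
    fwd_path: Union[str, Path], rev_path: Union[str, Path]
) -> Iterator[ReadRecord]:
    """Stream merged reads from overlapping paired-end FASTQ files.

    The reverse read is reverse-complemented into the forward frame before
    merging.
    """
    for fwd, rev in zip(read_fastq(fwd_path), read_fastq(rev_path), strict=True):
        yield merge_paired_reads(fwd, reverse_complement(rev))
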