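"""Shared domain model: variant classes, the Variant record, normalization.

Coordinates are 0-based half-open everywhere inside the package; 1-based
coordinates appear only at VCF/GFF boundaries (see :mod:`pansv.io`).

Insertions have zero reference extent: ``ref_start == ref_end`` is the
insertion point, and the inserted sequence sits immediately *before* that
reference position (the VCF anchor base is the base to its left).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

SV_MIN_SIZE = 50  # bp; variants with max allele length >= this are SVs


class VariantClass(str, Enum):
    SNP = "SNP"
    SMALL_INS = "SMALL_INS"
    SMALL_DEL = "SMALL_DEL"
    CAN_INS = "CAN_INS"
    CAN_DEL = "CAN_DEL"
    COM_INS = "COM_INS"
    COM_DEL = "COM_DEL"
    INV = "INV"
    TRANS = "TRANS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


INDEL_CLASSES = {
    VariantClass.SMALL_INS,
    VariantClass.SMALL_DEL,
    VariantClass.CAN_INS,
    VariantClass.CAN_DEL,
    VariantClass.COM_INS,
    VariantClass.COM_DEL,
}
SV_CLASSES = {
    VariantClass.CAN_INS,
    VariantClass.CAN_DEL,
    VariantClass.COM_INS,
    VariantClass.COM_DEL,
    VariantClass.INV,
    VariantClass.TRANS,
}
CANONICAL_CLASSES = {VariantClass.CAN_INS, VariantClass.CAN_DEL}
COMPLEX_CLASSES = {VariantClass.COM_INS, VariantClass.COM_DEL}
DELETION_CLASSES = {VariantClass.CAN_DEL, VariantClass.COM_DEL}
INSERTION_CLASSES = {VariantClass.CAN_INS, VariantClass.COM_INS}

# prefix used in the public SV identifier scheme SV_{TYPE}_{chrom}G{index}
ID_PREFIX = {
    VariantClass.CAN_INS: "INS",
    VariantClass.CAN_DEL: "DEL",
    VariantClass.COM_INS: "COMINS",
    VariantClass.COM_DEL: "COMDEL",
    VariantClass.INV: "INV",
    VariantClass.TRANS: "TRANS",
}


@dataclass
class Variant:
    """A typed difference between a reference and a query genome.

    Doubles as the simulator's truth record (``TruthVariant``) and the
    caller's output record; truth records simply have no ``id`` assigned.
    """

    variant_class: VariantClass
    ref_chrom: str
    ref_start: int
    ref_end: int
    ref_allele: str
    alt_allele: str
    accession_id: str = ""
    qry_chrom: Optional[str] = None
    qry_start: Optional[int] = None
    qry_end: Optional[int] = None
    precise: bool = True
    id: Optional[str] = None
    # translocations only: where the segment re-inserts
    dest_chrom: Optional[str] = None
    dest_pos: Optional[int] = None
    info: dict = field(default_factory=dict)

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def alt_len(self) -> int:
        return len(self.alt_allele)

    @property
    def size(self) -> int:
        """Size used for the 50 bp class boundary: longer allele length."""
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def is_sv(self) -> bool:
        return self.variant_class in SV_CLASSES

    def validate(self) -> None:
        c = self.variant_class
        if self.ref_start > self.ref_end or self.ref_start < 0:
            raise ValueError(f"bad interval {self.ref_start}..{self.ref_end}")
        if c is VariantClass.SNP:
            if not (len(self.ref_allele) == len(self.alt_allele) == 1) or (
                self.ref_allele == self.alt_allele
            ):
                raise ValueError("SNP alleles must be single differing bases")
        elif c in (VariantClass.SMALL_INS, VariantClass.SMALL_DEL):
            if self.size >= SV_MIN_SIZE:
                raise ValueError("small InDel must be < 50 bp")
        elif c in CANONICAL_CLASSES:
            if self.size < SV_MIN_SIZE or min(len(self.ref_allele), len(self.alt_allele)) != 0:
                raise ValueError("canonical SV must be a pure InDel >= 50 bp")
        elif c in COMPLEX_CLASSES:
            if not self.ref_allele or not self.alt_allele:
                raise ValueError("complex SV needs both alleles non-empty")
            if len(self.ref_allele) == len(self.alt_allele):
                raise ValueError("complex SV alleles must differ in length")
        elif c is VariantClass.INV:
            from ._seq import revcomp

            if self.alt_allele != revcomp(self.ref_allele):
                raise ValueError("inversion alt must be reverse complement of ref")


TruthVariant = Variant


def left_align(variant: Variant, ref_seq: str) -> Variant:
    """Left-normalize a pure insertion or deletion against the reference.

    Standard VCF-style normalization: shift the event left while the
    junction sequence permits it.  Non-InDel classes and replacements
    (both alleles non-empty) are returned unchanged.  Query coordinates,
    when present, are shifted by the same amount.
    """
    ref_a, alt_a = variant.ref_allele, variant.alt_allele
    if not ((ref_a and not alt_a) or (alt_a and not ref_a)):
        return variant
    shift = 0
    if ref_a and not alt_a:  # deletion of [s, e)
        s, e = variant.ref_start, variant.ref_end
        while s - shift > 0 and ref_seq[s - shift - 1] == ref_seq[e - shift - 1]:
            shift += 1
        if shift == 0:
            return variant
        s2, e2 = s - shift, e - shift
        return replace(
            variant,
            ref_start=s2,
            ref_end=e2,
            ref_allele=ref_seq[s2:e2],
            qry_start=None if variant.qry_start is None else variant.qry_start - shift,
            qry_end=None if variant.qry_end is None else variant.qry_end - shift,
        )
    # insertion at point p
    p = variant.ref_start
    alt = alt_a
    while p - shift > 0 and alt[-1] == ref_seq[p - shift - 1]:
        alt = ref_seq[p - shift - 1] + alt[:-1]
        shift += 1
    if shift == 0:
        return variant
    p2 = p - shift
    return replace(
        variant,
        ref_start=p2,
        ref_end=p2,
        alt_allele=alt,
        qry_start=None if variant.qry_start is None else variant.qry_start - shift,
        qry_end=None if variant.qry_end is None else variant.qry_end - shift,
    )
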